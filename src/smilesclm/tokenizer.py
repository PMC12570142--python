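"""Atom-wise SMILES tokenization and vocabulary handling.

SMILES are kekulized before splitting (aromatic rings rewritten with explicit
alternating bonds, so no lowercase aromatic tokens remain) and then split with
the standard atom-wise regex used throughout the reaction/generation
literature: bracket atoms, two-letter halogens, ring-bond digits and %nn
closures, bonds and branches each form one token.  Joining the tokens
reproduces the kekulized string character for character.

The vocabulary is induced from a corpus, with three reserved specials:
``<PAD>`` (id 0, excluded from the loss), ``^`` (begin-of-sequence, the
generation conditioning prefix) and ``$`` (end-of-sequence).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

PAD_TOKEN = "<PAD>"
BOS_TOKEN = "^"
EOS_TOKEN = "$"
SPECIAL_TOKENS = (PAD_TOKEN, BOS_TOKEN, EOS_TOKEN)

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|N|O|S|P|F|I|B|C|b|c|n|o|s|p"
    r"|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|%[0-9]{2}|[0-9])"
)


class TokenizationError(ValueError):
    pass


class UnknownTokenError(KeyError):
    def __init__(self, tokens: Sequence[str]):
        self.tokens = list(tokens)
        super().__init__(f"tokens not in vocabulary: {self.tokens}")


def kekulize_smiles(smiles: str) -> str:
    """Rewrite a SMILES with explicit Kekulé bonds, preserving atom order."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise TokenizationError(f"unparseable SMILES: {smiles!r}")
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return Chem.MolToSmiles(mol, kekuleSmiles=True, canonical=False)


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES into atom-wise tokens after kekulization.

    Raises :class:`TokenizationError` on unparseable input or if any character
    is not covered by the token pattern (join-equals-input is enforced).
    """
    kek = kekulize_smiles(smiles)
    tokens = _TOKEN_RE.findall(kek)
    if "".join(tokens) != kek:
        raise TokenizationError(f"token pattern does not cover {kek!r}")
    return tokens


@dataclass
class TokenVocabulary:
    """Bijective token<->id map with reserved specials at ids 0..2."""

    token_to_id: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.token_to_id)

    @property
    def id_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_id.items()}

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD_TOKEN]

    @property
    def bos_id(self) -> int:
        return self.token_to_id[BOS_TOKEN]

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS_TOKEN]

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                [{"token": t, "id": i, "special": t in SPECIAL_TOKENS}
                 for t, i in sorted(self.token_to_id.items(), key=lambda kv: kv[1])],
                fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TokenVocabulary":
        with open(path) as fh:
            entries = json.load(fh)
        return cls(token_to_id={e["token"]: e["id"] for e in entries})


def build_vocabulary(corpus: Sequence[str]) -> TokenVocabulary:
    """Induce the vocabulary from a corpus: specials first (PAD=0, BOS=1,
    EOS=2), then all observed tokens in lexicographic order.  Deterministic
    and invariant to corpus order."""
    if len(corpus) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    observed: set[str] = set()
    for smi in corpus:
        observed.update(tokenize(smi))
    clash = observed & set(SPECIAL_TOKENS)
    if clash:
        raise ValueError(f"corpus contains reserved special tokens: {sorted(clash)}")
    tokens = list(SPECIAL_TOKENS) + sorted(observed)
    return TokenVocabulary(token_to_id={t: i for i, t in enumerate(tokens)})


def encode(tokens: Sequence[str], vocab: TokenVocabulary,
           add_bos: bool = False, add_eos: bool = False) -> list[int]:
    """Map tokens to ids; BOS/EOS are added only on explicit request.

    Raises :class:`UnknownTokenError` naming every out-of-vocabulary token —
    there is no silent UNK, the vocabulary must cover the corpus.
    """
    unknown = [t for t in tokens if t not in vocab.token_to_id]
    if unknown:
        raise UnknownTokenError(unknown)
    ids = [vocab.token_to_id[t] for t in tokens]
    if add_bos:
        ids.insert(0, vocab.bos_id)
    if add_eos:
        ids.append(vocab.eos_id)
    return ids


def decode(ids: Sequence[int], vocab: TokenVocabulary,
           strip_specials: bool = False) -> list[str]:
    """Map ids back to tokens (inverse of :func:`encode`)."""
    rev = vocab.id_to_token
    bad = [i for i in ids if i not in rev]
    if bad:
        raise KeyError(f"ids out of vocabulary range: {bad}")
    tokens = [rev[i] for i in ids]
    if strip_specials:
        tokens = [t for t in tokens if t not in SPECIAL_TOKENS]
    return tokens


def coverage_check(corpus: Sequence[str], vocab: TokenVocabulary | None = None) -> float:
    """Fraction of corpus strings that survive tokenize -> join -> reparse with
    the same molecule (canonical SMILES equality), and whose tokens are all in
    ``vocab`` when one is given.  Failures are counted, never raised."""
    if len(corpus) == 0:
        raise ValueError("coverage_check requires a non-empty corpus")
    ok = 0
    for smi in corpus:
        try:
            tokens = tokenize(smi)
            if vocab is not None and any(t not in vocab for t in tokens):
                continue
            rebuilt = Chem.MolFromSmiles("".join(tokens))
            if rebuilt is not None and Chem.MolToSmiles(rebuilt) == Chem.CanonSmiles(smi):
                ok += 1
        except Exception:
            continue
    return ok / len(corpus)


def randomize_smiles(smiles: str, rng: np.random.Generator) -> str:
    """A randomized, non-canonical but chemically equivalent SMILES rendering,
    obtained by renumbering atoms with an rng-driven permutation.  Fully
    determined by the rng state."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise TokenizationError(f"unparseable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    if n <= 1:
        return Chem.MolToSmiles(mol, canonical=False)
    perm = [int(i) for i in rng.permutation(n)]
    mol = Chem.RenumberAtoms(mol, perm)
    return Chem.MolToSmiles(mol, canonical=False)


def length_filter(
    token_lists: Sequence[Sequence[str]],
    min_tokens: int = 3,
    max_percentile: float = 99.0,
) -> list[int]:
    """Indices of sequences kept at dataset assembly: at least ``min_tokens``
    tokens and no longer than the ``max_percentile``-th percentile of token
    length over the full corpus."""
    lengths = np.array([len(t) for t in token_lists])
    cutoff = np.percentile(lengths, max_percentile)
    return [i for i, n in enumerate(lengths) if min_tokens <= n <= cutoff]
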