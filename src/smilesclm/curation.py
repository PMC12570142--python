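"""SMILES corpus curation.

Standardizes raw SMILES the way large bioactivity databases are prepared for
language-model training: stereochemistry is stripped (the model has no stereo
tokens), salts are removed, charges neutralized, organometallics and exotic
elements rejected, duplicates collapsed on canonical SMILES, and extreme string
lengths trimmed.  Every decision is recorded per molecule so that the final
corpus size reconciles exactly with the input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Elements allowed in a curated corpus (organic subset typical of drug-like space).
ALLOWED_ELEMENTS = frozenset({"H", "C", "N", "O", "F", "Br", "I", "Cl", "P", "S"})

_METALS = frozenset(
    """Li Be Na Mg Al K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Rb Sr Y Zr Nb Mo Tc
    Ru Rh Pd Ag Cd In Sn Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf
    Ta W Re Os Ir Pt Au Hg Tl Pb Bi Po Fr Ra Ac Th Pa U Np Pu""".split()
)


class RejectReason(str, Enum):
    NO_SMILES = "no_smiles"
    PARSE_ERROR = "parse_error"
    INORGANIC_OR_METAL = "inorganic_or_metal"
    DISALLOWED_ELEMENT = "disallowed_element"
    NON_NEUTRALIZABLE = "non_neutralizable"
    DUPLICATE = "duplicate"
    LENGTH_OUTLIER = "length_outlier"


@dataclass
class MoleculeRecord:
    """Outcome of standardizing one raw SMILES string."""

    raw_smiles: str
    canonical_smiles: str | None = None
    status: str = "rejected"
    reject_reason: RejectReason | None = None

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


@dataclass
class CurationReport:
    """Audit trail for a curation run: input size, per-step rejection counts,
    and the surviving corpus size.  ``output_size + sum(rejections) == input_size``."""

    input_size: int
    output_size: int
    counts_per_step: dict[str, int] = field(default_factory=dict)

    def check_conservation(self) -> bool:
        return self.output_size + sum(self.counts_per_step.values()) == self.input_size


def _neutralize(mol: Chem.Mol) -> Chem.Mol | None:
    """Neutralize simple charged groups by moving protons.

    An atom with formal charge +q and enough explicit hydrogens (or -q needing
    extra hydrogens) is set to charge 0 with its hydrogen count adjusted, the
    standard proton-transfer approach.  Atoms whose charge is balanced by a
    bonded counter-charge (e.g. nitro written in charge-separated form) are
    left untouched.  Returns None if the result does not sanitize.
    """
    mol = Chem.RWMol(mol)
    for atom in mol.GetAtoms():
        chg = atom.GetFormalCharge()
        if chg == 0:
            continue
        if any(nb.GetFormalCharge() * chg < 0 for nb in atom.GetNeighbors()):
            continue  # internal zwitterion/ylide pair; keep as drawn
        hcount = atom.GetTotalNumHs()
        if chg > 0 and hcount >= chg:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(hcount - chg)
            atom.SetNoImplicit(True)
        elif chg < 0:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(hcount - chg)
            atom.SetNoImplicit(True)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Desalt: keep the fragment with the most heavy atoms; ties broken by
    lexicographically smallest canonical SMILES."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]
    keyed = []
    for f in frags:
        try:
            smi = Chem.MolToSmiles(f)
        except Exception:
            smi = "~"  # sorts after all SMILES characters of interest
        keyed.append((-f.GetNumHeavyAtoms(), smi, f))
    keyed.sort(key=lambda t: (t[0], t[1]))
    return keyed[0][2]


def standardize_molecule(raw: str) -> MoleculeRecord:
    """Standardize one raw SMILES string.

    Pipeline order: parse -> strip stereochemistry -> keep largest organic
    fragment (desalt) -> neutralize charges -> reject metals / disallowed
    elements -> reject non-neutral residual charge -> canonical SMILES.
    Unparseable input yields a rejected record, never an exception.
    """
    if raw is None or not str(raw).strip():
        return MoleculeRecord(raw_smiles="" if raw is None else raw,
                              reject_reason=RejectReason.NO_SMILES)
    raw = str(raw).strip()
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        return MoleculeRecord(raw_smiles=raw, reject_reason=RejectReason.PARSE_ERROR)

    Chem.RemoveStereochemistry(mol)
    mol = _largest_organic_fragment(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return MoleculeRecord(raw_smiles=raw, reject_reason=RejectReason.PARSE_ERROR)

    neutral = _neutralize(mol)
    if neutral is None:
        return MoleculeRecord(raw_smiles=raw, reject_reason=RejectReason.NON_NEUTRALIZABLE)
    mol = neutral

    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    if symbols & _METALS:
        return MoleculeRecord(raw_smiles=raw, reject_reason=RejectReason.INORGANIC_OR_METAL)
    if "C" not in symbols:
        return MoleculeRecord(raw_smiles=raw, reject_reason=RejectReason.INORGANIC_OR_METAL)
    if not symbols <= ALLOWED_ELEMENTS:
        return MoleculeRecord(raw_smiles=raw, reject_reason=RejectReason.DISALLOWED_ELEMENT)

    if Chem.GetFormalCharge(mol) != 0:
        return MoleculeRecord(raw_smiles=raw, reject_reason=RejectReason.NON_NEUTRALIZABLE)

    canonical = Chem.MolToSmiles(mol)
    return MoleculeRecord(raw_smiles=raw, canonical_smiles=canonical, status="accepted")


class EmptyCorpusError(ValueError):
    pass


def curate_corpus(
    records: Sequence[str],
    length_trim: tuple[float, float] = (0.05, 0.05),
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Curate a list of raw SMILES.

    Each string is standardized, exact duplicates on canonical SMILES are
    removed (first occurrence kept), and molecules whose canonical-SMILES
    character length falls strictly below the lower or strictly above the
    upper empirical quantile of the post-deduplication length distribution
    are dropped.

    Parameters
    ----------
    records:
        Raw SMILES strings; must be non-empty.
    length_trim:
        ``(lower, upper)`` tail fractions for the length filter; ``(0, 0)``
        disables it.

    Returns
    -------
    (records, report):
        One :class:`MoleculeRecord` per input (order preserved) and a
        :class:`CurationReport` whose counts partition the input exactly.
    """
    if len(records) == 0:
        raise EmptyCorpusError("curate_corpus requires a non-empty corpus")
    lo, hi = length_trim
    if not (0 <= lo < 1 and 0 <= hi < 1):
        raise ValueError(f"length_trim fractions must be in [0, 1): {length_trim}")

    out = [standardize_molecule(s) for s in records]

    seen: set[str] = set()
    for rec in out:
        if not rec.accepted:
            continue
        if rec.canonical_smiles in seen:
            rec.status = "rejected"
            rec.reject_reason = RejectReason.DUPLICATE
            rec.canonical_smiles = None
        else:
            seen.add(rec.canonical_smiles)

    survivors = [r for r in out if r.accepted]
    if survivors and (lo > 0 or hi > 0):
        lengths = np.array([len(r.canonical_smiles) for r in survivors], dtype=float)
        lo_q = np.quantile(lengths, lo)
        hi_q = np.quantile(lengths, 1.0 - hi)
        for rec in survivors:
            n = len(rec.canonical_smiles)
            if n < lo_q or n > hi_q:
                rec.status = "rejected"
                rec.reject_reason = RejectReason.LENGTH_OUTLIER
                rec.canonical_smiles = None

    counts = Counter(r.reject_reason.value for r in out if not r.accepted)
    report = CurationReport(
        input_size=len(records),
        output_size=sum(r.accepted for r in out),
        counts_per_step=dict(counts),
    )
    assert report.check_conservation()
    return out, report


def accepted_smiles(records: Iterable[MoleculeRecord]) -> list[str]:
    """Canonical SMILES of the accepted records, in input order."""
    return [r.canonical_smiles for r in records if r.accepted]
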