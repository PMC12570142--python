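"""Synthetic SMILES corpora for testing and desk-scale experiments.

A small fragment grammar assembles valid molecules from chains, branches and
rings over a configurable element set, with optional injection of
syntactically broken strings and canonical duplicates.  The generator is the
package's stand-in for a real training database: it exercises every pipeline
stage (curation, tokenization, training, splitting, metrics) without any
download, and is fully deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .curation import ALLOWED_ELEMENTS

#: elements that can sit inside a chain or ring (valence >= 2)
_CHAIN_CAPABLE = ("C", "N", "O", "S", "P")
#: monovalent elements, used only as terminal substituents
_TERMINAL = ("F", "Cl", "Br", "I")


class FixtureConfigError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Parameters of a synthetic corpus.

    ``invalid_fraction`` / ``duplicate_fraction`` are the fractions of the
    output that are syntactically broken strings and repeats of earlier
    molecules, respectively.
    """

    n_molecules: int = 100
    max_heavy_atoms: int = 12
    ring_fraction: float = 0.3
    heteroatom_set: tuple[str, ...] = ("C", "N", "O")
    invalid_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise FixtureConfigError("n_molecules must be >= 1")
        for name in ("ring_fraction", "invalid_fraction", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureConfigError(f"{name} must be in [0, 1], got {v}")
        bad = set(self.heteroatom_set) - ALLOWED_ELEMENTS
        if bad:
            raise FixtureConfigError(f"heteroatom_set outside allowed elements: {sorted(bad)}")
        if "C" not in self.heteroatom_set:
            raise FixtureConfigError("heteroatom_set must contain C")
        if self.ring_fraction > 0 and self.max_heavy_atoms < 3:
            raise FixtureConfigError("ring_fraction > 0 requires max_heavy_atoms >= 3")
        if self.max_heavy_atoms < 1:
            raise FixtureConfigError("max_heavy_atoms must be >= 1")


def _chain(rng: np.random.Generator, n: int, atoms: tuple[str, ...],
           terminals: tuple[str, ...], allow_branch: bool = True) -> str:
    """A linear chain of n heavy atoms with occasional branches / =O groups."""
    parts: list[str] = []
    budget = n
    hetero = [a for a in atoms if a != "C"]
    while budget > 0:
        # carbon-rich chains: heteroatoms appear at ~40% of positions overall
        if hetero and rng.random() < 0.4:
            a = hetero[rng.integers(len(hetero))]
        else:
            a = "C"
        parts.append(a)
        budget -= 1
        if a == "C" and allow_branch and budget >= 1 and rng.random() < 0.25:
            if terminals and rng.random() < 0.4:
                parts.append(f"({terminals[rng.integers(len(terminals))]})")
                budget -= 1
            elif "O" in atoms and rng.random() < 0.5:
                parts.append("(=O)")
                budget -= 1
            else:
                k = int(min(budget, 1 + rng.integers(2)))
                parts.append("(" + _chain(rng, k, atoms, (), allow_branch=False) + ")")
                budget -= k
    return "".join(parts)


def _molecule(rng: np.random.Generator, spec: FixtureSpec) -> str:
    atoms = tuple(a for a in _CHAIN_CAPABLE if a in spec.heteroatom_set)
    terminals = tuple(a for a in _TERMINAL if a in spec.heteroatom_set)
    n = int(rng.integers(2, spec.max_heavy_atoms + 1))
    want_ring = spec.max_heavy_atoms >= 3 and rng.random() < spec.ring_fraction
    if want_ring:
        size = int(rng.integers(3, min(6, max(3, n)) + 1))
        # at most one heteroatom inside the ring keeps valences trivially legal
        ring_atoms = ["C"] * size
        hetero = [a for a in atoms if a in ("N", "O", "S")]
        if hetero and rng.random() < 0.5:
            ring_atoms[int(rng.integers(size))] = hetero[int(rng.integers(len(hetero)))]
        smi = ring_atoms[0] + "1" + "".join(ring_atoms[1:]) + "1"
        rest = n - size
        if rest > 0:
            smi += _chain(rng, rest, atoms, terminals)
    else:
        smi = _chain(rng, max(1, n), atoms, terminals)
    return smi


def _corrupt(rng: np.random.Generator, smi: str) -> str:
    """Make a string that cannot parse as SMILES."""
    mode = int(rng.integers(3))
    if mode == 0:
        return smi + "("  # unclosed branch
    if mode == 1:
        return smi + "1"  # unclosed ring bond
    return smi + "J"  # no such element token


def generate_fixture_corpus(spec: FixtureSpec) -> list[str]:
    """Emit exactly ``spec.n_molecules`` SMILES strings, deterministically.

    Valid members parse under RDKit and use only ``spec.heteroatom_set``
    elements; ``invalid_fraction`` of the output is syntactically broken and
    ``duplicate_fraction`` repeats earlier molecules (canonical duplicates).
    """
    rng = np.random.default_rng(spec.seed)
    n_invalid = int(round(spec.n_molecules * spec.invalid_fraction))
    n_dup = int(round(spec.n_molecules * spec.duplicate_fraction))
    n_base = spec.n_molecules - n_invalid - n_dup
    if n_base < 1:
        raise FixtureConfigError(
            "invalid_fraction + duplicate_fraction leave no room for base molecules")

    base: list[str] = []
    seen: set[str] = set()
    stall = 0
    while len(base) < n_base:
        smi = _molecule(rng, spec)
        mol = Chem.MolFromSmiles(smi)  # grammar is valid by construction, but verify
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        # base set is canonically unique, so duplicate_fraction alone controls
        # the duplicate count; give up on uniqueness if the chemical space is
        # too small to supply n_base distinct molecules
        if canon in seen and stall < 50 * n_base:
            stall += 1
            continue
        seen.add(canon)
        base.append(smi)

    dups = [base[int(rng.integers(len(base)))] for _ in range(n_dup)]
    invalids = [_corrupt(rng, base[int(rng.integers(len(base)))]) for _ in range(n_invalid)]

    out = base + dups + invalids
    rng.shuffle(out)
    return out
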