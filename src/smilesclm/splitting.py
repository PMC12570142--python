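"""Leakage-safe holdout construction.

Evaluating a generative model on molecules that are near-duplicates of its
fine-tuning set inflates every recovery metric.  The protocol here prevents
that in two stages: (1) a Bemis-Murcko scaffold group split, so molecules
sharing a scaffold never straddle the train/holdout boundary, followed by
(2) sphere exclusion, removing every holdout candidate whose maximum Tanimoto
similarity (ECFP4, 2048 bits) to any training molecule reaches the threshold
(default 0.6).  Survivors are certified by the recorded maximum
cross-partition similarity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .fingerprints import ECFP4, FingerprintSpec, bulk_max_tanimoto, fingerprints

#: scaffold assigned to acyclic molecules (no ring system)
EMPTY_SCAFFOLD = ""


@dataclass
class LeakageSafeSplit:
    train: list[str]
    holdout: list[str]
    removed: list[str]
    threshold: float = 0.6
    fingerprint: FingerprintSpec = ECFP4
    max_cross_similarity: float = 0.0
    #: max Tanimoto to train per surviving holdout molecule, same order as holdout
    holdout_max_similarity: list[float] = field(default_factory=list)

    def audit(self) -> float:
        """Recompute the maximum train x holdout Tanimoto by brute force."""
        if not self.train or not self.holdout:
            return 0.0
        hfps = fingerprints(self.holdout, self.fingerprint)
        tfps = fingerprints(self.train, self.fingerprint)
        return float(bulk_max_tanimoto(hfps, tfps).max())

    def to_csv(self, path) -> None:
        """Split manifest: smiles, partition, scaffold, max similarity to train."""
        sims = dict(zip(self.holdout, self.holdout_max_similarity))
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["smiles", "partition", "scaffold", "max_similarity_to_train"])
            for part, items in (("train", self.train), ("holdout", self.holdout),
                                ("removed", self.removed)):
                for smi in items:
                    w.writerow([smi, part, bemis_murcko_scaffold(smi),
                                f"{sims[smi]:.6f}" if part == "holdout" else ""])


def bemis_murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold (ring systems + linkers, side chains
    removed).  Acyclic molecules map to the empty-scaffold sentinel ``""``."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    scaf = MurckoScaffold.GetScaffoldForMol(mol)
    if scaf is None or scaf.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    return Chem.MolToSmiles(scaf)


def scaffold_group_split(corpus: list[str], holdout_fraction: float = 0.2,
                         seed: int = 0) -> tuple[list[str], list[str]]:
    """Assign whole scaffold groups to the holdout side until its size is as
    close to ``holdout_fraction * N`` as group granularity allows.

    Groups are shuffled with the seed and assigned greedily; two molecules
    sharing a scaffold are always co-assigned.  A corpus with a single
    scaffold cannot be split and raises ``ValueError``.
    """
    if len(corpus) < 5:
        raise ValueError("corpus too small to split (need >= 5 molecules)")
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    groups: dict[str, list[str]] = {}
    for smi in corpus:
        groups.setdefault(bemis_murcko_scaffold(smi), []).append(smi)
    if len(groups) < 2:
        raise ValueError("corpus contains a single scaffold; cannot split")
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    target = holdout_fraction * len(corpus)
    holdout: list[str] = []
    train: list[str] = []
    for k in keys:
        members = groups[k]
        # take the group if it brings the holdout closer to the target size
        if abs(len(holdout) + len(members) - target) < abs(len(holdout) - target) \
                and len(holdout) < target:
            holdout.extend(members)
        else:
            train.extend(members)
    if not holdout:  # granularity pathologies: force the smallest group over
        k = min(keys, key=lambda k_: len(groups[k_]))
        holdout = groups[k]
        train = [s for s in train if s not in set(holdout)]
    return train, holdout


def sphere_exclusion(train: list[str], holdout_candidate: list[str],
                     threshold: float = 0.6,
                     fp: FingerprintSpec = ECFP4) -> LeakageSafeSplit:
    """Remove every holdout candidate whose maximum Tanimoto similarity to any
    training molecule is >= ``threshold`` (survivors satisfy strict ``<``).

    An emptied holdout is a legitimate outcome for small, homogeneous targets
    and is reported, not raised.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not holdout_candidate:
        return LeakageSafeSplit(train=list(train), holdout=[], removed=[],
                                threshold=threshold, fingerprint=fp)
    tfps = fingerprints(train, fp)
    hfps = fingerprints(holdout_candidate, fp)
    max_sims = bulk_max_tanimoto(hfps, tfps)
    holdout, removed, kept_sims = [], [], []
    for smi, s in zip(holdout_candidate, max_sims):
        if s >= threshold:
            removed.append(smi)
        else:
            holdout.append(smi)
            kept_sims.append(float(s))
    return LeakageSafeSplit(
        train=list(train), holdout=holdout, removed=removed,
        threshold=threshold, fingerprint=fp,
        max_cross_similarity=float(max(kept_sims)) if kept_sims else 0.0,
        holdout_max_similarity=kept_sims)


def leakage_safe_split(corpus: list[str], holdout_fraction: float = 0.2,
                       threshold: float = 0.6, seed: int = 0,
                       fp: FingerprintSpec = ECFP4) -> LeakageSafeSplit:
    """Full protocol: scaffold group split, then sphere exclusion."""
    train, holdout_candidate = scaffold_group_split(corpus, holdout_fraction, seed)
    return sphere_exclusion(train, holdout_candidate, threshold, fp)
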