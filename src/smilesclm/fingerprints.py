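"""Morgan fingerprints and Tanimoto similarity helpers.

Three fingerprint settings are used at different sites of the pipeline, each
fixed where it is consumed: radius 2 / 2048 bits (the classic ECFP4 setting)
for the leakage-safe split, nearest-neighbor and diversity metrics and the
chemical-space projection, and radius 3 / 2048 bits for scaffold clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator


@dataclass(frozen=True)
class FingerprintSpec:
    kind: str = "morgan"
    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.kind != "morgan":
            raise ValueError(f"unsupported fingerprint kind {self.kind!r}")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.n_bits < 1 or self.n_bits & (self.n_bits - 1):
            raise ValueError("n_bits must be a positive power of two")


#: ECFP4-equivalent setting used by split/SNN/IntDiv/recovery metrics
ECFP4 = FingerprintSpec(radius=2, n_bits=2048)
#: radius-3 setting used for scaffold clustering
SCAFFOLD_FP = FingerprintSpec(radius=3, n_bits=2048)


def fingerprint(smiles: str, spec: FingerprintSpec = ECFP4):
    """Bit-vector Morgan fingerprint; raises on unparseable SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=spec.radius,
                                                    fpSize=spec.n_bits)
    return gen.GetFingerprint(mol)


def fingerprints(smiles: Sequence[str], spec: FingerprintSpec = ECFP4) -> list:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=spec.radius,
                                                    fpSize=spec.n_bits)
    out = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {s!r}")
        out.append(gen.GetFingerprint(mol))
    return out


def tanimoto(fp_a, fp_b) -> float:
    return DataStructs.TanimotoSimilarity(fp_a, fp_b)


def bulk_max_tanimoto(query_fps: Sequence, reference_fps: Sequence) -> np.ndarray:
    """For each query fingerprint, the maximum Tanimoto similarity over the
    reference set."""
    out = np.zeros(len(query_fps))
    for i, fp in enumerate(query_fps):
        sims = DataStructs.BulkTanimotoSimilarity(fp, list(reference_fps))
        out[i] = max(sims) if sims else 0.0
    return out


def fingerprint_matrix(smiles: Sequence[str], spec: FingerprintSpec = ECFP4) -> np.ndarray:
    """Dense 0/1 numpy array (n_molecules, n_bits), e.g. for UMAP."""
    fps = fingerprints(smiles, spec)
    arr = np.zeros((len(fps), spec.n_bits), dtype=np.uint8)
    for i, fp in enumerate(fps):
        DataStructs.ConvertToNumpyArray(fp, arr[i])
    return arr
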