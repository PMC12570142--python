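"""Generative-chemistry metric panel.

Covers the standard axes of evaluation for a SMILES generator:

* quality — validity / uniqueness / novelty percentages;
* physicochemical profile — MW, logP, ring count, HBD, HBA, rotatable bonds,
  QED, SA score, Lipinski rule-of-five pass and PAINS flags per molecule;
* distributional fidelity — Kolmogorov-Smirnov statistic and Kullback-Leibler
  divergence per property, plus a Fréchet distance between Gaussian fits of
  molecular embeddings computed on equal-size resampled subsets;
* target-specific — recovery rate, scaffold recovery, similarity to nearest
  neighbor (SNN), internal diversity (IntDiv1/2);
* scaffold diversity — greedy fingerprint clustering of unique Bemis-Murcko
  scaffolds and the Shannon entropy of cluster populations (SDI, in bits);
* chemical-space projection — 2D UMAP on fingerprints (Jaccard metric).

QED, SA, NP-likeness and PAINS are consumed from RDKit's published scorers,
never re-implemented.
"""

from __future__ import annotations

import contextlib
import io
import math
import os
import sys
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDConfig
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdMolDescriptors
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams
from scipy import linalg, stats

from .fingerprints import (ECFP4, SCAFFOLD_FP, FingerprintSpec,
                           bulk_max_tanimoto, fingerprint_matrix, fingerprints,
                           tanimoto)
from .splitting import bemis_murcko_scaffold

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
sys.path.append(os.path.join(RDConfig.RDContribDir, "NP_Score"))
import sascorer  # noqa: E402  (RDKit contrib, published SA scorer)
import npscorer  # noqa: E402  (RDKit contrib, published NP-likeness scorer)

with contextlib.redirect_stdout(io.StringIO()), contextlib.redirect_stderr(io.StringIO()):
    _NP_MODEL = npscorer.readNPModel()

_PAINS_PARAMS = FilterCatalogParams()
_PAINS_PARAMS.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
_PAINS = FilterCatalog(_PAINS_PARAMS)


# ---------------------------------------------------------------------------
# quality metrics
# ---------------------------------------------------------------------------

def quality_metrics(generated_raw: Sequence[str],
                    train_canonical_set: set[str] | Sequence[str]
                    ) -> tuple[float, float | None, float | None]:
    """Validity, uniqueness and novelty, all as percentages.

    validity   = valid strings / raw strings;
    uniqueness = unique canonical molecules / valid strings;
    novelty    = unique molecules absent from the training set / unique.

    With zero valid molecules uniqueness and novelty are undefined and
    returned as ``None``.
    """
    if len(generated_raw) == 0:
        raise ValueError("empty generated set")
    train = set(train_canonical_set)
    valid = []
    for s in generated_raw:
        mol = Chem.MolFromSmiles(s) if s else None
        if mol is not None:
            valid.append(Chem.MolToSmiles(mol))
    validity = 100.0 * len(valid) / len(generated_raw)
    if not valid:
        return validity, None, None
    unique = list(dict.fromkeys(valid))
    uniqueness = 100.0 * len(unique) / len(valid)
    novelty = 100.0 * sum(1 for s in unique if s not in train) / len(unique)
    return validity, uniqueness, novelty


def uniqueness_at_k(generated_raw: Sequence[str], k: int) -> float | None:
    """Uniqueness computed on the first k valid molecules in generation order
    (the convention of standardized benchmark reporting)."""
    valid = []
    for s in generated_raw:
        mol = Chem.MolFromSmiles(s) if s else None
        if mol is not None:
            valid.append(Chem.MolToSmiles(mol))
        if len(valid) == k:
            break
    if not valid:
        return None
    return 100.0 * len(set(valid)) / len(valid)


# ---------------------------------------------------------------------------
# property profile
# ---------------------------------------------------------------------------

PROPERTY_COLUMNS = ("mw", "logp", "rings", "hbd", "hba", "rot_bonds",
                    "qed", "sa", "lipinski_pass", "pains_flag")


def property_profile(smiles_list: Sequence[str]) -> pd.DataFrame:
    """One row per valid molecule with the standard descriptor panel.

    Invalid SMILES are skipped (their count is attached as
    ``df.attrs['n_skipped']``).  QED is in [0, 1]; SA in [1, 10] with lower
    values indicating easier synthesis.
    """
    rows = []
    skipped = 0
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            skipped += 1
            continue
        mw = Descriptors.MolWt(mol)
        logp = Crippen.MolLogP(mol)
        hbd = Lipinski.NumHDonors(mol)
        hba = Lipinski.NumHAcceptors(mol)
        rows.append({
            "smiles": smi,
            "mw": mw,
            "logp": logp,
            "rings": rdMolDescriptors.CalcNumRings(mol),
            "hbd": hbd,
            "hba": hba,
            "rot_bonds": Descriptors.NumRotatableBonds(mol),
            "qed": QED.qed(mol),
            "sa": sascorer.calculateScore(mol),
            "lipinski_pass": (mw <= 500 and logp <= 5 and hbd <= 5 and hba <= 10),
            "pains_flag": _PAINS.HasMatch(mol),
        })
    df = pd.DataFrame(rows, columns=["smiles", *PROPERTY_COLUMNS])
    df.attrs["n_skipped"] = skipped
    return df


def np_likeness(smiles: str) -> float:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return float(npscorer.scoreMol(mol, _NP_MODEL))


def np_likeness_profile(gen: Sequence[str], ref: Sequence[str]
                        ) -> tuple[float, float, float]:
    """Mean NP-likeness of each set plus the KS statistic between the two
    per-molecule score distributions."""
    sg = np.array([np_likeness(s) for s in gen])
    sr = np.array([np_likeness(s) for s in ref])
    ks, _ = distribution_distance(sg, sr)
    return float(sg.mean()), float(sr.mean()), ks


# ---------------------------------------------------------------------------
# distributional metrics
# ---------------------------------------------------------------------------

def distribution_distance(values_gen: Sequence[float], values_ref: Sequence[float],
                          n_bins: int = 50, smoothing: float = 1e-10
                          ) -> tuple[float, float]:
    """(KS statistic, KL divergence) between two samples of a property.

    KS is the supremum ECDF difference; KL is computed on ``n_bins``
    equal-width bins spanning the pooled range with additive smoothing, so
    disjoint supports give a large but finite divergence.
    """
    a = np.asarray(values_gen, dtype=float)
    b = np.asarray(values_ref, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ks = float(stats.ks_2samp(a, b, method="asymp").statistic)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:  # all values identical across both samples
        return ks, 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p = np.histogram(a, bins=edges)[0].astype(float) + smoothing
    q = np.histogram(b, bins=edges)[0].astype(float) + smoothing
    p /= p.sum()
    q /= q.sum()
    kl = float(np.sum(p * np.log(p / q)))
    return ks, max(kl, 0.0)


def descriptor_embedding(smiles_list: Sequence[str]) -> np.ndarray:
    """Default molecular embedding for the Fréchet metric: a vector of ten
    physicochemical descriptors per molecule.  Pluggable — any callable
    returning an (n, d) array can replace it."""
    rows = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        rows.append([
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            rdMolDescriptors.CalcNumRings(mol),
            Lipinski.NumHDonors(mol),
            Lipinski.NumHAcceptors(mol),
            Descriptors.NumRotatableBonds(mol),
            rdMolDescriptors.CalcTPSA(mol),
            rdMolDescriptors.CalcFractionCSP3(mol),
            rdMolDescriptors.CalcNumAromaticRings(mol),
            mol.GetNumHeavyAtoms(),
        ])
    return np.asarray(rows, dtype=float)


def frechet_distance(gen: Sequence[str], ref: Sequence[str],
                     featurizer: Callable[[Sequence[str]], np.ndarray]
                     = descriptor_embedding) -> float:
    """Fréchet distance between Gaussian fits of molecular embeddings:
    ``|mu1 - mu2|^2 + Tr(C1 + C2 - 2 (C1 C2)^1/2)``."""
    x = featurizer(gen)
    y = featurizer(ref)
    mu1, mu2 = x.mean(0), y.mean(0)
    c1 = np.cov(x, rowvar=False)
    c2 = np.cov(y, rowvar=False)
    c1 = np.atleast_2d(c1)
    c2 = np.atleast_2d(c2)
    eps = 1e-9 * np.eye(c1.shape[0])
    covmean = linalg.sqrtm((c1 + eps) @ (c2 + eps))
    if isinstance(covmean, tuple):  # older scipy returns (sqrtm, errest)
        covmean = covmean[0]
    covmean = np.real(covmean)
    d2 = float(np.sum((mu1 - mu2) ** 2) + np.trace(c1 + c2 - 2 * covmean))
    return max(d2, 0.0)


def fcd_resampled(gen_smiles: Sequence[str], ref_smiles: Sequence[str],
                  subset_size: int, n_rep: int = 3, seed: int = 0,
                  featurizer: Callable[[Sequence[str]], np.ndarray]
                  = descriptor_embedding) -> tuple[float, float]:
    """Fréchet distance on equal-size random subsets of both sets, repeated
    ``n_rep`` times; returns (mean, sd).

    Equal-size subsampling avoids the size-trap bias of comparing sets of
    different cardinality.  The two sides are subsampled with the same
    per-repetition seed, so identical inputs give distance 0.
    """
    if subset_size > len(gen_smiles) or subset_size > len(ref_smiles):
        raise ValueError("subset_size larger than one of the sets")
    vals = []
    for rep in range(n_rep):
        s = int(np.random.default_rng([seed, rep]).integers(2 ** 31))
        gi = np.random.default_rng(s).choice(len(gen_smiles), subset_size, replace=False)
        ri = np.random.default_rng(s).choice(len(ref_smiles), subset_size, replace=False)
        vals.append(frechet_distance([gen_smiles[i] for i in gi],
                                     [ref_smiles[i] for i in ri], featurizer))
    return float(np.mean(vals)), float(np.std(vals))


# ---------------------------------------------------------------------------
# similarity-based metrics
# ---------------------------------------------------------------------------

def snn(gen: Sequence[str], reference: Sequence[str],
        fp: FingerprintSpec = ECFP4) -> float:
    """Mean over generated molecules of the maximum Tanimoto similarity to the
    reference set (similarity to nearest neighbor)."""
    if not gen or not reference:
        raise ValueError("both sets must be non-empty")
    gfps = fingerprints(gen, fp)
    rfps = fingerprints(reference, fp)
    return float(bulk_max_tanimoto(gfps, rfps).mean())


def internal_diversity(gen: Sequence[str], fp: FingerprintSpec = ECFP4,
                       p: int = 1) -> float:
    """IntDiv_p = 1 - (mean over ordered pairs of Tanimoto^p)^(1/p).

    ``p=1`` is the plain average pairwise dissimilarity; ``p=2`` penalizes
    clusters of highly similar molecules more strongly (IntDiv2 <= IntDiv1).
    Ordered pairs include self-pairs, the standard benchmarking convention.
    """
    if not gen:
        raise ValueError("empty set")
    if p < 1:
        raise ValueError("p must be >= 1")
    from rdkit import DataStructs
    fps = fingerprints(gen, fp)
    n = len(fps)
    acc = 0.0
    for i in range(n):
        sims = np.array(DataStructs.BulkTanimotoSimilarity(fps[i], fps))
        acc += float((sims ** p).sum())
    return 1.0 - (acc / (n * n)) ** (1.0 / p)


def recovery_rate(holdout: Sequence[str], generated: Sequence[str],
                  threshold: float = 0.6, fp: FingerprintSpec = ECFP4) -> float:
    """Fraction of holdout molecules whose maximum Tanimoto similarity to any
    generated molecule is >= ``threshold`` (rediscovery)."""
    if not holdout:
        raise ValueError("empty holdout set")
    if not generated:
        return 0.0
    hfps = fingerprints(holdout, fp)
    gfps = fingerprints(generated, fp)
    return float((bulk_max_tanimoto(hfps, gfps) >= threshold).mean())


def scaffold_recovery(reference_set: Sequence[str], generated: Sequence[str]) -> float:
    """Fraction of unique Bemis-Murcko scaffolds of the reference set that
    appear among the scaffolds of the generated set.  The empty (acyclic)
    scaffold sentinel participates as one scaffold."""
    ref_scaffolds = {bemis_murcko_scaffold(s) for s in reference_set}
    if not ref_scaffolds:
        raise ValueError("empty reference set")
    gen_scaffolds = {bemis_murcko_scaffold(s) for s in generated}
    return len(ref_scaffolds & gen_scaffolds) / len(ref_scaffolds)


# ---------------------------------------------------------------------------
# scaffold clustering / diversity
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldClustering:
    clusters: list[list[str]]
    threshold: float = 0.6
    fingerprint: FingerprintSpec = SCAFFOLD_FP

    @property
    def representatives(self) -> list[str]:
        return [c[0] for c in self.clusters]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def canonical_scaffold_order(scaffolds: Sequence[str],
                             counts: dict[str, int] | None = None) -> list[str]:
    """Deterministic greedy-clustering input order: descending scaffold
    frequency (all ties when no counts are given), ties lexicographic."""
    if counts is None:
        return sorted(scaffolds)
    return sorted(scaffolds, key=lambda s: (-counts.get(s, 0), s))


def scaffold_clusters(scaffolds: Sequence[str], threshold: float = 0.6,
                      fp: FingerprintSpec = SCAFFOLD_FP,
                      counts: dict[str, int] | None = None
                      ) -> tuple[ScaffoldClustering, int, float]:
    """Greedy clustering of unique scaffolds plus the scaffold diversity index.

    Scaffolds are visited in the canonical order and assigned to the first
    existing cluster whose representative (first member) has Tanimoto
    similarity >= ``threshold``, else they start a new cluster.  SDI is the
    Shannon entropy (base 2) of the cluster population distribution; 0 when
    everything collapses into one cluster, log2(n_clusters) when populations
    are even.

    The empty acyclic-scaffold sentinel forms its own cluster.
    """
    scaffolds = list(scaffolds)
    if len(scaffolds) == 0:
        raise ValueError("no scaffolds to cluster")
    if len(set(scaffolds)) != len(scaffolds):
        raise ValueError("scaffold_clusters expects unique scaffolds")
    ordered = canonical_scaffold_order(scaffolds, counts)

    clusters: list[list[str]] = []
    rep_fps: list = []
    empty_cluster: list[str] | None = None
    for scaf in ordered:
        if scaf == "":
            if empty_cluster is None:
                empty_cluster = []
                clusters.append(empty_cluster)
                rep_fps.append(None)
            empty_cluster.append(scaf)
            continue
        sfp = fingerprints([scaf], fp)[0]
        placed = False
        for ci, rfp in enumerate(rep_fps):
            if rfp is not None and tanimoto(sfp, rfp) >= threshold:
                clusters[ci].append(scaf)
                placed = True
                break
        if not placed:
            clusters.append([scaf])
            rep_fps.append(sfp)

    sizes = np.array([len(c) for c in clusters], dtype=float)
    f = sizes / sizes.sum()
    sdi = float(-(f * np.log2(f)).sum()) + 0.0  # normalize -0.0
    return ScaffoldClustering(clusters=clusters, threshold=threshold,
                              fingerprint=fp), len(clusters), sdi


# ---------------------------------------------------------------------------
# chemical-space projection
# ---------------------------------------------------------------------------

def chemical_space_projection(train: Sequence[str], generated: Sequence[str],
                              holdout: Sequence[str] | None = None,
                              n_neighbors: int = 30, min_dist: float = 0.1,
                              seed: int = 0,
                              fp: FingerprintSpec = ECFP4) -> dict[str, np.ndarray]:
    """2D UMAP of Morgan fingerprints (Jaccard metric).

    The projection is fitted on train + generated; holdout molecules are only
    transformed into the fitted space, never used for fitting.  Returns a dict
    of coordinate arrays keyed ``train`` / ``generated`` / ``holdout``.
    """
    import umap  # deferred: numba compilation makes this import expensive

    fit_smiles = list(train) + list(generated)
    if len(fit_smiles) < 4:
        raise ValueError("need at least 4 molecules to project")
    if n_neighbors >= len(fit_smiles):
        warnings.warn(
            f"n_neighbors={n_neighbors} >= n_molecules={len(fit_smiles)}; "
            f"reducing to {len(fit_smiles) - 1}")
        n_neighbors = len(fit_smiles) - 1
    x = fingerprint_matrix(fit_smiles, fp)
    reducer = umap.UMAP(n_components=2, metric="jaccard",
                        n_neighbors=n_neighbors, min_dist=min_dist,
                        random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(x)
    out = {"train": coords[: len(train)], "generated": coords[len(train):]}
    if holdout:
        h = fingerprint_matrix(list(holdout), fp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["holdout"] = reducer.transform(h)
    return out


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """The full metric panel for one generated set against its references."""

    validity: float
    uniqueness: float | None
    novelty: float | None
    qed_mean: float | None = None
    sa_mean: float | None = None
    ks_stats: dict[str, float] = field(default_factory=dict)
    kl_divs: dict[str, float] = field(default_factory=dict)
    fcd_mean: float | None = None
    fcd_sd: float | None = None
    snn: float | None = None
    intdiv1: float | None = None
    intdiv2: float | None = None
    rr: float | None = None
    rr_scaffold: float | None = None
    n_distinct_scaffold_clusters: int | None = None
    sdi: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def table(self) -> str:
        lines = [f"{'metric':<32}value"]
        for k, v in self.to_dict().items():
            if isinstance(v, dict):
                for kk, vv in v.items():
                    key = f"{k}.{kk}"
                    lines.append(f"{key:<32}{vv:.4f}")
            elif isinstance(v, float):
                lines.append(f"{k:<32}{v:.4f}")
            elif v is not None:
                lines.append(f"{k:<32}{v}")
        return "\n".join(lines)


def evaluate_generation(generated_raw: Sequence[str], train_set: Sequence[str],
                        holdout: Sequence[str] | None = None,
                        fcd_subset: int | None = None, seed: int = 0
                        ) -> MetricsReport:
    """Convenience driver assembling the panel for one generation run."""
    train_canon = [Chem.CanonSmiles(s) for s in train_set]
    validity, uniqueness, novelty = quality_metrics(generated_raw, set(train_canon))
    report = MetricsReport(validity=validity, uniqueness=uniqueness, novelty=novelty)
    valid = [Chem.MolToSmiles(m) for m in
             (Chem.MolFromSmiles(s) for s in generated_raw if s) if m is not None]
    if not valid:
        return report
    unique = list(dict.fromkeys(valid))

    props_gen = property_profile(unique)
    props_ref = property_profile(train_canon)
    report.qed_mean = float(props_gen["qed"].mean())
    report.sa_mean = float(props_gen["sa"].mean())
    for col in ("mw", "logp", "rings", "hbd", "hba", "rot_bonds", "qed", "sa"):
        ks, kl = distribution_distance(props_gen[col], props_ref[col])
        report.ks_stats[col] = ks
        report.kl_divs[col] = kl

    subset = fcd_subset or min(len(unique), len(train_canon), 500)
    if subset >= 2:
        report.fcd_mean, report.fcd_sd = fcd_resampled(
            unique, train_canon, subset_size=min(subset, len(unique), len(train_canon)),
            seed=seed)
    report.snn = snn(unique, train_canon)
    report.intdiv1 = internal_diversity(unique, p=1)
    report.intdiv2 = internal_diversity(unique, p=2)
    if holdout:
        report.rr = recovery_rate(holdout, unique)
        report.rr_scaffold = scaffold_recovery(holdout, unique)
    gen_scaffolds = sorted({bemis_murcko_scaffold(s) for s in unique})
    _, n_clusters, sdi = scaffold_clusters(gen_scaffolds)
    report.n_distinct_scaffold_clusters = n_clusters
    report.sdi = sdi
    return report
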