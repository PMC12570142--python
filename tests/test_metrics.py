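"""Metric panel: hand-computable cases and brute-force oracle equivalence."""

import math

import numpy as np
import pytest
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from smilesclm import (distribution_distance, evaluate_generation,
                       fcd_resampled, frechet_distance, internal_diversity,
                       np_likeness_profile, property_profile, quality_metrics,
                       recovery_rate, scaffold_clusters, scaffold_recovery,
                       snn)
from smilesclm.metrics import (PROPERTY_COLUMNS, canonical_scaffold_order,
                               descriptor_embedding, uniqueness_at_k)


def _oracle_fps(smiles):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    return [gen.GetFingerprint(Chem.MolFromSmiles(s)) for s in smiles]


class TestQualityMetrics:
    def test_hand_case(self):
        generated = ["CCO", "OCC", "C1CC", "CCC", ""]
        train = {"CCO"}
        validity, uniqueness, novelty = quality_metrics(generated, train)
        # 3 of 5 parse; CCO==OCC so 2 unique; CCC is novel -> 1 of 2
        assert validity == pytest.approx(60.0)
        assert uniqueness == pytest.approx(100.0 * 2 / 3)
        assert novelty == pytest.approx(50.0)

    def test_no_valid_molecules(self):
        validity, uniqueness, novelty = quality_metrics(["C1CC", ""], set())
        assert validity == 0.0 and uniqueness is None and novelty is None

    def test_empty_generated_rejected(self):
        with pytest.raises(ValueError):
            quality_metrics([], set())

    def test_uniqueness_at_k(self):
        generated = ["CCO", "bad", "OCC", "CCC"]
        assert uniqueness_at_k(generated, 2) == pytest.approx(50.0)
        assert uniqueness_at_k(generated, 3) == pytest.approx(100.0 * 2 / 3)
        assert uniqueness_at_k(["bad"], 5) is None


class TestPropertyProfile:
    def test_columns_and_skips(self):
        df = property_profile(["CCO", "C1CC", "c1ccccc1O"])
        assert list(df.columns) == ["smiles", *PROPERTY_COLUMNS]
        assert len(df) == 2
        assert df.attrs["n_skipped"] == 1

    def test_known_values_ethanol(self):
        df = property_profile(["CCO"])
        row = df.iloc[0]
        assert row["mw"] == pytest.approx(46.069, abs=0.01)
        assert row["hbd"] == 1 and row["hba"] == 1
        assert row["rings"] == 0
        assert bool(row["lipinski_pass"])
        assert not bool(row["pains_flag"])
        assert 0.0 <= row["qed"] <= 1.0
        assert 1.0 <= row["sa"] <= 10.0


class TestDistributionDistance:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        ks, kl = distribution_distance(x, list(x))
        assert ks == 0.0 and kl == pytest.approx(0.0, abs=1e-12)

    def test_ks_matches_manual_ecdf(self):
        a = [1.0, 2.0, 3.0]
        b = [2.5, 3.5, 4.5, 5.5]
        ks, _ = distribution_distance(a, b)
        # manual supremum ECDF difference
        pts = sorted(set(a + b))
        sup = max(abs(sum(v <= p for v in a) / 3 - sum(v <= p for v in b) / 4)
                  for p in pts)
        assert ks == pytest.approx(sup, abs=1e-12)

    def test_disjoint_supports_large_finite_kl(self):
        ks, kl = distribution_distance([0.0, 0.1, 0.2], [10.0, 10.1, 10.2])
        assert ks == 1.0
        assert math.isfinite(kl) and kl > 5.0

    def test_constant_samples(self):
        ks, kl = distribution_distance([2.0, 2.0], [2.0, 2.0])
        assert kl == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            distribution_distance([], [1.0])


class TestFrechet:
    def test_identical_sets_zero(self, small_corpus):
        assert frechet_distance(small_corpus[:30], small_corpus[:30]) == \
            pytest.approx(0.0, abs=1e-6)

    def test_matches_univariate_closed_form(self):
        # 1-D featurizer: Frechet distance = (mu1-mu2)^2 + (s1-s2)^2
        def feat(smiles):
            return np.array([[float(len(s))] for s in smiles])

        a = ["C", "CC", "CCC", "CCCC"]
        b = ["CC", "CCC", "CCCC", "CCCCC", "CCCCCC"]
        x = feat(a)[:, 0]
        y = feat(b)[:, 0]
        expect = (x.mean() - y.mean()) ** 2 + (x.std(ddof=1) - y.std(ddof=1)) ** 2
        assert frechet_distance(a, b, featurizer=feat) == pytest.approx(expect, abs=1e-6)

    def test_fcd_resampled_identical_zero(self, small_corpus):
        mean, sd = fcd_resampled(small_corpus, small_corpus, subset_size=30, seed=1)
        assert mean == pytest.approx(0.0, abs=1e-6)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_fcd_subset_size_guard(self, small_corpus):
        with pytest.raises(ValueError):
            fcd_resampled(small_corpus, small_corpus, subset_size=10 ** 6)

    def test_descriptor_embedding_shape(self, small_corpus):
        x = descriptor_embedding(small_corpus[:5])
        assert x.shape == (5, 10)
        assert np.all(np.isfinite(x))


class TestSimilarityMetrics:
    def test_snn_matches_double_loop(self, small_corpus):
        gen, ref = small_corpus[:20], small_corpus[20:50]
        got = snn(gen, ref)
        gf, rf = _oracle_fps(gen), _oracle_fps(ref)
        expect = np.mean([max(DataStructs.TanimotoSimilarity(a, b) for b in rf)
                          for a in gf])
        assert got == pytest.approx(expect, abs=1e-12)

    def test_intdiv_matches_double_loop(self, small_corpus):
        gen = small_corpus[:15]
        fps = _oracle_fps(gen)
        n = len(fps)
        for p in (1, 2):
            acc = sum(DataStructs.TanimotoSimilarity(fps[i], fps[j]) ** p
                      for i in range(n) for j in range(n))
            expect = 1.0 - (acc / n ** 2) ** (1.0 / p)
            assert internal_diversity(gen, p=p) == pytest.approx(expect, abs=1e-12)

    def test_intdiv2_le_intdiv1(self, small_corpus):
        gen = small_corpus[:20]
        assert internal_diversity(gen, p=2) <= internal_diversity(gen, p=1) + 1e-12

    def test_recovery_rate_matches_oracle(self, small_corpus):
        holdout, generated = small_corpus[:10], small_corpus[5:30]
        got = recovery_rate(holdout, generated, threshold=0.6)
        hf, gf = _oracle_fps(holdout), _oracle_fps(generated)
        expect = np.mean([max(DataStructs.TanimotoSimilarity(a, b) for b in gf) >= 0.6
                          for a in hf])
        assert got == pytest.approx(expect, abs=1e-12)

    def test_recovery_rate_bounds(self, small_corpus):
        assert recovery_rate(small_corpus[:5], small_corpus[:5]) == 1.0
        assert recovery_rate(small_corpus[:5], []) == 0.0

    def test_scaffold_recovery(self, ring_corpus):
        assert scaffold_recovery(ring_corpus, ring_corpus) == 1.0
        # acyclic generated set shares only the empty-scaffold sentinel (if present)
        got = scaffold_recovery(ring_corpus, ["CCC"])
        from smilesclm import bemis_murcko_scaffold
        ref_scafs = {bemis_murcko_scaffold(s) for s in ring_corpus}
        assert got == pytest.approx(("" in ref_scafs) / len(ref_scafs))


class TestScaffoldClustering:
    def test_identical_scaffolds_rejected(self):
        with pytest.raises(ValueError):
            scaffold_clusters(["c1ccccc1", "c1ccccc1"])

    def test_single_cluster_sdi_zero(self):
        _, n, sdi = scaffold_clusters(["c1ccccc1"])
        assert n == 1 and sdi == 0.0

    def test_even_clusters_sdi_log2(self):
        # two structurally unrelated scaffolds -> 2 singleton clusters, SDI = 1 bit
        scafs = ["c1ccccc1", "C1CCNCC1"]
        clustering, n, sdi = scaffold_clusters(scafs, threshold=0.9)
        assert n == 2
        assert sdi == pytest.approx(1.0, abs=1e-12)

    def test_empty_sentinel_own_cluster(self):
        clustering, n, sdi = scaffold_clusters(["", "c1ccccc1"])
        assert n == 2
        assert [""] in clustering.clusters

    def test_greedy_assignment_matches_oracle(self, ring_corpus):
        from smilesclm import bemis_murcko_scaffold
        from smilesclm.fingerprints import SCAFFOLD_FP, fingerprints, tanimoto
        scafs = sorted({bemis_murcko_scaffold(s) for s in ring_corpus})
        clustering, n, sdi = scaffold_clusters(scafs, threshold=0.6)
        # oracle: replay greedy first-fit in canonical order
        ordered = canonical_scaffold_order(scafs)
        oracle: list[list[str]] = []
        for s in ordered:
            placed = False
            for c in oracle:
                if s == "" or c[0] == "":
                    continue
                a = fingerprints([s], SCAFFOLD_FP)[0]
                b = fingerprints([c[0]], SCAFFOLD_FP)[0]
                if tanimoto(a, b) >= 0.6:
                    c.append(s)
                    placed = True
                    break
            if not placed:
                oracle.append([s])
        assert clustering.clusters == oracle
        sizes = np.array([len(c) for c in oracle], dtype=float)
        f = sizes / sizes.sum()
        assert sdi == pytest.approx(float(-(f * np.log2(f)).sum()), abs=1e-12)

    def test_canonical_order(self):
        scafs = ["b", "a", "c"]
        assert canonical_scaffold_order(scafs) == ["a", "b", "c"]
        assert canonical_scaffold_order(scafs, {"b": 5, "a": 1, "c": 5}) == \
            ["b", "c", "a"]


class TestChemicalSpaceProjection:
    def test_shapes_and_holdout_transform_only(self, small_corpus):
        from smilesclm import chemical_space_projection
        train, generated, holdout = (small_corpus[:30], small_corpus[30:60],
                                     small_corpus[60:70])
        with pytest.warns(UserWarning):  # n_neighbors reduced for small fit set
            coords = chemical_space_projection(train, generated, holdout,
                                               n_neighbors=100, seed=0)
        assert coords["train"].shape == (30, 2)
        assert coords["generated"].shape == (30, 2)
        assert coords["holdout"].shape == (10, 2)
        assert all(np.all(np.isfinite(v)) for v in coords.values())

    def test_too_few_molecules(self):
        from smilesclm import chemical_space_projection
        with pytest.raises(ValueError):
            chemical_space_projection(["CCO"], ["CCC"])


class TestNpLikeness:
    def test_profile(self, small_corpus):
        g_mean, r_mean, ks = np_likeness_profile(small_corpus[:10], small_corpus[:10])
        assert g_mean == pytest.approx(r_mean)
        assert ks == 0.0
        assert -5.0 <= g_mean <= 5.0


class TestEvaluateGeneration:
    def test_full_panel(self, small_corpus):
        generated = small_corpus[:40] + ["C1CC", ""]
        report = evaluate_generation(generated, small_corpus[20:60],
                                     holdout=small_corpus[60:70], seed=0)
        assert report.validity == pytest.approx(100.0 * 40 / 42)
        assert report.uniqueness == pytest.approx(100.0)
        assert 0.0 <= report.snn <= 1.0
        assert 0.0 <= report.intdiv2 <= report.intdiv1 <= 1.0
        assert report.fcd_mean is not None and report.fcd_mean >= 0.0
        assert report.rr is not None and 0.0 <= report.rr <= 1.0
        assert report.n_distinct_scaffold_clusters >= 1
        assert report.sdi >= 0.0
        for col in ("mw", "logp", "qed", "sa"):
            assert col in report.ks_stats and col in report.kl_divs
        d = report.to_dict()
        assert d["validity"] == report.validity
        assert "validity" in report.table()

    def test_all_invalid(self):
        report = evaluate_generation(["C1CC", "xx"], ["CCO", "CCC"])
        assert report.validity == 0.0
        assert report.snn is None
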