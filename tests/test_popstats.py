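import itertools

import numpy as np
import pandas as pd
import pytest

from conigen.genio import allele_frequencies
from conigen.popstats import (
    diversity_table,
    kinship_screen,
    nei_distance_matrix,
    pairwise_fst,
    pcoa,
    prevosti_distance_matrix,
)
from conigen.simdata import SimulationConfig, simulate_dataset

from conftest import make_matrix, make_popmap


class TestDiversityTable:
    def test_hand_computed_fixture(self):
        # 5 samples x 4 loci (one missing call); expected values frozen
        # from an independent spreadsheet-style per-locus calculation
        g = make_matrix([
            [0, 0, 1, 2],
            [1, 0, 1, 2],
            [2, 0, 1, 1],
            [1, 0, 1, 0],
            [0, 0, 1, None],
        ])
        pm = make_popmap({f"s{i}": ("a", "r") for i in range(1, 6)})
        t = diversity_table(g, pm, min_n=5).table
        assert t.loc["a", "A"] == pytest.approx(1.75, abs=1e-12)
        assert t.loc["a", "A_E"] == pytest.approx(1.7013574660633484, abs=1e-12)
        assert t.loc["a", "H_O"] == pytest.approx(0.4125, abs=1e-12)
        assert t.loc["a", "H_E"] == pytest.approx(0.40615079365079365, abs=1e-12)
        assert t.loc["a", "P_E"] == pytest.approx(0.3621875, abs=1e-12)
        assert t.loc["a", "F_IS"] == pytest.approx(-0.0055555555555555, abs=1e-12)

    def test_all_heterozygous_bound(self):
        g = make_matrix([[1]] * 30)
        pm = make_popmap({f"s{i}": ("a", "r") for i in range(1, 31)})
        t = diversity_table(g, pm, min_n=6).table
        assert t.loc["a", "H_O"] == 1.0
        # F_IS = 1 - (2n-1)/n -> approximately -1 at large n
        assert t.loc["a", "F_IS"] == pytest.approx(1 - 59 / 30, abs=1e-12)
        assert t.loc["a", "F_IS"] < -0.9

    def test_monomorphic_locus_excluded_from_fis(self):
        g = make_matrix([[0, 1], [0, 1], [0, 0], [0, 1], [0, 2], [0, 0]])
        pm = make_popmap({f"s{i}": ("a", "r") for i in range(1, 7)})
        t = diversity_table(g, pm).table
        # monomorphic locus: A=1, contributes 0 to H_O/H_E, skipped in F_IS
        assert t.loc["a", "A"] == 1.5
        he2 = (12 / 11) * 2 * (5 / 12) * (7 / 12)
        assert t.loc["a", "F_IS"] == pytest.approx(1 - 0.5 / he2, abs=1e-12)

    def test_small_population_excluded(self, two_lineage_dataset):
        g, pm, _ = two_lineage_dataset
        t = diversity_table(g, pm, min_n=11)
        assert set(t.excluded) == {"pop2", "pop3"}  # n = 10 and 6
        assert set(t.table.index) == {"pop1", "pop4"}

    def test_biallelic_bounds(self, two_lineage_dataset):
        g, pm, _ = two_lineage_dataset
        t = diversity_table(g, pm).table
        assert ((t["A"] >= 1) & (t["A"] <= 2)).all()
        assert (t["A_E"] <= t["A"] + 1e-12).all()
        assert ((t["H_O"] >= 0) & (t["H_O"] <= 1)).all()
        assert ((t["F_IS"] >= -1) & (t["F_IS"] <= 1)).all()


class TestPairwiseFst:
    def test_fixed_differences_reach_one(self):
        g = make_matrix([[0, 0]] * 5 + [[2, 2]] * 5)
        pm = make_popmap({f"s{i}": ("a" if i <= 5 else "b", "r") for i in range(1, 11)})
        d = pairwise_fst(g, pm, n_perm=0)
        assert d.fst.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)
        assert d.gst_hedrick.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(0)
        dosage = rng.binomial(2, 0.3, size=(40, 800)).astype(float)
        pm = make_popmap({f"s{i}": ("a" if i <= 20 else "b", "r") for i in range(1, 41)})
        g = make_matrix(dosage)
        d = pairwise_fst(g, pm, n_perm=0)
        assert abs(d.fst.loc["a", "b"]) < 0.02  # may be slightly negative

    def test_three_locus_fixture_matches_frozen_oracle(self):
        """Locus-by-locus plain-Python Nei-Chesser computation, frozen."""
        a = np.array([[0, 1, 2], [1, 1, 2], [2, 0, 2], [2, 2, 1]], float)
        b = np.array([[0, 2, 0], [0, 1, 1], [1, 1, 0]], float)
        g = make_matrix(np.vstack([a, b]))
        pm = make_popmap({f"s{i}": ("a" if i <= 4 else "b", "r") for i in range(1, 8)})
        d = pairwise_fst(g, pm, n_perm=0)
        assert d.fst.loc["a", "b"] == pytest.approx(0.288770053475936, abs=1e-12)
        assert d.gst_hedrick.loc["a", "b"] == pytest.approx(0.792651044539851, abs=1e-12)

    def test_gst_exceeds_fst_and_symmetry(self, two_lineage_dataset):
        g, pm, _ = two_lineage_dataset
        d = pairwise_fst(g, pm, n_perm=0)
        f, h = d.fst.to_numpy(), d.gst_hedrick.to_numpy()
        assert np.allclose(f, f.T) and np.allclose(h, h.T)
        assert np.all(np.diag(f) == 0)
        off = ~np.eye(f.shape[0], dtype=bool)
        assert np.all(h[off] >= f[off] - 1e-9)
        assert np.all(f[off] <= 1) and np.all(h[off] <= 1 + 1e-9)

    def test_permutation_p_for_strong_differentiation(self):
        rng = np.random.default_rng(1)
        da = rng.binomial(2, 0.05, size=(12, 300)).astype(float)
        db = rng.binomial(2, 0.95, size=(12, 300)).astype(float)
        g = make_matrix(np.vstack([da, db]))
        pm = make_popmap({f"s{i}": ("a" if i <= 12 else "b", "r") for i in range(1, 25)})
        d = pairwise_fst(g, pm, n_perm=99, seed=0)
        assert d.p_value.loc["a", "b"] == pytest.approx(1 / 100)

    def test_undefined_for_tiny_population(self):
        g = make_matrix([[0, 1], [2, 1], [1, 0]])
        pm = make_popmap({"s1": ("a", "r"), "s2": ("a", "r"), "s3": ("b", "r")})
        d = pairwise_fst(g, pm, n_perm=0)
        assert np.isnan(d.fst.loc["a", "b"])


class TestKinship:
    def test_duplicated_sample_near_half(self):
        rng = np.random.default_rng(3)
        base = rng.binomial(2, rng.uniform(0.1, 0.5, 2000), size=(10, 2000)).astype(float)
        dosage = np.vstack([base, base[0]])  # planted self-duplicate
        pm = make_popmap({f"s{i}": ("a", "r") for i in range(1, 12)})
        res = kinship_screen(make_matrix(dosage), pm, threshold=0.125)
        dup = res.pairs[(res.pairs.sample_a == "s1") & (res.pairs.sample_b == "s11")]
        assert dup.kinship.iloc[0] == pytest.approx(0.5, abs=0.05)
        assert dup.flagged.iloc[0]

    def test_parent_offspring_detection(self):
        cfg = SimulationConfig(n_loci=5000, n_kin_pairs=2, missing_rate=0.0, seed=21)
        g, pm, _ = simulate_dataset(cfg)
        res = kinship_screen(g, pm, threshold=0.125)
        planted = {tuple(sorted((c, p))) for c, p1, p2 in pm.kin_pairs for p in (p1, p2)}
        found = {tuple(sorted((r.sample_a, r.sample_b)))
                 for r in res.flagged_pairs.itertuples()}
        assert planted <= found
        po = res.pairs[res.pairs.apply(
            lambda r: tuple(sorted((r.sample_a, r.sample_b))) in planted, axis=1)]
        assert np.all(np.abs(po.kinship - 0.25) < 0.05)
        # unrelated pairs stay near zero
        unrel = res.pairs[~res.pairs.apply(
            lambda r: tuple(sorted((r.sample_a, r.sample_b))) in planted, axis=1)]
        assert np.quantile(np.abs(unrel.kinship), 0.95) < 0.05

    def test_pruning_removes_one_member_per_pair(self):
        cfg = SimulationConfig(n_loci=3000, n_kin_pairs=1, missing_rate=0.0, seed=5)
        g, pm, _ = simulate_dataset(cfg)
        res = kinship_screen(g, pm)
        for r in res.flagged_pairs.itertuples():
            assert (r.sample_a in res.pruned_samples) or (r.sample_b in res.pruned_samples)

    def test_singleton_population_empty(self):
        g = make_matrix([[0, 1]])
        pm = make_popmap({"s1": ("a", "r")})
        assert kinship_screen(g, pm).pairs.empty


class TestDistancesAndPcoa:
    def test_nei_distance_two_pop_frozen(self):
        freq = pd.DataFrame([[0.2, 0.5, 0.9], [0.1, 0.6, 0.7]],
                            index=["a", "b"], columns=["L1", "L2", "L3"])
        D = nei_distance_matrix(freq)
        assert D.loc["a", "b"] == pytest.approx(0.030882297127423, abs=1e-12)
        assert D.loc["a", "a"] == 0.0

    def test_prevosti_simple(self):
        g = make_matrix([[0, 2, 1], [2, 2, 0]])
        D = prevosti_distance_matrix(g)
        assert D.iloc[0, 1] == pytest.approx((1 + 0 + 0.5) / 3)

    def test_collinear_populations_single_axis(self):
        # three populations with frequencies on a line in allele space
        freq = pd.DataFrame({"L1": [0.1, 0.3, 0.5], "L2": [0.1, 0.3, 0.5]},
                            index=["a", "b", "c"])
        # Euclidean distances between the rows are collinear
        from scipy.spatial.distance import squareform, pdist
        D = pd.DataFrame(squareform(pdist(freq)), index=freq.index, columns=freq.index)
        ord_ = pcoa(D)
        assert ord_.percent_variance[0] == pytest.approx(100.0, abs=1e-6)

    def test_identical_populations_degenerate(self):
        D = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        ord_ = pcoa(D)
        assert ord_.degenerate

    def test_embedding_round_trip(self, two_lineage_dataset):
        g, pm, _ = two_lineage_dataset
        freq, _ = allele_frequencies(g, pm)
        D = nei_distance_matrix(freq)
        ord_ = pcoa(D, level="population", distance_name="nei_population")
        # for a Euclidean-embeddable matrix the coordinates reproduce it
        X = ord_.coordinates.to_numpy()
        recon = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        assert np.allclose(recon, D.to_numpy(), atol=1e-9)
        pct = ord_.percent_variance
        assert np.all(np.diff(pct) <= 1e-9) and pct.sum() <= 100 + 1e-9
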