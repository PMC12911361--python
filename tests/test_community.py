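"""Dissimilarity, ordination and permutation statistics."""

import numpy as np
import pandas as pd
import pytest

from planktonet import community as cm
from planktonet import data_model as dm


def _dissim(values, ids=None):
    values = np.asarray(values, dtype=float)
    return cm.DissimilarityMatrix(ids or list(range(len(values))), values)


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

class TestBrayCurtis:
    def test_matches_brute_force_double_loop(self, rng):
        X = rng.integers(0, 50, size=(20, 15)).astype(float) + 0.5
        D = cm.bray_curtis_matrix(X).values
        for i in range(20):
            for j in range(20):
                expected = np.abs(X[i] - X[j]).sum() / (X[i] + X[j]).sum()
                assert abs(D[i, j] - expected) < 1e-12

    def test_identity_disjoint_and_worked_example(self):
        D = cm.bray_curtis_matrix(np.array([
            [2.0, 2.0, 0.0], [1.0, 3.0, 0.0], [0.0, 0.0, 5.0]]))
        assert D.values[0, 0] == 0.0
        assert D.values[0, 2] == 1.0  # disjoint supports
        assert abs(D.values[0, 1] - 0.25) < 1e-12  # (2,2) vs (1,3)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            cm.bray_curtis_matrix(np.array([[1.0, 2.0], [0.0, 0.0]]))

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0.0, 0.4], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            _dissim(bad)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

class TestNmds:
    def test_perfect_planar_configuration_has_low_stress(self, rng):
        pts = rng.normal(size=(8, 2))
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(pts))
        D = _dissim(D / D.max())
        res = cm.nmds_embed(D, k=2, seed=0)
        assert res.stress < 0.01

    def test_full_dimensional_embedding_is_nearly_exact(self, rng):
        X = rng.random((5, 6)) + 0.1
        D = cm.bray_curtis_matrix(X)
        res = cm.nmds_embed(D, k=4, seed=0)
        assert res.stress < 0.02

    def test_duplicated_samples_map_to_coincident_points(self, rng):
        X = rng.random((6, 8)) + 0.1
        X = np.vstack([X, X[0]])  # sample 6 duplicates sample 0
        D = cm.bray_curtis_matrix(X)
        res = cm.nmds_embed(D, k=2, seed=0)
        gap = np.linalg.norm(res.coordinates.iloc[0] - res.coordinates.iloc[6])
        assert gap < 1e-4 * np.abs(res.coordinates.to_numpy()).max()

    def test_stress_not_worse_than_classical_scaling_start(self, rng):
        X = rng.random((12, 10)) + 0.05
        D = cm.bray_curtis_matrix(X)
        init_stress = cm.kruskal_stress(D, cm.classical_scaling(D, 2))
        res = cm.nmds_embed(D, k=2, seed=3)
        assert res.stress <= init_stress + 1e-9

    def test_k_must_be_smaller_than_n(self):
        D = _dissim(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            cm.nmds_embed(D, k=3)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

class TestAnosim:
    def _separated(self):
        # within-group distances all below between-group distances
        D = np.array([
            [0.0, 0.1, 0.9, 0.8],
            [0.1, 0.0, 0.85, 0.95],
            [0.9, 0.85, 0.0, 0.2],
            [0.8, 0.95, 0.2, 0.0],
        ])
        return _dissim(D), np.array(["x", "x", "y", "y"])

    def test_perfect_separation_gives_r_one(self):
        D, g = self._separated()
        res = cm.anosim(D, g, n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value >= 1 / 100

    def test_singleton_group_rejected(self):
        D, _ = self._separated()
        with pytest.raises(ValueError, match="size 1"):
            cm.anosim(D, np.array(["x", "x", "x", "y"]))

    def test_statistic_invariant_to_sample_relabeling(self, rng):
        X = rng.random((10, 6)) + 0.1
        D = cm.bray_curtis_matrix(X)
        g = np.array(["a"] * 5 + ["b"] * 5)
        base = cm.anosim(D, g, n_permutations=199, seed=1)
        perm = rng.permutation(10)
        D2 = _dissim(D.values[np.ix_(perm, perm)])
        res = cm.anosim(D2, g[perm], n_permutations=199, seed=1)
        assert res.statistic == pytest.approx(base.statistic, abs=1e-12)

    def test_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as skbio_anosim

        X = rng.random((12, 8)) + 0.1
        D = cm.bray_curtis_matrix(X)
        g = ["a"] * 6 + ["b"] * 6
        ours = cm.anosim(D, np.array(g), n_permutations=99, seed=0)
        theirs = skbio_anosim(skbio.DistanceMatrix(D.values), grouping=g,
                              permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"], abs=1e-10)


# ---------------------------------------------------------------------------
# EnvFit
# ---------------------------------------------------------------------------

class TestEnvfit:
    def test_variable_equal_to_axis_one(self, rng):
        coords = rng.normal(size=(20, 2))
        res = cm.envfit(coords, coords[:, 0], n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        np.testing.assert_allclose(np.abs(res.extras["arrow"]), [1.0, 0.0], atol=1e-8)

    def test_r2_invariant_to_rotation(self, rng):
        coords = rng.normal(size=(25, 2))
        y = coords @ [0.3, -0.7] + rng.normal(scale=0.5, size=25)
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        r2_a = cm.envfit(coords, y, n_permutations=9, seed=0).statistic
        r2_b = cm.envfit(coords @ R, y, n_permutations=9, seed=0).statistic
        assert r2_a == pytest.approx(r2_b, abs=1e-10)

    def test_constant_variable_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            cm.envfit(rng.normal(size=(10, 2)), np.ones(10))


# ---------------------------------------------------------------------------
# Persistence subset vs whole
# ---------------------------------------------------------------------------

def _persistence(asv_ids, persistent):
    labels = pd.Series(
        {a: ("persistent" if a in persistent else "ephemeral") for a in asv_ids})
    return dm.PersistenceLabel(labels=labels)


class TestSubsetVsWhole:
    def test_subset_equal_to_whole_gives_zero(self, tiny_table):
        labels = _persistence(tiny_table.asv_ids, set(tiny_table.asv_ids))
        res = cm.subset_vs_whole_dissimilarity(tiny_table, labels)
        persistent = res["distances"].query("`class` == 'persistent'")
        assert (persistent["distance"] < 1e-12).all()

    def test_dominant_class_sits_near_zero(self):
        # persistent ASVs hold ~99% of every sample's abundance
        data = pd.DataFrame([[990, 9, 1], [495, 500, 5]],
                            index=["s1", "s2"], columns=["p1", "p2", "e1"])
        table = dm.AsvTable(data)
        labels = _persistence(["p1", "p2", "e1"], {"p1", "p2"})
        res = cm.subset_vs_whole_dissimilarity(table, labels)
        summary = res["summary"]
        assert summary.loc["persistent", "mean"] < 0.02
        assert summary.loc["ephemeral", "mean"] > 0.9

    def test_distance_equals_one_minus_share_for_disjoint_classes(self):
        data = pd.DataFrame([[60, 20, 20]], index=["s"], columns=["p1", "e1", "e2"])
        labels = _persistence(["p1", "e1", "e2"], {"p1"})
        res = cm.subset_vs_whole_dissimilarity(dm.AsvTable(data), labels)
        d = res["distances"].set_index("class")["distance"]
        assert d["persistent"] == pytest.approx(0.4)  # 1 - 0.6
        assert d["ephemeral"] == pytest.approx(0.6)  # 1 - 0.4

    def test_complementary_class_distances_sum_to_one(self, rng):
        # classes partition the ASVs, so each class's distance to the whole is
        # exactly 1 minus its abundance share and the pair always sums to 1
        for _ in range(20):
            counts = rng.integers(1, 50, size=(4, 6))
            table = dm.AsvTable(pd.DataFrame(
                counts, index=[f"s{i}" for i in range(4)],
                columns=[f"a{j}" for j in range(6)]))
            labels = _persistence(table.asv_ids, set(table.asv_ids[:3]))
            res = cm.subset_vs_whole_dissimilarity(table, labels)
            wide = res["distances"].pivot(index="sample", columns="class",
                                          values="distance")
            np.testing.assert_allclose(wide.sum(axis=1), 1.0, atol=1e-10)

    def test_empty_class_cells_are_counted_not_fatal(self):
        data = pd.DataFrame([[5, 5]], index=["s"], columns=["p1", "p2"])
        labels = _persistence(["p1", "p2"], {"p1", "p2"})  # no ephemeral ASVs
        res = cm.subset_vs_whole_dissimilarity(dm.AsvTable(data), labels)
        assert res["skipped"] >= 1
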