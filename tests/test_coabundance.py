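"""Soft-thresholded co-abundance networks, TOM, modules and trait tests."""

import numpy as np
import pandas as pd
import pytest

from planktonet import coabundance as ca


def _abund(X, prefix="a"):
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, index=[f"s{i}" for i in range(X.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(X.shape[1])])


def _module_data(rng, n_samples=60, sizes=(20, 20, 20), noise=0.4):
    """Latent-factor module data: members of module m = factor_m + noise."""
    blocks, labels = [], []
    for m, size in enumerate(sizes):
        f = rng.normal(size=n_samples)
        blocks.append(f[:, None] + noise * rng.normal(size=(n_samples, size)))
        labels += [m] * size
    return _abund(np.hstack(blocks)), np.array(labels)


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

class TestBoxCox:
    def test_lambda_one_is_shift_by_one(self, rng):
        y = rng.uniform(1, 5, size=30)
        t, lam, shift = ca.boxcox_transform(y, lmbda=1.0)
        np.testing.assert_allclose(t, y - 1, atol=1e-12)
        assert shift == 0.0

    def test_lognormal_sample_estimates_lambda_near_zero(self, rng):
        y = rng.lognormal(0, 0.8, size=300)
        _, lam, _ = ca.boxcox_transform(y)
        assert abs(lam) < 0.3

    def test_normal_sample_transform_is_nearly_affine(self, rng):
        # for already-normal data the profile likelihood is flat in lambda, so
        # the estimate scatters; the transform must still be ~affine in y
        y = rng.normal(20, 2, size=300)
        t, lam, _ = ca.boxcox_transform(y)
        assert np.corrcoef(t, y)[0, 1] > 0.995

    def test_nonpositive_values_shifted(self):
        t, lam, shift = ca.boxcox_transform(np.array([-1.0, 0.0, 2.0, 5.0]))
        assert shift == 2.0
        assert np.isfinite(t).all()

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ca.boxcox_transform(np.ones(10))


# ---------------------------------------------------------------------------
# Adjacency, soft threshold, TOM
# ---------------------------------------------------------------------------

class TestAdjacency:
    def test_power_one_is_absolute_correlation(self, rng):
        X = _abund(rng.normal(size=(30, 6)))
        A = ca.adjacency_matrix(X, power=1)
        r = np.corrcoef(X.to_numpy(), rowvar=False)
        np.testing.assert_allclose(A.to_numpy(), np.abs(r), atol=1e-12)

    def test_mean_connectivity_decreases_with_power(self, rng):
        X, _ = _module_data(rng)
        report = ca.pick_soft_threshold(X, powers=range(1, 9))
        conns = report.mean_connectivity
        assert all(a >= b for a, b in zip(conns, conns[1:]))

    def test_constant_profile_rejected(self, rng):
        X = _abund(rng.normal(size=(20, 3)))
        X["a2"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            ca.adjacency_matrix(X, power=2)


class TestTopologicalOverlap:
    def test_identity_adjacency_gives_identity(self):
        assert np.allclose(ca.topological_overlap(np.eye(6)), np.eye(6))

    def test_identical_neighbor_profiles_give_overlap_one(self):
        A = np.ones((5, 5))  # every pair shares every neighbor at full weight
        assert np.allclose(ca.topological_overlap(A), 1.0)

    def test_matches_brute_force_triple_loop(self, rng):
        A = rng.uniform(0, 1, size=(15, 15))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = ca.topological_overlap(A)
        k = A.sum(axis=0) - 1
        for i in range(15):
            for j in range(15):
                if i == j:
                    expected = 1.0
                else:
                    shared = sum(A[i, u] * A[u, j] for u in range(15)
                                 if u not in (i, j))
                    expected = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-10)

    def test_entries_bounded(self, rng):
        A = rng.uniform(0, 1, size=(20, 20))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = ca.topological_overlap(A)
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_out_of_range_entries_rejected(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 1.5
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ca.topological_overlap(A)


# ---------------------------------------------------------------------------
# Eigengenes and module detection
# ---------------------------------------------------------------------------

class TestModuleEigengene:
    def test_identical_profiles_recover_standardized_profile(self, rng):
        profile = rng.normal(size=25)
        X = _abund(np.tile(profile[:, None], (1, 4)))
        eg, explained = ca.module_eigengene(X)
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eg.to_numpy(), z, atol=1e-8)
        assert explained == pytest.approx(1.0)

    def test_sign_oriented_toward_members(self, rng):
        for _ in range(5):
            X = _abund(rng.normal(size=(30, 6)))
            eg, _ = ca.module_eigengene(X)
            Z = (X - X.mean()) / X.std()
            mean_cor = np.mean([np.corrcoef(eg, Z[c])[0, 1] for c in X.columns])
            assert mean_cor > 0

    def test_explained_variance_at_least_average_share(self, rng):
        X, _ = _module_data(rng, sizes=(8,))
        _, explained = ca.module_eigengene(X)
        assert explained >= 1 / X.shape[1]


class TestDetectModules:
    def test_recovers_planted_modules(self, rng):
        from sklearn.metrics import adjusted_rand_score

        X, truth = _module_data(rng, sizes=(18, 15, 12))
        A = ca.adjacency_matrix(X, power=6)
        part = ca.detect_modules(ca.topological_overlap(A), X)
        ari = adjusted_rand_score(truth, part.labels.to_numpy())
        assert ari >= 0.8

    def test_identical_planted_modules_are_merged(self, rng):
        f = rng.normal(size=50)
        X = _abund(f[:, None] + 0.3 * rng.normal(size=(50, 24)))
        A = ca.adjacency_matrix(X, power=6)
        part = ca.detect_modules(ca.topological_overlap(A), X, merge_threshold=0.25)
        assert len(part.modules()) == 1

    def test_noise_data_mostly_unassigned(self, rng):
        X = _abund(rng.normal(size=(40, 60)))
        A = ca.adjacency_matrix(X, power=6)
        part = ca.detect_modules(ca.topological_overlap(A), X, on_empty="keep")
        assert part.n_unassigned > 30

    def test_all_unassigned_raises_by_default(self, rng):
        X = _abund(rng.normal(size=(40, 20)))
        A = ca.adjacency_matrix(X, power=6)
        tom = ca.topological_overlap(A)
        try:
            part = ca.detect_modules(tom, X)
            assert len(part.modules()) > 0  # if it didn't raise, it found one
        except ValueError as err:
            assert "min_module_size" in str(err)

    def test_partition_invariant_to_asv_order(self, rng):
        X, _ = _module_data(rng, sizes=(15, 12))
        A = ca.adjacency_matrix(X, power=6)
        part = ca.detect_modules(ca.topological_overlap(A), X)
        cols = list(rng.permutation(X.columns))
        Xp = X[cols]
        Ap = ca.adjacency_matrix(Xp, power=6)
        part_p = ca.detect_modules(ca.topological_overlap(Ap), Xp)
        # same sets of members per module, regardless of input order
        sets_a = sorted(frozenset(part.members(m)) for m in part.modules())
        sets_b = sorted(frozenset(part_p.members(m)) for m in part_p.modules())
        assert sets_a == sets_b


class TestModuleTrait:
    def _partition(self, rng):
        X, _ = _module_data(rng, sizes=(15, 15))
        A = ca.adjacency_matrix(X, power=6)
        return X, ca.detect_modules(ca.topological_overlap(A), X)

    def test_planted_trait_recovered(self, rng):
        X, part = self._partition(rng)
        module = part.modules()[0]
        trait = part.eigengenes[module] + 0.1 * rng.normal(size=len(X))
        trait = pd.DataFrame({"NCP": 10 + 2 * trait})
        mt = ca.module_trait_correlation(part, trait, transform=False)
        row = mt[(mt["module"] == module)].iloc[0]
        assert row["r"] > 0.9 and row["p"] < 1e-3

    def test_correlation_invariant_to_affine_trait_rescaling(self, rng):
        X, part = self._partition(rng)
        trait = pd.DataFrame({"POC": rng.normal(size=len(X)) + 5}, index=X.index)
        base = ca.module_trait_correlation(part, trait, transform=False)
        scaled = ca.module_trait_correlation(part, 3.0 * trait + 11.0,
                                             transform=False)
        np.testing.assert_allclose(base["r"], scaled["r"], atol=1e-10)

    def test_too_few_paired_observations_marked_na(self, rng):
        X, part = self._partition(rng)
        trait = pd.DataFrame({"PON": [1.0, 2.0] + [np.nan] * (len(X) - 2)},
                             index=X.index)
        mt = ca.module_trait_correlation(part, trait, transform=False)
        assert mt["r"].isna().all()


class TestPowerStability:
    def test_identical_data_identical_power_gives_jaccard_one(self, rng):
        X, _ = _module_data(rng, sizes=(15, 15))
        stab = ca.module_power_stability(X, powers=[4, 6], reference_power=6)
        ref_rows = stab[stab["power"] == 6]
        assert (ref_rows["jaccard"] == 1.0).all()

    def test_strong_modules_stable_across_powers(self, rng):
        X, _ = _module_data(rng, sizes=(18, 18), noise=0.3)
        stab = ca.module_power_stability(X, powers=range(1, 9), reference_power=6)
        assert stab["jaccard"].min() >= 0.8

    def test_requires_two_powers(self, rng):
        X, _ = _module_data(rng, sizes=(10, 10))
        with pytest.raises(ValueError, match=">= 2"):
            ca.module_power_stability(X, powers=[5])
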