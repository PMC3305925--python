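import numpy as np
import pytest

from mbopls.datatypes import (
    DataError,
    OmicsBlock,
    PopulationMembership,
    TraitVector,
)
from mbopls.preprocessing import (
    correct_population_structure,
    filter_missing,
    impute_missing,
    inverse_unit_variance_scale,
    log2_transform,
    nipals_pca,
    nipals_pca_matrix,
    summarize_annotated_peaks,
    unit_variance_scale,
)

from .conftest import make_block


class TestLog2Transform:
    def test_power_of_two(self):
        b = make_block([[8.0], [2.0], [1.0]])
        out = log2_transform(b)
        assert out.values[0, 0] == 3
        assert out.values[2, 0] == 0

    def test_offset_matches_independent_log(self):
        b = make_block([[5.0], [3.0], [7.0]])
        out = log2_transform(b, offset=1.0)
        import math
        assert out.values[0, 0] == pytest.approx(math.log(6) / math.log(2))
        assert out.values[0, 0] == pytest.approx(2.584962500721156)

    def test_preserves_missing(self):
        b = make_block([[4.0, np.nan], [2.0, 1.0], [1.0, 2.0]])
        out = log2_transform(b)
        assert np.isnan(out.values[0, 1])
        assert out.values[1, 1] == 0

    def test_nonpositive_names_feature(self):
        b = make_block([[1.0, -2.0], [2.0, 3.0]])
        with pytest.raises(DataError, match="f2"):
            log2_transform(b)


class TestUnitVarianceScale:
    def test_symmetric_column(self):
        b = make_block([[1.0], [2.0], [3.0]])
        out, centers, scales = unit_variance_scale(b)
        np.testing.assert_allclose(out.values[:, 0], [-1, 0, 1])
        assert centers[0] == 2 and scales[0] == 1

    def test_zero_variance_errors(self):
        b = make_block([[10.0], [10.0], [10.0]])
        with pytest.raises(DataError, match="zero-variance"):
            unit_variance_scale(b)

    def test_missing_column_hand_computed(self):
        # mean over {2,4,6} is 4, sample sd is 2
        b = make_block([[2.0], [np.nan], [4.0], [6.0]])
        out, centers, scales = unit_variance_scale(b)
        assert centers[0] == pytest.approx(4)
        assert scales[0] == pytest.approx(2)
        np.testing.assert_allclose(out.values[[0, 2, 3], 0], [-1, 0, 1])
        assert np.isnan(out.values[1, 0])

    def test_scaled_columns_standardized(self, rng):
        b = make_block(rng.normal(5, 3, size=(30, 8)))
        out, _, _ = unit_variance_scale(b)
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(out.values.var(axis=0, ddof=1), 1, atol=1e-10)

    def test_inverse_round_trip(self, rng):
        vals = rng.normal(2, 5, size=(20, 6))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        vals[0] = 1.0  # keep every column with >=2 observed
        vals[1] = 2.0
        b = make_block(vals)
        out, centers, scales = unit_variance_scale(b)
        back = inverse_unit_variance_scale(out, centers, scales)
        obs = ~np.isnan(vals)
        np.testing.assert_allclose(back.values[obs], vals[obs], atol=1e-10)


class TestFilterMissing:
    def test_boundary_is_kept(self):
        vals = np.ones((10, 1))
        vals[:3, 0] = np.nan
        out = filter_missing(make_block(vals), 0.3)
        assert out.n_features == 1

    def test_above_boundary_dropped(self):
        vals = np.ones((10, 1))
        vals[:4, 0] = np.nan
        out = filter_missing(make_block(vals), 0.3)
        assert out.n_features == 0

    def test_matches_recount_oracle(self, rng):
        vals = rng.normal(size=(15, 20))
        vals[rng.random(vals.shape) < 0.35] = np.nan
        b = make_block(vals)
        out = filter_missing(b, 0.3)
        expected = [b.feature_ids[j] for j in range(20)
                    if sum(np.isnan(vals[i, j]) for i in range(15)) / 15 <= 0.3]
        assert out.feature_ids == expected

    def test_never_removes_complete_feature(self, rng):
        vals = rng.normal(size=(12, 10))
        vals[rng.random(vals.shape) < 0.5] = np.nan
        vals[:, 3] = 1.0
        out = filter_missing(make_block(vals), 0.3)
        assert "f4" in out.feature_ids


class TestImputeMissing:
    def test_column_mean(self):
        b = make_block([[1.0], [np.nan], [3.0]])
        out = impute_missing(b)
        assert out.values[1, 0] == 2.0

    def test_all_missing_errors(self):
        b = make_block([[np.nan], [np.nan]])
        with pytest.raises(DataError):
            impute_missing(b)


class TestSummarizeAnnotatedPeaks:
    def _annotated(self, vals, anns, prefix="f"):
        b = make_block(vals, feature_prefix=prefix)
        b.annotations = {f"{prefix}{j + 1}": a for j, a in enumerate(anns)
                         if a is not None}
        return b

    def test_duplicate_collapse(self, rng):
        x = rng.normal(size=20)
        b = self._annotated(np.column_stack([x, x]), ["met1", "met1"])
        out, prov = summarize_annotated_peaks([b], 0.5)
        assert out.n_features == 1
        assert prov["met1"] == ["f1", "f2"]
        r = np.corrcoef(out.values[:, 0], x)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)
        assert r > 0  # sign-oriented with the group mean profile

    def test_uncorrelated_same_annotation_kept_separate(self, rng):
        a, b_ = rng.normal(size=(2, 50))
        blk = self._annotated(np.column_stack([a, b_]), ["met1", "met1"])
        out, prov = summarize_annotated_peaks([blk], 0.5)
        assert out.n_features == 2
        assert prov == {}

    def test_collinear_features_recover_latent(self, rng):
        t = rng.normal(size=40)
        vals = np.column_stack([2 * t, -3 * t, 0.5 * t, rng.normal(size=40)])
        blk = self._annotated(vals, ["m", "m", "m", None])
        out, prov = summarize_annotated_peaks([blk], 0.5)
        assert out.n_features == 2
        assert sorted(prov["m"]) == ["f1", "f2", "f3"]
        merged = out.values[:, out.feature_ids.index("m")]
        assert abs(np.corrcoef(merged, t)[0, 1]) > 0.999

    def test_sample_count_preserved_and_features_never_grow(self, rng):
        vals = rng.normal(size=(15, 6))
        blk = self._annotated(vals, ["a", "a", "b", "b", None, None])
        out, _ = summarize_annotated_peaks([blk], -1.0)
        assert out.n_samples == 15
        assert out.n_features <= 6

    def test_mismatched_samples_error(self, rng):
        b1 = make_block(rng.normal(size=(5, 2)))
        b2 = make_block(rng.normal(size=(5, 2)), sample_prefix="x",
                        feature_prefix="g")
        with pytest.raises(DataError):
            summarize_annotated_peaks([b1, b2], 0.5)

    def test_concatenates_blocks(self, rng):
        b1 = make_block(rng.normal(size=(8, 3)))
        b2 = make_block(rng.normal(size=(8, 2)), feature_prefix="g")
        out, _ = summarize_annotated_peaks([b1, b2], 0.5)
        assert out.feature_ids == ["f1", "f2", "f3", "g1", "g2"]


class TestCorrectPopulationStructure:
    def test_intercept_only_removes_mean(self):
        q = PopulationMembership(["s1", "s2", "s3"], np.ones((3, 1)))
        tr = TraitVector(["s1", "s2", "s3"], [1.0, 2.0, 3.0])
        out = correct_population_structure(tr, q)
        np.testing.assert_allclose(out.values, [-1, 0, 1], atol=1e-12)
        assert out.corrected

    def test_idempotent(self, rng):
        n = 12
        qm = rng.dirichlet([1, 1, 1], size=n)
        ids = [f"s{i}" for i in range(n)]
        q = PopulationMembership(ids, qm)
        tr = TraitVector(ids, rng.normal(size=n))
        once = correct_population_structure(tr, q)
        twice = correct_population_structure(once, q)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_hard_groups_match_normal_equations(self, rng):
        n = 30
        g = rng.integers(0, 3, size=n)
        qm = np.eye(3)[g]
        ids = [f"s{i}" for i in range(n)]
        z = np.array([0.0, 5.0, -2.0])[g] + rng.normal(0, 0.3, size=n)
        out = correct_population_structure(
            TraitVector(ids, z), PopulationMembership(ids, qm))
        for k in range(3):
            assert abs(out.values[g == k].mean()) < 1e-8
        # independent normal-equations solver
        beta = np.linalg.solve(qm.T @ qm, qm.T @ z)
        np.testing.assert_allclose(out.values, z - qm @ beta, atol=1e-8)

    def test_residual_orthogonal_to_q(self, rng):
        n = 25
        qm = rng.dirichlet([0.5] * 4, size=n)
        ids = [f"s{i}" for i in range(n)]
        tr = TraitVector(ids, rng.normal(size=n))
        out = correct_population_structure(tr, PopulationMembership(ids, qm))
        np.testing.assert_allclose(qm.T @ out.values, 0, atol=1e-8)

    def test_missing_trait_values_preserved(self, rng):
        ids = ["a", "b", "c", "d", "e"]
        q = PopulationMembership(ids, np.ones((5, 1)))
        tr = TraitVector(ids, [1.0, np.nan, 2.0, 3.0, np.nan])
        out = correct_population_structure(tr, q)
        assert np.isnan(out.values[[1, 4]]).all()
        np.testing.assert_allclose(out.values[[0, 2, 3]], [-1, 0, 1], atol=1e-12)

    def test_too_few_samples_error(self):
        ids = ["a", "b"]
        q = PopulationMembership(ids, np.column_stack([np.ones(2) / 3] * 3))
        tr = TraitVector(ids, [1.0, np.nan])
        with pytest.raises(DataError):
            correct_population_structure(tr, q)


class TestNipalsPca:
    def test_rank_one_exact(self, rng):
        t = rng.normal(size=20)
        p = rng.normal(size=6)
        X = np.outer(t, p)
        res = nipals_pca_matrix(X, 1)
        tc = t - t.mean()
        assert abs(np.corrcoef(res.scores[:, 0], tc)[0, 1]) > 1 - 1e-10
        assert res.r2[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_svd_on_complete_data(self, rng):
        X = rng.normal(size=(25, 8))
        res = nipals_pca_matrix(X, 3)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        for k in range(3):
            assert abs(np.corrcoef(res.scores[:, k], U[:, k] * s[k])[0, 1]) > 0.9999
            assert abs(res.loadings[:, k] @ Vt[k]) > 0.9999
        np.testing.assert_allclose(res.r2[:3], s[:3] ** 2 / np.sum(s ** 2),
                                   atol=1e-6)

    def test_missing_cells_recovery(self, rng):
        t = rng.normal(size=60)
        p = rng.normal(size=15)
        X = np.outer(t, p) + 0.01 * rng.normal(size=(60, 15))
        X[rng.random(X.shape) < 0.1] = np.nan
        res = nipals_pca_matrix(X, 1)
        assert abs(np.corrcoef(res.loadings[:, 0], p)[0, 1]) > 0.99

    def test_all_missing_column_errors(self):
        X = np.ones((5, 2))
        X[:, 1] = np.nan
        with pytest.raises(DataError):
            nipals_pca_matrix(X, 1)

    def test_block_wrapper(self, rng):
        b = make_block(rng.normal(size=(10, 4)))
        res = nipals_pca(b, 2)
        assert res.scores.shape == (10, 2)
        np.testing.assert_allclose(np.linalg.norm(res.loadings, axis=0), 1,
                                   atol=1e-8)
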