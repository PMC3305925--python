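import itertools

import numpy as np
import pytest

from mbopls.feature_selection import (
    bh_fdr,
    bootstrap_loadings,
    log_b_score,
    null_loadings,
    observed_loadings,
    score_features,
    spearman_screen,
)

from .conftest import scale_matrix


@pytest.fixture
def signal_block(rng):
    """n=40, 30 features, the first 5 informative."""
    n, p, k = 40, 30, 5
    t = rng.normal(size=n)
    X = 0.3 * rng.normal(size=(n, p))
    X[:, :k] += np.outer(t, 1.0 + rng.random(k))
    y = t + 0.2 * rng.normal(size=n)
    return [scale_matrix(X)], y - y.mean()


class TestBootstrapLoadings:
    def test_degenerate_signal_tight(self, rng):
        n = 30
        y = rng.normal(size=n)
        y -= y.mean()
        X = np.column_stack([y, y * 2.0, -y])
        boot = bootstrap_loadings([scale_matrix(X)], y, [0], 0, n_boot=60,
                                  seed=1)
        assert np.nanstd(np.abs(boot[:, 0])) < 0.01
        assert np.nanmean(np.abs(boot[:, 0])) > 0.99

    def test_determinism(self, signal_block):
        blocks, y = signal_block
        a = bootstrap_loadings(blocks, y, [0], 0, n_boot=20, seed=5)
        b = bootstrap_loadings(blocks, y, [0], 0, n_boot=20, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_bootstrap_mean_near_observed(self, signal_block):
        blocks, y = signal_block
        obs = observed_loadings(blocks, y, [0], 0)
        boot = bootstrap_loadings(blocks, y, [0], 0, n_boot=100, seed=2)
        informative = np.abs(obs) > 0.5
        assert np.all(np.abs(np.nanmean(boot[:, informative], axis=0)
                             - obs[informative]) < 0.1)

    def test_shape(self, signal_block):
        blocks, y = signal_block
        boot = bootstrap_loadings(blocks, y, [0], 0, n_boot=15, seed=0)
        assert boot.shape == (15, blocks[0].shape[1])


class TestNullLoadings:
    def test_null_mean_near_zero(self, signal_block):
        blocks, y = signal_block
        null = null_loadings(blocks, y, [0], 0, n_null=100, seed=3)
        m = np.nanmean(null, axis=0)
        s = np.nanstd(null, axis=0)
        assert np.all(np.abs(m) < 3 * s / np.sqrt(100) + 0.05)

    def test_determinism(self, signal_block):
        blocks, y = signal_block
        a = null_loadings(blocks, y, [0], 0, n_null=10, seed=4)
        b = null_loadings(blocks, y, [0], 0, n_null=10, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_null_approximately_symmetric(self, rng):
        X = scale_matrix(rng.normal(size=(40, 10)))
        y = rng.normal(size=40)
        y -= y.mean()
        null = null_loadings([X], y, [0], 0, n_null=300, seed=6)
        from scipy import stats
        assert abs(stats.skew(null[:, 0])) < 0.5


class TestLogBScore:
    def test_equal_density_formula(self):
        # identical sample sets -> equal densities at any point
        samples = np.array([-0.2, -0.1, 0.0, 0.1, 0.2])
        b, log_b = log_b_score(0.0, samples, samples, prior_h0=0.95)
        assert b == pytest.approx(0.05, abs=1e-9)
        assert log_b == pytest.approx(np.log(0.05 / 0.95), abs=1e-6)
        assert log_b == pytest.approx(-2.9444, abs=1e-3)

    def test_strong_signal_limit(self, rng):
        boot = 0.95 + 0.01 * rng.normal(size=200)
        null = 0.01 * rng.normal(size=200)
        b, log_b = log_b_score(0.95, boot, null, prior_h0=0.95)
        assert b > 0.99
        assert log_b > 0

    def test_sign_iff_b_above_half(self, rng):
        for _ in range(10):
            boot = rng.normal(rng.uniform(-0.5, 0.5), 0.1, size=80)
            null = rng.normal(0, 0.2, size=80)
            b, log_b = log_b_score(float(np.mean(boot)), boot, null)
            assert (log_b > 0) == (b > 0.5)
            assert 0 <= b <= 1

    def test_monotone_in_prior_limits(self, rng):
        boot = rng.normal(0.5, 0.1, size=100)
        null = rng.normal(0.0, 0.2, size=100)
        b_lo, _ = log_b_score(0.5, boot, null, prior_h0=1e-6)
        b_hi, _ = log_b_score(0.5, boot, null, prior_h0=1 - 1e-6)
        assert b_lo > 1 - 1e-3
        assert b_hi < 1e-3

    def test_monotone_in_densities(self):
        # shifting the null density mass away from the evaluation point
        # raises the score
        boot = np.linspace(0.4, 0.6, 50)
        null_near = np.linspace(0.3, 0.7, 50)
        null_far = np.linspace(-0.7, -0.3, 50)
        _, lb_near = log_b_score(0.5, boot, null_near)
        _, lb_far = log_b_score(0.5, boot, null_far)
        assert lb_far > lb_near

    def test_invalid_prior(self):
        with pytest.raises(ValueError):
            log_b_score(0.0, np.zeros(3), np.zeros(3), prior_h0=1.0)


class TestSpearmanScreen:
    def test_monotone_pair(self):
        X = np.arange(5.0)[:, None]
        y = np.array([1.0, 4.0, 9.0, 16.0, 25.0])
        rho, p, q = spearman_screen(X, y)
        assert rho[0] == pytest.approx(1.0)

    def test_reversed(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        y = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        rho, _, _ = spearman_screen(X, y)
        assert rho[0] == pytest.approx(-1.0)

    def test_hand_ranked(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        rho, p, q = spearman_screen(X, y)
        # brute-force rank correlation: d = (0,1,-1,1,-1), sum d^2 = 4
        # rho = 1 - 6*4/(5*24) = 0.8
        assert rho[0] == pytest.approx(0.8)

    def test_constant_feature_flagged(self, rng):
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        y = rng.normal(size=10)
        rho, p, q = spearman_screen(X, y)
        assert np.isnan(rho[0]) and np.isnan(q[0])
        assert np.isfinite(rho[1])


class TestBhFdr:
    def test_hand_applied_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5)

    def test_exhaustive_transcription_oracle(self, rng):
        def bh_literal(p):
            # literal step-up definition: q_(i) = min_{j >= i} p_(j) m / j
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p, kind="stable")
            q = np.empty(m)
            for rank_i, idx in enumerate(order, start=1):
                cands = [p[order[j - 1]] * m / j for j in range(rank_i, m + 1)]
                q[idx] = min(min(cands), 1.0)
            return q

        for _ in range(30):
            m = rng.integers(1, 13)
            p = np.round(rng.random(m), 3)
            np.testing.assert_allclose(bh_fdr(p), bh_literal(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(50)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_sm, atol=1e-12)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestScoreFeatures:
    def test_table_contract(self, signal_block):
        blocks, y = signal_block
        table = score_features(blocks, y, [0], 0, n_boot=60, n_null=60, seed=0)
        assert len(table) == blocks[0].shape[1]
        assert set(["feature_id", "p_C", "b", "log_b", "rho_S", "p_rho",
                    "q_rho", "selected_logb", "selected_fdr",
                    "selected"]) <= set(table.columns)
        ok = table["q_rho"].notna()
        assert np.all(table.loc[ok, "q_rho"] >= table.loc[ok, "p_rho"] - 1e-12)
        assert np.all((table.loc[ok, "q_rho"] >= 0)
                      & (table.loc[ok, "q_rho"] <= 1))
        # selection rule is the disjunction of the two flags
        np.testing.assert_array_equal(
            table["selected"], table["selected_logb"] | table["selected_fdr"])
        fin = np.isfinite(table["log_b"])
        np.testing.assert_array_equal(table.loc[fin, "log_b"] > 0,
                                      table.loc[fin, "b"] > 0.5)

    def test_informative_features_ranked_high(self, signal_block):
        blocks, y = signal_block
        table = score_features(blocks, y, [0], 0, n_boot=80, n_null=80, seed=1)
        top5 = set(table.sort_values("log_b", ascending=False)
                   .head(5)["feature_id"])
        # the first 5 features are the planted informative set
        assert len(top5 & {f"block1:f{j}" for j in range(1, 6)}) >= 4
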