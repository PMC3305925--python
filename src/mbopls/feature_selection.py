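"""Probabilistic feature relevance scoring.

The sampling distribution of each feature's correlation loading is
estimated by bootstrapping the fitted model, and its null distribution
by refitting against a permuted trait.  Both are turned into Gaussian
kernel densities, evaluated at the observed loading, and combined with a
prior null probability into a posterior-style score

    b = d_boot(pc) (1 - P0) / (d_boot(pc) (1 - P0) + d_null(pc) P0)

whose log-odds log B = ln(b / (1 - b)) exceeds zero exactly when the
alternative is more likely than the prior allows.  A bivariate Spearman
screen with Benjamini-Hochberg FDR control complements the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .multiblock import _as_matrix, build_top_regressors, fit_mbopls
from .opls import correlation_loadings

__all__ = ["bootstrap_loadings", "null_loadings", "log_b_score",
           "spearman_screen", "bh_fdr", "score_features", "FeatureScore"]

DENSITY_FLOOR = 1e-12


@dataclass
class FeatureScore:
    feature_id: str
    p_c: float
    b: float
    log_b: float
    rho_s: float
    p_rho: float
    q_rho: float
    selected_logb: bool
    selected_fdr: bool

    @property
    def selected(self) -> bool:
        return self.selected_logb or self.selected_fdr


def _center(y):
    return y - y.mean()


def _refit_loadings(mats, y, n_orth_per_block, n_orth_top):
    model = fit_mbopls(mats, _center(y), n_orth_per_block, n_orth_top)
    X_top = build_top_regressors(model.block_models)
    return correlation_loadings(model.top_model, X_top)


def observed_loadings(blocks, y, n_orth_per_block, n_orth_top):
    """Full-data correlation loadings at fixed component counts."""
    mats = [_as_matrix(b) for b in blocks]
    y = np.asarray(y, dtype=float).ravel()
    return _refit_loadings(mats, y, n_orth_per_block, n_orth_top)


def bootstrap_loadings(blocks, y, n_orth_per_block, n_orth_top, n_boot=200,
                       seed=0, max_redraw=100):
    """Bootstrap sampling distribution of every correlation loading.

    Samples are resampled with replacement; the model is refitted with the
    already-selected component counts (resampled data re-centered per
    replicate).  Returns an (n_boot, n_features) array; replicates where a
    feature's loading is undefined hold ``nan``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    mats = [_as_matrix(b) for b in blocks]
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    rng = np.random.default_rng(seed)
    out = None
    for r in range(n_boot):
        for _ in range(max_redraw):
            idx = rng.integers(0, n, size=n)
            if np.ptp(y[idx]) > 0:
                break
        else:
            raise ValueError("could not draw a non-degenerate bootstrap sample")
        sub = [X[idx] - X[idx].mean(axis=0) for X in mats]
        pc = _refit_loadings(sub, y[idx], n_orth_per_block, n_orth_top)
        if out is None:
            out = np.empty((n_boot, pc.shape[0]))
        out[r] = pc
    return out


def null_loadings(blocks, y, n_orth_per_block, n_orth_top, n_null=200, seed=0):
    """Null sampling distribution of loadings by trait permutation."""
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    mats = [_as_matrix(b) for b in blocks]
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    out = None
    for r in range(n_null):
        y_perm = y[rng.permutation(len(y))]
        pc = _refit_loadings(mats, y_perm, n_orth_per_block, n_orth_top)
        if out is None:
            out = np.empty((n_null, pc.shape[0]))
        out[r] = pc
    return out


def log_b_score(observed_pc: float, boot_samples, null_samples,
                prior_h0: float = 0.95, bw_method: str = "silverman"):
    """Posterior-style relevance score and its log-odds.

    Gaussian KDEs (Silverman bandwidth by default) are fitted to the
    bootstrap and null loading samples and evaluated at the observed
    loading; densities are floored at 1e-12.
    """
    if not (0 < prior_h0 < 1):
        raise ValueError("prior must lie strictly inside (0, 1)")
    boot = np.asarray(boot_samples, dtype=float)
    null = np.asarray(null_samples, dtype=float)
    if boot.size == 0 or null.size == 0:
        raise ValueError("sample sets must be non-empty")
    if np.isnan(observed_pc):
        return np.nan, np.nan

    def _density(samples):
        s = samples[~np.isnan(samples)]
        if s.size == 0:
            return DENSITY_FLOOR
        if np.ptp(s) == 0:
            return 1.0 / DENSITY_FLOOR if abs(observed_pc - s[0]) < 1e-12 \
                else DENSITY_FLOOR
        kde = stats.gaussian_kde(s, bw_method=bw_method)
        return max(float(kde(observed_pc)[0]), DENSITY_FLOOR)

    d1 = _density(boot)
    d0 = _density(null)
    num = d1 * (1.0 - prior_h0)
    b = num / (num + d0 * prior_h0)
    b = min(max(b, DENSITY_FLOOR), 1.0 - DENSITY_FLOOR)
    return b, float(np.log(b / (1.0 - b)))


def spearman_screen(X, y):
    """Per-feature Spearman correlation with the trait, with BH q-values.

    Returns (rho, p, q) arrays; constant features yield ``nan`` in all
    three and are excluded from the FDR adjustment.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0] or X.shape[0] < 4:
        raise ValueError("need >= 4 paired observations")
    p_feat = X.shape[1]
    rho = np.full(p_feat, np.nan)
    pval = np.full(p_feat, np.nan)
    for j in range(p_feat):
        col = X[:, j]
        ok = ~np.isnan(col) & ~np.isnan(y)
        if ok.sum() < 4 or np.ptp(col[ok]) == 0 or np.ptp(y[ok]) == 0:
            continue
        r, p = stats.spearmanr(col[ok], y[ok])
        rho[j], pval[j] = r, p
    q = np.full(p_feat, np.nan)
    tested = ~np.isnan(pval)
    if tested.any():
        q[tested] = bh_fdr(pval[tested])
    return rho, pval, q


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-D vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downward
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def score_features(blocks, y, n_orth_per_block, n_orth_top, feature_ids=None,
                   n_boot=200, n_null=200, prior_h0=0.95, seed=0,
                   fdr_threshold=0.05) -> pd.DataFrame:
    """Full per-feature scoring table.

    Combines the observed loading, the bootstrap/null log B score, and the
    Spearman screen; a feature is ``selected`` if log B > 0 or its
    Spearman q-value is below `fdr_threshold` (both flags also reported
    separately).
    """
    mats = [_as_matrix(b) for b in blocks]
    y = np.asarray(y, dtype=float).ravel()
    pc = observed_loadings(mats, y, n_orth_per_block, n_orth_top)
    ss = np.random.SeedSequence(seed).spawn(2)
    boot = bootstrap_loadings(mats, y, n_orth_per_block, n_orth_top,
                              n_boot=n_boot,
                              seed=int(np.random.default_rng(ss[0]).integers(2 ** 31)))
    null = null_loadings(mats, y, n_orth_per_block, n_orth_top, n_null=n_null,
                         seed=int(np.random.default_rng(ss[1]).integers(2 ** 31)))
    X_all = np.concatenate(mats, axis=1)
    rho, p_rho, q_rho = spearman_screen(X_all, y)
    if feature_ids is None:
        feature_ids = []
        for i, b in enumerate(blocks):
            fids = getattr(b, "feature_ids", None)
            if fids is None:
                fids = [f"block{i + 1}:f{j + 1}" for j in range(mats[i].shape[1])]
            feature_ids.extend(fids)
    rows = []
    for j, fid in enumerate(feature_ids):
        b_j, logb_j = log_b_score(pc[j], boot[:, j], null[:, j],
                                  prior_h0=prior_h0)
        sel_logb = bool(logb_j > 0) if np.isfinite(logb_j) else False
        sel_fdr = bool(q_rho[j] < fdr_threshold) if np.isfinite(q_rho[j]) else False
        rows.append({"feature_id": fid, "p_C": pc[j], "b": b_j,
                     "log_b": logb_j, "rho_S": rho[j], "p_rho": p_rho[j],
                     "q_rho": q_rho[j], "selected_logb": sel_logb,
                     "selected_fdr": sel_fdr,
                     "selected": sel_logb or sel_fdr})
    return pd.DataFrame(rows)
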