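"""Abundance-matrix and trait preprocessing.

Implements the standard metabolomics pre-treatment chain (log2 transform,
unit-variance scaling, missing-value filtering, redundant-peak
summarization), least-squares correction of traits for population
structure, and a missing-value tolerant NIPALS PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .datatypes import (
    UNKNOWN_ANNOTATION,
    DataError,
    OmicsBlock,
    PopulationMembership,
    TraitVector,
    align_samples,
)

__all__ = [
    "log2_transform",
    "unit_variance_scale",
    "filter_missing",
    "impute_missing",
    "summarize_annotated_peaks",
    "correct_population_structure",
    "nipals_pca",
    "PcaResult",
]


def log2_transform(block: OmicsBlock, offset: float = 0.0) -> OmicsBlock:
    """Replace every non-missing value v with log2(v + offset).

    Raises
    ------
    DataError
        If any non-missing value plus the offset is not strictly positive;
        the message names the first offending feature.
    """
    if offset < 0:
        raise DataError("offset must be nonnegative")
    vals = block.values
    shifted = vals + offset
    bad = np.where(~np.isnan(shifted) & (shifted <= 0))
    if bad[0].size:
        j = int(bad[1][0])
        raise DataError(
            f"nonpositive value after offset in feature "
            f"{block.feature_ids[j]!r} (sample {block.sample_ids[int(bad[0][0])]!r})"
        )
    with np.errstate(invalid="ignore"):
        out = np.log2(shifted)
    return block.with_values(out)


def unit_variance_scale(block: OmicsBlock):
    """Autoscale columns over their non-missing entries.

    Each column is centered on its non-missing mean and divided by its
    non-missing sample standard deviation (``ddof=1``).  Returns
    ``(scaled_block, centers, scales)`` for the inverse transform.

    Raises
    ------
    DataError
        If any column has fewer than two non-missing values or zero
        variance; all offending columns are listed.
    """
    vals = block.values
    n_obs = np.sum(~np.isnan(vals), axis=0)
    too_few = np.flatnonzero(n_obs < 2)
    if too_few.size:
        names = [block.feature_ids[j] for j in too_few[:10]]
        raise DataError(f"columns with <2 non-missing values: {names}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        centers = np.nanmean(vals, axis=0)
        scales = np.nanstd(vals, axis=0, ddof=1)
    zero = np.flatnonzero(scales == 0)
    if zero.size:
        names = [block.feature_ids[j] for j in zero[:10]]
        raise DataError(f"zero-variance columns cannot be scaled: {names}")
    scaled = (vals - centers) / scales
    return block.with_values(scaled), centers, scales


def inverse_unit_variance_scale(block: OmicsBlock, centers, scales) -> OmicsBlock:
    return block.with_values(block.values * np.asarray(scales) + np.asarray(centers))


def filter_missing(block: OmicsBlock, max_missing_fraction: float = 0.3) -> OmicsBlock:
    """Drop features whose missing fraction strictly exceeds the threshold."""
    if not (0 <= max_missing_fraction < 1):
        raise DataError("max_missing_fraction must be in [0, 1)")
    frac = np.isnan(block.values).mean(axis=0)
    return block.subset_features(frac <= max_missing_fraction)


def impute_missing(block: OmicsBlock) -> OmicsBlock:
    """Replace remaining missing cells by their column mean.

    On unit-variance scaled data this is zero imputation.  Columns with no
    observed value at all raise an error.
    """
    vals = block.values.copy()
    nan = np.isnan(vals)
    if not nan.any():
        return block
    all_missing = np.flatnonzero(nan.all(axis=0))
    if all_missing.size:
        names = [block.feature_ids[j] for j in all_missing[:10]]
        raise DataError(f"all-missing columns cannot be imputed: {names}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(vals, axis=0)
    rows, cols = np.where(nan)
    vals[rows, cols] = col_mean[cols]
    return block.with_values(vals)


def _pairwise_pearson(sub: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations over pairwise-complete observations."""
    p = sub.shape[1]
    corr = np.eye(p)
    for a in range(p):
        for b in range(a + 1, p):
            mask = ~np.isnan(sub[:, a]) & ~np.isnan(sub[:, b])
            if mask.sum() < 3:
                c = 0.0
            else:
                xa = sub[mask, a] - sub[mask, a].mean()
                xb = sub[mask, b] - sub[mask, b].mean()
                den = np.sqrt((xa @ xa) * (xb @ xb))
                c = float(xa @ xb / den) if den > 0 else 0.0
            corr[a, b] = corr[b, a] = c
    return corr


def summarize_annotated_peaks(blocks, correlation_threshold: float = 0.5):
    """Concatenate blocks and collapse redundant same-annotation peaks.

    Features sharing a non-"unknown" metabolite identifier whose mean
    pairwise Pearson correlation with the rest of the group exceeds
    ``correlation_threshold`` are replaced by the scores of the first
    principal component of the scaled subgroup (NIPALS, so missing cells
    are tolerated).  The component is sign-oriented to correlate
    positively with the subgroup's mean profile.

    Returns ``(block, provenance)`` where provenance maps each merged
    output feature id to the list of input feature ids it replaced.
    """
    if not blocks:
        raise DataError("no blocks given")
    ref = blocks[0].sample_ids
    mats, fids, anns = [], [], {}
    for blk in blocks:
        idx = align_samples(ref, blk.sample_ids, "blocks")
        mats.append(blk.values[idx])
        for f in blk.feature_ids:
            if f in fids:
                raise DataError(f"feature id {f!r} occurs in more than one block")
            anns[f] = blk.annotation_for(f)
        fids.extend(blk.feature_ids)
    X = np.concatenate(mats, axis=1)

    groups: dict[str, list[int]] = {}
    for j, f in enumerate(fids):
        a = anns[f]
        if a != UNKNOWN_ANNOTATION:
            groups.setdefault(a, []).append(j)

    merged_cols, merged_ids, provenance = [], [], {}
    drop = set()
    for ann, idxs in groups.items():
        if len(idxs) < 2:
            continue
        sub = X[:, idxs]
        # collinearity is sign-agnostic: same-metabolite peaks may load
        # with opposite signs, so the merge criterion uses |r|
        corr = np.abs(_pairwise_pearson(sub))
        mean_corr = (corr.sum(axis=0) - 1.0) / (len(idxs) - 1)
        sel = [idxs[k] for k in np.flatnonzero(mean_corr > correlation_threshold)]
        if len(sel) < 2:
            continue
        grp = X[:, sel]
        # scale within-group so each peak contributes equally to the PC
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(grp, axis=0)
            sd = np.nanstd(grp, axis=0, ddof=1)
        sd[sd == 0] = 1.0
        grp = (grp - mu) / sd
        res = nipals_pca_matrix(grp, n_components=1)
        score = res.scores[:, 0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            profile = np.nanmean(grp, axis=1)
        ok = ~np.isnan(profile)
        if np.corrcoef(score[ok], profile[ok])[0, 1] < 0:
            score = -score
        merged_cols.append(score)
        merged_ids.append(ann)
        provenance[ann] = [fids[j] for j in sel]
        drop.update(sel)

    keep = [j for j in range(len(fids)) if j not in drop]
    out_vals = np.column_stack([X[:, keep]] + [c[:, None] for c in merged_cols]) \
        if merged_cols else X[:, keep]
    out_ids = [fids[j] for j in keep] + merged_ids
    out_ann = {f: anns[f] for f in (fids[j] for j in keep)}
    out_ann.update({m: m for m in merged_ids})
    block = OmicsBlock(list(ref), out_ids, out_vals, platform="summarized",
                       annotations=out_ann)
    return block, provenance


def correct_population_structure(trait: TraitVector,
                                 q: PopulationMembership) -> TraitVector:
    """Regress a trait on the Q-matrix and return the residual trait.

    B is the least-squares solution of Z = Q B over samples with observed
    trait values (pseudoinverse, so rank-deficient Q is fine; no extra
    intercept because Q rows sum to one).  The output keeps missing values
    missing and is flagged ``corrected``.
    """
    idx = align_samples(trait.sample_ids, q.sample_ids, "trait and Q-matrix")
    Q = q.q[idx]
    z = trait.values
    obs = ~np.isnan(z)
    if obs.sum() < q.n_subpopulations:
        raise DataError("fewer observed samples than subpopulations")
    beta, *_ = np.linalg.lstsq(Q[obs], z[obs], rcond=None)
    y = np.full_like(z, np.nan)
    y[obs] = z[obs] - Q[obs] @ beta
    return replace(trait, values=y, corrected=True)


@dataclass
class PcaResult:
    scores: np.ndarray          # (n_samples, n_components)
    loadings: np.ndarray        # (n_features, n_components), unit norm
    r2: np.ndarray              # explained-variance fraction per component
    converged: list             # bool per component
    centers: np.ndarray


def nipals_pca_matrix(X: np.ndarray, n_components: int, max_iter: int = 500,
                      tol: float = 1e-9) -> PcaResult:
    """NIPALS PCA on a samples x features matrix, skipping missing cells.

    Columns are centered on their non-missing means.  Components are
    extracted by successive deflation; loadings are unit norm and
    components are ordered by explained variance (NIPALS extracts them in
    that order for well-separated eigenvalues, and we re-sort defensively).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (1 <= n_components <= min(n, p)):
        raise DataError("n_components out of range")
    if np.isnan(X).all(axis=0).any():
        raise DataError("all-missing column")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        centers = np.nanmean(X, axis=0)
    R = X - centers
    mask = ~np.isnan(R)
    Rz = np.where(mask, R, 0.0)
    total_ss = float(np.sum(Rz ** 2))
    scores = np.zeros((n, n_components))
    loadings = np.zeros((p, n_components))
    r2 = np.zeros(n_components)
    converged = []
    for k in range(n_components):
        # seed with the column of largest observed variance
        j0 = int(np.argmax(np.sum(Rz ** 2, axis=0)))
        t = Rz[:, j0].copy()
        if np.all(t == 0):
            t = np.ones(n)
        ok = False
        for _ in range(max_iter):
            tt = (t ** 2) @ mask            # per-feature sum of t^2 over observed
            tt[tt == 0] = 1.0
            pvec = (t @ Rz) / tt
            nrm = np.linalg.norm(pvec)
            if nrm == 0:
                break
            pvec /= nrm
            pp = mask @ (pvec ** 2)
            pp[pp == 0] = 1.0
            t_new = (Rz @ pvec) / pp
            if np.linalg.norm(t_new - t) < tol * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                ok = True
                break
            t = t_new
        converged.append(ok)
        scores[:, k] = t
        loadings[:, k] = pvec
        approx = np.where(mask, np.outer(t, pvec), 0.0)
        r2[k] = float(np.sum(approx ** 2)) / total_ss if total_ss > 0 else 0.0
        Rz = Rz - approx
    order = np.argsort(-r2, kind="stable")
    return PcaResult(scores[:, order], loadings[:, order], r2[order],
                     [converged[i] for i in order], centers)


def nipals_pca(block: OmicsBlock, n_components: int, max_iter: int = 500,
               tol: float = 1e-9) -> PcaResult:
    """NIPALS PCA of a block's value matrix (see :func:`nipals_pca_matrix`)."""
    return nipals_pca_matrix(block.values, n_components, max_iter=max_iter, tol=tol)
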