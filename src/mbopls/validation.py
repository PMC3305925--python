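"""External cross-validation performance and permutation significance.

rCV^2 is the squared Pearson correlation between the observed trait and
its out-of-fold cross-validated predictions.  The external CV is fully
nested: orthogonal-component counts are re-selected by internal CV
inside every training fold, so held-out samples never influence any
training computation.  The empirical P-value uses the positively biased
estimator (n0 + 1)/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .multiblock import (
    _as_matrix,
    _predict_mbopls_arrays,
    cv_folds,
    fit_mbopls,
    select_components,
)

__all__ = ["CvResult", "PermutationResult", "rcv2", "external_cv",
           "permutation_test"]


def rcv2(y_true, y_pred) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape or y_true.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    a = y_true - y_true.mean()
    b = y_pred - y_pred.mean()
    den = np.sqrt((a @ a) * (b @ b))
    if den == 0:
        raise ValueError("constant input")
    r = float(a @ b) / den
    return r * r


@dataclass
class CvResult:
    """Repeated external-CV outcome for one model specification."""

    rcv2_per_run: np.ndarray
    median_rcv2: float
    predictions_per_run: np.ndarray      # (n_repeats, n_samples), out-of-fold
    fold_assignments: np.ndarray         # (n_repeats, n_samples) fold index
    selections_per_run: list             # per run, per fold (block counts, top)
    n_folds: int
    n_repeats: int
    seed: int


@dataclass
class PermutationResult:
    observed: float
    null_statistics: np.ndarray
    n0: int
    p_value: float
    n_perm: int
    seed: int
    observed_cv: CvResult | None = field(default=None, repr=False)


def _one_cv_run(mats, y, n_folds, max_orth_block, max_orth_top, run_rng):
    n = len(y)
    folds = cv_folds(n, n_folds, run_rng)
    y_hat = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    selections = []
    for f, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test, assume_unique=False)
        ytr = y[train]
        mu = ytr.mean()
        tr_mats = [X[train] for X in mats]
        inner_seed = int(run_rng.integers(2 ** 31))
        n_ob, n_ot, _ = select_components(
            tr_mats, ytr - mu, max_orth_block=max_orth_block,
            max_orth_top=max_orth_top, n_folds=min(n_folds, len(train)),
            seed=inner_seed)
        model = fit_mbopls(tr_mats, ytr - mu, n_ob, n_ot)
        y_hat[test] = mu + _predict_mbopls_arrays(model, [X[test] for X in mats])
        fold_of[test] = f
        selections.append((n_ob, n_ot))
    return y_hat, fold_of, selections


def external_cv(blocks, y, n_folds=7, n_repeats=50, max_orth_block=5,
                max_orth_top=5, seed=0) -> CvResult:
    """Repeated nested external cross-validation.

    Per repeat the samples are partitioned into `n_folds` segments; each
    segment is predicted by a model whose component counts were selected
    by internal CV on the remaining samples only.  The per-run statistic
    is rCV^2 and the headline number is the median over repeats.
    """
    mats = [_as_matrix(b) for b in blocks]
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < n_folds:
        raise ValueError("sample count below fold count")
    if n // n_folds < 1 or min(len(f) for f in
                               np.array_split(np.arange(n), n_folds)) < 2:
        raise ValueError("a fold would hold fewer than 2 samples")
    root = np.random.SeedSequence(seed)
    preds = np.empty((n_repeats, n))
    folds_out = np.empty((n_repeats, n), dtype=int)
    stats = np.empty(n_repeats)
    selections = []
    for r, child in enumerate(root.spawn(n_repeats)):
        rng = np.random.default_rng(child)
        y_hat, fold_of, sel = _one_cv_run(
            mats, y, n_folds, max_orth_block, max_orth_top, rng)
        preds[r] = y_hat
        folds_out[r] = fold_of
        stats[r] = rcv2(y, y_hat)
        selections.append(sel)
    return CvResult(rcv2_per_run=stats, median_rcv2=float(np.median(stats)),
                    predictions_per_run=preds, fold_assignments=folds_out,
                    selections_per_run=selections, n_folds=n_folds,
                    n_repeats=n_repeats, seed=seed)


def permutation_test(blocks, y, n_perm=1000, n_folds=7, n_repeats=50,
                     max_orth_block=5, max_orth_top=5, seed=0,
                     null_repeats=1) -> PermutationResult:
    """Permutation significance of the external-CV rCV^2.

    The observed statistic is the median rCV^2 over `n_repeats` runs; for
    each of `n_perm` permutations the trait is shuffled uniformly and the
    same CV machinery is re-run (`null_repeats` runs each, default 1 for
    cost).  n0 counts null statistics greater than or equal to the
    observed one; p = (n0 + 1)/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mats = [_as_matrix(b) for b in blocks]
    y = np.asarray(y, dtype=float).ravel()
    root = np.random.SeedSequence(seed)
    obs_ss, perm_ss = root.spawn(2)
    observed_cv = external_cv(mats, y, n_folds=n_folds, n_repeats=n_repeats,
                              max_orth_block=max_orth_block,
                              max_orth_top=max_orth_top,
                              seed=int(np.random.default_rng(obs_ss).integers(2 ** 31)))
    observed = observed_cv.median_rcv2
    null_stats = np.empty(n_perm)
    for i, child in enumerate(perm_ss.spawn(n_perm)):
        rng = np.random.default_rng(child)
        y_perm = y[rng.permutation(len(y))]
        cv_seed = int(rng.integers(2 ** 31))
        res = external_cv(mats, y_perm, n_folds=n_folds,
                          n_repeats=null_repeats,
                          max_orth_block=max_orth_block,
                          max_orth_top=max_orth_top, seed=cv_seed)
        null_stats[i] = res.median_rcv2
    n0 = int(np.sum(null_stats >= observed))
    return PermutationResult(observed=observed, null_statistics=null_stats,
                             n0=n0, p_value=(n0 + 1) / (n_perm + 1),
                             n_perm=n_perm, seed=seed, observed_cv=observed_cv)
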