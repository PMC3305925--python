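"""Two-step multi-block OPLS.

Step 1 fits one OPLS model per block against the trait and strips each
block's response-orthogonal variance.  Step 2 concatenates the filtered
blocks along the feature axis and fits a top-level OPLS on the result.
With a single block and no block-level orthogonal components the method
reduces exactly to ordinary OPLS.

Component counts (one orthogonal count per block plus one for the top
model) are chosen by seeded seven-fold internal cross-validation with a
greedy stop-on-no-improvement scan.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .opls import (
    InsufficientOrthogonalVarianceError,
    OplsModel,
    _fit_opls_arrays,
    _predict_arrays,
    correlation_loadings,
    fit_opls,
    predict_opls,
)

__all__ = ["MbOplsModel", "build_top_regressors", "fit_mbopls",
           "predict_mbopls", "select_components", "cv_folds"]


def _as_matrix(block):
    """Accept either an OmicsBlock or a bare samples x features array."""
    vals = getattr(block, "values", block)
    return np.asarray(vals, dtype=float)


def _feature_ids(block, i):
    fids = getattr(block, "feature_ids", None)
    if fids is None:
        return [f"block{i + 1}:f{j + 1}" for j in range(_as_matrix(block).shape[1])]
    return list(fids)


@dataclass
class MbOplsModel:
    """Per-block OPLS filters plus the top-level OPLS model."""

    block_models: list
    top_model: OplsModel
    n_orth_per_block: list
    n_orth_top: int
    feature_offsets: list            # start index of each block within X_Top
    feature_ids: list                # concatenated feature ids
    trait_name: str = ""
    y_mean: float = 0.0
    cv_meta: dict = field(default_factory=dict)

    @property
    def n_blocks(self) -> int:
        return len(self.block_models)

    @property
    def n_parameters(self) -> int:
        """Free structural parameters: one orthogonal count per block + top."""
        return self.n_blocks + 1

    def fitted_values(self) -> np.ndarray:
        return self.top_model.fitted_values()

    def correlation_loadings(self, blocks) -> np.ndarray:
        """Correlation loadings of every concatenated feature."""
        X_top = build_top_regressors(self.block_models)
        return correlation_loadings(self.top_model, X_top)

    def to_dict(self) -> dict:
        return {
            "format": "mbopls.mb-model", "version": 1,
            "block_models": [m.to_dict() for m in self.block_models],
            "top_model": self.top_model.to_dict(),
            "n_orth_per_block": list(self.n_orth_per_block),
            "n_orth_top": self.n_orth_top,
            "feature_offsets": list(self.feature_offsets),
            "feature_ids": list(self.feature_ids),
            "trait_name": self.trait_name, "y_mean": self.y_mean,
            "cv_meta": self.cv_meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MbOplsModel":
        if d.get("format") != "mbopls.mb-model":
            raise ValueError("not an MB-OPLS model container")
        return cls(
            block_models=[OplsModel.from_dict(b) for b in d["block_models"]],
            top_model=OplsModel.from_dict(d["top_model"]),
            n_orth_per_block=list(d["n_orth_per_block"]),
            n_orth_top=int(d["n_orth_top"]),
            feature_offsets=list(d["feature_offsets"]),
            feature_ids=list(d["feature_ids"]),
            trait_name=d.get("trait_name", ""),
            y_mean=float(d.get("y_mean", 0.0)),
            cv_meta=d.get("cv_meta", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "MbOplsModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_top_regressors(block_models) -> np.ndarray:
    """Concatenate each block's orthogonal-filtered training matrix.

    The filtered matrix is the scaled block minus its orthogonal part,
    i.e. the response-correlated part plus residual, ``t p^T + E``.
    """
    n = block_models[0].t.shape[0]
    for m in block_models:
        if m.t.shape[0] != n:
            raise ValueError("block models trained on different sample counts")
    return np.concatenate([m.filtered_training_matrix() for m in block_models],
                          axis=1)


def fit_mbopls(blocks, y, n_orth_per_block, n_orth_top, trait_name="",
               feature_ids=None) -> MbOplsModel:
    """Fit block-wise OPLS filters and the top-level OPLS model.

    `blocks` is a list of complete, scaled samples x features matrices
    (or OmicsBlocks); `y` is the centered trait.
    """
    y = np.asarray(y, dtype=float).ravel()
    mats = [_as_matrix(b) for b in blocks]
    if isinstance(n_orth_per_block, int):
        n_orth_per_block = [n_orth_per_block] * len(mats)
    if len(n_orth_per_block) != len(mats):
        raise ValueError("one orthogonal count per block required")
    block_models = [fit_opls(X, y, k) for X, k in zip(mats, n_orth_per_block)]
    X_top = build_top_regressors(block_models)
    top = fit_opls(X_top, y, n_orth_top)
    offsets, fids, off = [], [], 0
    for i, b in enumerate(blocks):
        offsets.append(off)
        ids = _feature_ids(b, i)
        fids.extend(ids)
        off += len(ids)
    return MbOplsModel(block_models=block_models, top_model=top,
                       n_orth_per_block=list(n_orth_per_block),
                       n_orth_top=n_orth_top, feature_offsets=offsets,
                       feature_ids=fids, trait_name=trait_name)


def _predict_mbopls_arrays(model: MbOplsModel, mats) -> np.ndarray:
    parts = []
    for bm, X in zip(model.block_models, mats):
        if X.shape[1] != bm.n_features:
            raise ValueError("feature mismatch between model and new block")
        _, Xf, _ = _predict_arrays(bm.w, bm.c, bm.W_orth, bm.P_orth, X)
        parts.append(Xf)
    X_top = np.concatenate(parts, axis=1)
    y_hat, _, _ = _predict_arrays(model.top_model.w, model.top_model.c,
                                  model.top_model.W_orth,
                                  model.top_model.P_orth, X_top)
    return y_hat


def predict_mbopls(model: MbOplsModel, new_blocks) -> np.ndarray:
    """Predict the (centered) trait for new samples.

    Each block is deflated by its fitted orthogonal components, the
    filtered blocks are concatenated, and the top model predicts.  Add
    ``model.y_mean`` to report on the raw trait scale.
    """
    mats = [_as_matrix(b) for b in new_blocks]
    if len(mats) != model.n_blocks:
        raise ValueError("block count mismatch")
    return _predict_mbopls_arrays(model, mats)


# ---------------------------------------------------------------------
# component selection by internal cross-validation
# ---------------------------------------------------------------------

def cv_folds(n: int, n_folds: int, rng) -> list:
    """Random balanced partition of range(n) into n_folds index arrays."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n < n_folds:
        raise ValueError("more folds than samples")
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, n_folds)]


def _train_test_pairs(folds, n):
    all_idx = np.arange(n)
    return [(np.delete(all_idx, test), test) for test in folds]


def _q2_single_block(X, y, n_orth, pairs):
    """Internal-CV Q^2 of a single-block OPLS with `n_orth` components."""
    press = tss = 0.0
    for train, test in pairs:
        ytr = y[train]
        mu = ytr.mean()
        w, t, p, c, W_o, P_o, T_o, Xd = _fit_opls_arrays(X[train], ytr - mu, n_orth)
        y_hat, _, _ = _predict_arrays(w, c, W_o, P_o, X[test])
        press += float(np.sum((y[test] - mu - y_hat) ** 2))
        tss += float(np.sum((y[test] - mu) ** 2))
    if tss == 0:
        raise ValueError("constant response within folds")
    return 1.0 - press / tss


def _top_fold_cache(mats, y, n_orth_per_block, pairs):
    """Per-fold filtered top matrices for a fixed set of block counts.

    The block filters do not depend on the top-level count, so they are
    fitted once per fold and reused across the top-level scan.
    """
    cache = []
    for train, test in pairs:
        ytr = y[train]
        mu = ytr.mean()
        tr_parts, te_parts = [], []
        for X, k in zip(mats, n_orth_per_block):
            w, t, p, c, W_o, P_o, T_o, Xd = _fit_opls_arrays(
                X[train], ytr - mu, k)
            tr_parts.append(Xd)
            _, Xf, _ = _predict_arrays(w, c, W_o, P_o, X[test])
            te_parts.append(Xf)
        cache.append((np.concatenate(tr_parts, axis=1),
                      np.concatenate(te_parts, axis=1),
                      ytr - mu, mu, test))
    return cache


def _q2_top(cache, y, n_orth_top):
    press = tss = 0.0
    for Xtr, Xte, ytr_c, mu, test in cache:
        w, t, p, c, W_o, P_o, T_o, Xd = _fit_opls_arrays(Xtr, ytr_c, n_orth_top)
        y_hat, _, _ = _predict_arrays(w, c, W_o, P_o, Xte)
        press += float(np.sum((y[test] - mu - y_hat) ** 2))
        tss += float(np.sum((y[test] - mu) ** 2))
    if tss == 0:
        raise ValueError("constant response within folds")
    return 1.0 - press / tss


def _greedy_scan(q2_of, max_count, min_improvement):
    """Scan counts 0..max_count, stopping when Q^2 stops improving.

    An extra component is only accepted when it raises Q^2 by more than
    `min_improvement`; marginal gains from fitting noise do not justify a
    structural parameter.
    """
    curve = []
    best_k, best_q2 = 0, None
    for k in range(max_count + 1):
        try:
            q2 = q2_of(k)
        except InsufficientOrthogonalVarianceError:
            warnings.warn(f"orthogonal-variance scan truncated at {k} components")
            break
        curve.append((k, q2))
        if best_q2 is None or q2 > best_q2 + min_improvement:
            best_k, best_q2 = k, q2
        else:
            break
    return best_k, curve


def select_components(blocks, y, max_orth_block=5, max_orth_top=5,
                      n_folds=7, seed=0, min_improvement=0.01):
    """Choose orthogonal component counts by internal cross-validation.

    Each block's count is scanned independently (0 upward, greedy stop
    when CV Q^2 no longer improves); with the block counts fixed, the
    top-level count is scanned the same way using the full two-step
    pipeline per fold.  Deterministic given `seed` (folds are one random
    balanced partition drawn from it).

    Returns ``(n_orth_per_block, n_orth_top, cv_curve)``.
    """
    mats = [_as_matrix(b) for b in blocks]
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    folds = cv_folds(len(y), n_folds, rng)
    pairs = _train_test_pairs(folds, len(y))
    curves = {}
    n_orth_per_block = []
    for i, X in enumerate(mats):
        k, curve = _greedy_scan(lambda k: _q2_single_block(X, y, k, pairs),
                                max_orth_block, min_improvement)
        n_orth_per_block.append(k)
        curves[f"block{i + 1}"] = curve
    cache = _top_fold_cache(mats, y, n_orth_per_block, pairs)
    k_top, curve = _greedy_scan(lambda k: _q2_top(cache, y, k), max_orth_top,
                                min_improvement)
    curves["top"] = curve
    return n_orth_per_block, k_top, curves
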