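"""Single-response OPLS regression (NIPALS form).

The model splits a scaled predictor matrix into a response-predictive
part ``t p^T``, a response-orthogonal structured part ``T_orth P_orth^T``
and a residual ``E``.  Exactly one predictive component is used (single
trait regression throughout).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["OplsModel", "fit_opls", "predict_opls", "correlation_loadings",
           "InsufficientOrthogonalVarianceError"]

_W_ORTH_TOL = 1e-10


class InsufficientOrthogonalVarianceError(ValueError):
    """No response-orthogonal structured variance left to extract."""


def _fit_opls_arrays(X: np.ndarray, y: np.ndarray, n_orth: int):
    """Lean OPLS fit on centered/scaled arrays.

    Returns ``(w, t, p, c, W_orth, P_orth, T_orth, X_filtered)`` where
    ``X_filtered`` is X after removal of the orthogonal components (the
    predictive-plus-residual part handed to multi-block top models).
    """
    n, m = X.shape
    yss = float(y @ y)
    if yss <= 0:
        raise ValueError("response is constant")
    w = X.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("X has no covariance with the response")
    w /= nw
    W_orth = np.empty((m, n_orth))
    P_orth = np.empty((m, n_orth))
    T_orth = np.empty((n, n_orth))
    Xd = X
    for k in range(n_orth):
        t = Xd @ w
        p = (Xd.T @ t) / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < _W_ORTH_TOL:
            raise InsufficientOrthogonalVarianceError(
                f"insufficient orthogonal variance for component {k + 1}"
            )
        w_o = w_o / n_o
        t_o = Xd @ w_o
        p_o = (Xd.T @ t_o) / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_orth[:, k] = w_o
        P_orth[:, k] = p_o
        T_orth[:, k] = t_o
    t = Xd @ w
    p = (Xd.T @ t) / (t @ t)
    c = float(y @ t) / float(t @ t)
    return w, t, p, c, W_orth, P_orth, T_orth, Xd


@dataclass
class OplsModel:
    """Fitted OPLS decomposition for one response.

    Attributes
    ----------
    w, t, p, c : predictive weight (unit norm), training score, loading
        and the scalar regression coefficient of y on t.
    W_orth, P_orth, T_orth : per-orthogonal-component weights/loadings
        (features x n_orth) and training scores (samples x n_orth).
    E : residual matrix after removing predictive and orthogonal parts.
    """

    w: np.ndarray
    t: np.ndarray
    p: np.ndarray
    c: float
    W_orth: np.ndarray
    P_orth: np.ndarray
    T_orth: np.ndarray
    E: np.ndarray
    n_orth: int
    feature_ids: list | None = None
    centers: np.ndarray | None = None
    scales: np.ndarray | None = None
    y_mean: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.w.shape[0]

    def fitted_values(self) -> np.ndarray:
        return self.c * self.t

    def filtered_training_matrix(self) -> np.ndarray:
        """Training X with orthogonal components removed: ``t p^T + E``."""
        return np.outer(self.t, self.p) + self.E

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "format": "mbopls.opls-model", "version": 1,
            "w": self.w.tolist(), "t": self.t.tolist(), "p": self.p.tolist(),
            "c": self.c, "W_orth": self.W_orth.tolist(),
            "P_orth": self.P_orth.tolist(), "T_orth": self.T_orth.tolist(),
            "E": self.E.tolist(), "n_orth": self.n_orth,
            "feature_ids": self.feature_ids, "y_mean": self.y_mean,
            "centers": None if self.centers is None else self.centers.tolist(),
            "scales": None if self.scales is None else self.scales.tolist(),
            "meta": self.meta,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OplsModel":
        if d.get("format") != "mbopls.opls-model":
            raise ValueError("not an OPLS model container")
        arr = lambda k: np.asarray(d[k], dtype=float)
        return cls(
            w=arr("w"), t=arr("t"), p=arr("p"), c=float(d["c"]),
            W_orth=arr("W_orth").reshape(len(d["w"]), -1),
            P_orth=arr("P_orth").reshape(len(d["w"]), -1),
            T_orth=arr("T_orth").reshape(len(d["t"]), -1),
            E=arr("E"), n_orth=int(d["n_orth"]),
            feature_ids=d.get("feature_ids"),
            centers=None if d.get("centers") is None else arr("centers"),
            scales=None if d.get("scales") is None else arr("scales"),
            y_mean=float(d.get("y_mean", 0.0)), meta=d.get("meta", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "OplsModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_opls(X: np.ndarray, y: np.ndarray, n_orth: int = 0,
             feature_ids=None, **meta) -> OplsModel:
    """Fit a single-y OPLS model on a complete, centered/scaled matrix.

    The predictive weight is ``X^T y`` normalized; each orthogonal
    component removes the part of the current loading that is not in the
    predictive direction, deflating X before the final predictive
    component is computed.

    Raises
    ------
    InsufficientOrthogonalVarianceError
        If ``n_orth`` exceeds the available orthogonal structured variance.
    ValueError
        If y is constant or X has fewer than 3 rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y shapes disagree")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("X and y must be complete (impute first)")
    w, t, p, c, W_o, P_o, T_o, Xd = _fit_opls_arrays(X, y, n_orth)
    E = Xd - np.outer(t, p)
    return OplsModel(w=w, t=t, p=p, c=c, W_orth=W_o, P_orth=P_o, T_orth=T_o,
                     E=E, n_orth=n_orth, feature_ids=feature_ids, meta=meta)


def _predict_arrays(w, c, W_orth, P_orth, X_new):
    n_orth = W_orth.shape[1]
    T_o = np.empty((X_new.shape[0], n_orth))
    Xd = X_new
    for k in range(n_orth):
        t_o = Xd @ W_orth[:, k]
        Xd = Xd - np.outer(t_o, P_orth[:, k])
        T_o[:, k] = t_o
    return c * (Xd @ w), Xd, T_o


def predict_opls(model: OplsModel, X_new: np.ndarray):
    """Predict new samples: orthogonal deflation then projection onto w.

    Returns ``(y_hat, X_filtered, T_orth_new)``; predictions are on the
    centered-response scale (add ``model.y_mean`` for reporting).
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"feature mismatch: model has {model.n_features} features, "
            f"input has {X_new.shape[1]}"
        )
    return _predict_arrays(model.w, model.c, model.W_orth, model.P_orth, X_new)


def correlation_loadings(model: OplsModel, X: np.ndarray) -> np.ndarray:
    """Correlation of each (orthogonal-filtered) feature with the score t.

    Zero-variance columns after filtering yield ``nan``.
    """
    _, Xf, _ = predict_opls(model, X)
    t = model.t
    tc = t - t.mean()
    Xc = Xf - Xf.mean(axis=0)
    denom = np.sqrt((tc @ tc) * np.sum(Xc ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        pc = np.where(denom > 0, (Xc.T @ tc) / denom, np.nan)
    return pc
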