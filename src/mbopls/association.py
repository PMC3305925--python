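"""Supporting association analyses: Mantel test, one-vs-rest differential
abundance, and metabolite-metabolite correlation networks."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .datatypes import DataError, align_samples
from .feature_selection import bh_fdr
from .multiblock import _as_matrix

__all__ = ["DistanceMatrix", "NetworkEdge", "euclidean_distance_matrix",
           "mantel_test", "differential_abundance", "correlation_network"]


@dataclass
class DistanceMatrix:
    sample_ids: list
    matrix: np.ndarray
    metric: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise DataError("distance matrix shape does not match sample ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise DataError("distance matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise DataError("distance matrix diagonal must be exactly zero")
        if np.any(self.matrix < 0):
            raise DataError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n, k=-1)
        return self.matrix[i, j]


@dataclass(frozen=True)
class NetworkEdge:
    feature_a: str
    feature_b: str
    rho_s: float
    p_value: float


def euclidean_distance_matrix(X, sample_ids=None) -> DistanceMatrix:
    """Pairwise Euclidean distances between samples over all features."""
    vals = _as_matrix(X)
    if np.isnan(vals).any():
        raise DataError("distance computation requires a complete matrix")
    if sample_ids is None:
        sample_ids = getattr(X, "sample_ids",
                             [f"s{i + 1}" for i in range(vals.shape[0])])
    return DistanceMatrix(list(sample_ids), squareform(pdist(vals)),
                          metric="euclidean")


def _mantel_r(a_tri, b_tri):
    a = a_tri - a_tri.mean()
    b = b_tri - b_tri.mean()
    den = math.sqrt((a @ a) * (b @ b))
    if den == 0:
        raise DataError("constant distance triangle")
    return float(a @ b) / den


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 10000,
                seed: int = 0, exhaustive: bool = False):
    """Mantel correlation of two distance matrices with a permutation null.

    The statistic is the Pearson correlation of the lower triangles; the
    null permutes the sample labels of the second matrix (rows and
    columns jointly).  One-sided ("positive association"):
    p = (#{r_perm >= r_obs} + 1)/(n_perm + 1), or an exact count over all
    n! relabelings when `exhaustive` is set.
    """
    idx = align_samples(d1.sample_ids, d2.sample_ids, "distance matrices")
    m2 = d2.matrix[np.ix_(idx, idx)]
    n = d1.n
    if n < 4:
        raise DataError("need at least 4 samples")
    tri = np.tril_indices(n, k=-1)
    a = d1.matrix[tri]
    r_obs = _mantel_r(a, m2[tri])
    if exhaustive:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            perm = np.array(perm)
            r = _mantel_r(a, m2[np.ix_(perm, perm)][tri])
            total += 1
            if r >= r_obs - 1e-12:
                count += 1
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = _mantel_r(a, m2[np.ix_(perm, perm)][tri])
        if r >= r_obs - 1e-12:
            hits += 1
    return r_obs, (hits + 1) / (n_perm + 1)


def differential_abundance(block, group_labels, min_fold: float = 2.0,
                           fdr_max: float = 0.01, welch: bool = False):
    """One-vs-rest differential abundance on log2-scale data.

    Per feature and group a two-sided Student t-test (pooled variance by
    default, Welch optionally) compares the group against all other
    samples.  The fold criterion on the log2 scale is
    |group mean - grand mean| >= log2(min_fold).  BH FDR is applied across
    all feature x group tests; the returned table flags features passing
    both criteria, with the direction of change.
    """
    vals = _as_matrix(block)
    fids = getattr(block, "feature_ids",
                   [f"f{j + 1}" for j in range(vals.shape[1])])
    labels = np.asarray(group_labels)
    if labels.shape[0] != vals.shape[0]:
        raise DataError("one group label per sample required")
    groups = [g for g in pd.unique(labels)]
    if len(groups) < 2:
        raise DataError("need at least 2 groups")
    for g in groups:
        if np.sum(labels == g) < 2:
            raise DataError(f"group {g!r} has fewer than 2 samples")
    log_min_fold = math.log2(min_fold)
    grand = vals.mean(axis=0)
    rows = []
    for g in groups:
        in_g = labels == g
        a, b = vals[in_g], vals[~in_g]
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
        delta = a.mean(axis=0) - grand
        for j, fid in enumerate(fids):
            rows.append({"feature_id": fid, "group": g,
                         "delta_log2": float(delta[j]),
                         "t": float(t[j]), "p": float(p[j])})
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["fold_pass"] = np.abs(table["delta_log2"]) >= log_min_fold - 1e-12
    table["fdr_pass"] = table["q"] < fdr_max
    table["selected"] = table["fold_pass"] & table["fdr_pass"]
    table["direction"] = np.where(table["delta_log2"] >= 0, "up", "down")
    return table


def correlation_network(X, feature_ids=None, selected_features=None,
                        p_max: float = 0.001):
    """Spearman correlation edges among selected features.

    All pairwise correlations among the selected features are tested
    two-sided; pairs with p < `p_max` become undirected edges in
    canonical (a < b) order.
    """
    vals = _as_matrix(X)
    if feature_ids is None:
        feature_ids = getattr(X, "feature_ids",
                              [f"f{j + 1}" for j in range(vals.shape[1])])
    feature_ids = list(feature_ids)
    if selected_features is None:
        selected_features = feature_ids
    pos = {f: j for j, f in enumerate(feature_ids)}
    missing = [f for f in selected_features if f not in pos]
    if missing:
        raise DataError(f"selected features not in matrix: {missing[:5]}")
    sel = list(dict.fromkeys(selected_features))  # dedupe, keep order
    edges = []
    for fa, fb in itertools.combinations(sel, 2):
        xa, xb = vals[:, pos[fa]], vals[:, pos[fb]]
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        if ok.sum() < 4 or np.ptp(xa[ok]) == 0 or np.ptp(xb[ok]) == 0:
            continue
        rho, p = stats.spearmanr(xa[ok], xb[ok])
        if p < p_max:
            a, b = sorted((fa, fb))
            edges.append(NetworkEdge(a, b, float(rho), float(p)))
    edges.sort(key=lambda e: (e.feature_a, e.feature_b))
    return edges
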