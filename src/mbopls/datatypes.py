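"""Core domain types shared across the package.

All matrices are oriented samples x features.  Missing values are encoded
as ``numpy.nan`` in float arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

UNKNOWN_ANNOTATION = "unknown"


class DataError(ValueError):
    """Raised when input data violates a structural contract."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class OmicsBlock:
    """One analytical platform's sample x feature abundance matrix.

    Parameters
    ----------
    sample_ids : list of str
        Row identifiers, unique, in matrix order.
    feature_ids : list of str
        Column identifiers, unique within the block, in matrix order.
    values : ndarray of shape (n_samples, n_features)
        Abundances; ``nan`` marks a missing cell.
    platform : str
        Free-text platform label.
    annotations : dict or None
        Optional map feature_id -> metabolite identifier.  Features absent
        from the map (or mapped to ``"unknown"``) are treated as
        unannotated.
    """

    sample_ids: list
    feature_ids: list
    values: np.ndarray
    platform: str = ""
    annotations: dict | None = None

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D samples x features matrix")
        if self.values.shape[0] != len(self.sample_ids):
            raise DataError(
                f"row count {self.values.shape[0]} != number of sample ids "
                f"{len(self.sample_ids)}"
            )
        if self.values.shape[1] != len(self.feature_ids):
            raise DataError(
                f"column count {self.values.shape[1]} != number of feature "
                f"ids {len(self.feature_ids)}"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.feature_ids, "feature id")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def annotation_for(self, feature_id) -> str:
        if self.annotations is None:
            return UNKNOWN_ANNOTATION
        return self.annotations.get(feature_id, UNKNOWN_ANNOTATION)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def with_values(self, values: np.ndarray) -> "OmicsBlock":
        return replace(self, values=np.asarray(values, dtype=float))

    def subset_features(self, keep: np.ndarray) -> "OmicsBlock":
        """Return a block restricted to the boolean/index selection `keep`."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        fids = [self.feature_ids[i] for i in keep]
        ann = None
        if self.annotations is not None:
            ann = {f: self.annotations[f] for f in fids if f in self.annotations}
        return OmicsBlock(self.sample_ids, fids, self.values[:, keep],
                          platform=self.platform, annotations=ann)


@dataclass
class TraitVector:
    """One quantitative trait across samples (raw or structure-corrected)."""

    sample_ids: list
    values: np.ndarray
    name: str = ""
    corrected: bool = False

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape[0] != len(self.sample_ids):
            raise DataError(
                f"trait length {self.values.shape[0]} != number of sample "
                f"ids {len(self.sample_ids)}"
            )
        _check_unique(self.sample_ids, "sample id")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class PopulationMembership:
    """Sample x subpopulation membership-probability matrix (Q-matrix)."""

    sample_ids: list
    q: np.ndarray
    subpopulation_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[1] < 1:
            raise DataError("Q must be 2-D with at least one subpopulation")
        if self.q.shape[0] != len(self.sample_ids):
            raise DataError("Q row count does not match sample ids")
        if not self.subpopulation_labels:
            self.subpopulation_labels = [f"pop{k + 1}" for k in range(self.q.shape[1])]
        if len(self.subpopulation_labels) != self.q.shape[1]:
            raise DataError("subpopulation label count mismatch")
        if np.any(self.q < -1e-9) or np.any(self.q > 1 + 1e-9):
            raise DataError("Q entries must lie in [0, 1]")
        rowsum = self.q.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(rowsum - 1.0)))
            raise DataError(
                f"Q rows must sum to 1; row {self.sample_ids[bad]!r} sums to "
                f"{rowsum[bad]:.6g}"
            )

    @property
    def n_subpopulations(self) -> int:
        return self.q.shape[1]


def align_samples(sample_ids_a, sample_ids_b, what="inputs"):
    """Indices aligning `b` onto `a`'s order; error if sets differ."""
    if set(sample_ids_a) != set(sample_ids_b):
        missing = set(sample_ids_a) ^ set(sample_ids_b)
        raise DataError(f"sample sets differ between {what}: {sorted(missing)[:5]} ...")
    pos = {s: i for i, s in enumerate(sample_ids_b)}
    return np.array([pos[s] for s in sample_ids_a], dtype=int)
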