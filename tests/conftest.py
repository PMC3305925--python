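import numpy as np
import pytest

from mbopls.datatypes import OmicsBlock, TraitVector
from mbopls.preprocessing import filter_missing, impute_missing, unit_variance_scale


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_block(values, sample_prefix="s", feature_prefix="f", **kw):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return OmicsBlock([f"{sample_prefix}{i + 1}" for i in range(n)],
                      [f"{feature_prefix}{j + 1}" for j in range(p)],
                      values, **kw)


def scaled_complete(block):
    """filter -> unit-variance scale -> impute, returning the bare matrix."""
    b = filter_missing(block)
    b, _, _ = unit_variance_scale(b)
    return impute_missing(b).values


def scale_matrix(X):
    """Center/scale a complete matrix (ddof=1), for model-level tests."""
    X = np.asarray(X, dtype=float)
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


@pytest.fixture
def planted_single_block(rng):
    """One block with a y-correlated latent and one orthogonal latent."""
    n, p = 40, 25
    t = rng.normal(size=n)
    t_o = rng.normal(size=n)
    t_o -= (t_o @ t) / (t @ t) * t
    w = rng.normal(size=p)
    p_o = rng.normal(size=p)
    X = np.outer(t, w) + np.outer(t_o, p_o) + 0.05 * rng.normal(size=(n, p))
    y = t + 0.05 * rng.normal(size=n)
    return scale_matrix(X), y - y.mean(), t, t_o
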