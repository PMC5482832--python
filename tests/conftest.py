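import numpy as np
import pytest

from ccsbiclust.core import ExpressionMatrix


def make_matrix(values, prefix=("g", "s")):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionMatrix(
        [f"{prefix[0]}{i}" for i in range(n)],
        [f"{prefix[1]}{j}" for j in range(m)],
        values,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def noise_matrix(rng):
    """Pure i.i.d. Gaussian 20×10 matrix."""
    return make_matrix(rng.normal(size=(20, 10)))


@pytest.fixture
def affine_block_matrix(rng):
    """30 noise genes plus a planted 6-gene affine family over 5 columns.

    Rows 0..5 are scale·base + shift over columns 0..4 (strong amplitude),
    noise elsewhere; the family is mutually correlated (|r| ≈ 1) over those
    columns only.
    """
    values = rng.normal(scale=1.0, size=(36, 12))
    base = rng.normal(scale=3.0, size=5)
    scales = [2.0, 1.5, -1.8, 2.5, 1.2, 3.0]
    shifts = [0.0, 1.0, -1.0, 2.0, 0.5, -0.5]
    for r, (a, c) in enumerate(zip(scales, shifts)):
        values[r, :5] = a * base + c
    return make_matrix(values), list(range(6)), list(range(5))
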