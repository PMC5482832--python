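"""Synthetic expression matrices with planted biclusters, plus ground truth.

Two planted models, in the style of the standard bicluster benchmarks:

* **constant** — a submatrix holding one constant value (plus optional cell
  noise) against an i.i.d. Gaussian background.  Such a block has no internal
  correlation structure over its own columns; a correlation-based search
  detects it through the contrast between the block value and the background.
* **shift-scale** — each block row is an affine transform ``scale·base +
  shift`` of one shared base row (plus cell noise), so within-block rows are
  near-perfectly correlated over the block's columns.  A fraction of rows get
  a negative scale, planting negative-correlation structure.

Planted blocks are pairwise row- and column-disjoint by default, and the row
and column index sets are drawn scattered (not contiguous), so detection
cannot exploit adjacency.  Generation is a pure function of the parameter
set, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import Bicluster, ExpressionMatrix

__all__ = [
    "SyntheticDataset",
    "generate_constant",
    "generate_shift_scale",
    "table1_preset",
    "PRESETS",
    "InfeasiblePlacementError",
]


class InfeasiblePlacementError(ValueError):
    """The requested blocks cannot be placed disjointly in the matrix."""


@dataclass
class SyntheticDataset:
    """A generated matrix together with its planted truth."""

    matrix: ExpressionMatrix
    truth: list[Bicluster]
    spec: dict[str, Any] = field(default_factory=dict)


def _block_sizes(total: int, k: int, divisor: int, rng: np.random.Generator,
                 size_range: tuple[int, int] | None) -> list[int]:
    """Per-block sizes: total/divisor jittered ±20%, or a user range."""
    if size_range is not None:
        lo, hi = size_range
        return [int(rng.integers(lo, hi + 1)) for _ in range(k)]
    base = total / divisor
    lo = max(2, int(round(base * 0.8)))
    hi = max(lo, int(round(base * 1.2)))
    return [int(rng.integers(lo, hi + 1)) for _ in range(k)]


def _place_disjoint(total: int, sizes: list[int], rng: np.random.Generator,
                    axis_name: str) -> list[np.ndarray]:
    """Draw pairwise-disjoint scattered index sets of the given sizes."""
    if sum(sizes) > total:
        raise InfeasiblePlacementError(
            f"{sum(sizes)} {axis_name} requested for {len(sizes)} disjoint "
            f"blocks but the matrix has only {total}"
        )
    pool = rng.permutation(total)
    out, start = [], 0
    for size in sizes:
        out.append(np.sort(pool[start:start + size]))
        start += size
    return out


def _finish(values: np.ndarray, row_sets, col_sets, spec: dict) -> SyntheticDataset:
    n_rows, n_cols = values.shape
    gene_ids = [f"g{i:04d}" for i in range(n_rows)]
    sample_ids = [f"s{j:04d}" for j in range(n_cols)]
    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    truth = [
        Bicluster(
            genes=tuple(gene_ids[i] for i in rows),
            samples=tuple(sample_ids[j] for j in cols),
            bscore=0.0,
            base_gene=None,
            pattern_class=spec["type"],
        )
        for rows, cols in zip(row_sets, col_sets)
    ]
    return SyntheticDataset(matrix=matrix, truth=truth, spec=spec)


def generate_constant(
    n_rows: int,
    n_cols: int,
    k: int,
    row_range: tuple[int, int] | None = None,
    col_range: tuple[int, int] | None = None,
    bg_sd: float = 1.0,
    signal_value: float = 5.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticDataset:
    """Matrix with ``k`` disjoint constant-valued blocks on Gaussian noise.

    Background cells are N(0, bg_sd²); each planted cell is
    ``signal_value`` + N(0, noise_sd²).  Default block sizes are about
    n_rows/(k+2) × n_cols/(k+1), jittered ±20%.
    """
    rng = np.random.default_rng(seed)
    row_sizes = _block_sizes(n_rows, k, k + 2, rng, row_range)
    col_sizes = _block_sizes(n_cols, k, k + 1, rng, col_range)
    row_sets = _place_disjoint(n_rows, row_sizes, rng, "rows")
    col_sets = _place_disjoint(n_cols, col_sizes, rng, "columns")
    values = rng.normal(0.0, bg_sd, size=(n_rows, n_cols))
    for rows, cols in zip(row_sets, col_sets):
        block = signal_value + (
            rng.normal(0.0, noise_sd, size=(len(rows), len(cols)))
            if noise_sd > 0 else 0.0
        )
        values[np.ix_(rows, cols)] = block
    spec = dict(
        type="constant", n_rows=n_rows, n_cols=n_cols, k=k,
        row_range=row_range, col_range=col_range, bg_sd=bg_sd,
        signal_value=signal_value, noise_sd=noise_sd, seed=seed,
    )
    return _finish(values, row_sets, col_sets, spec)


def generate_shift_scale(
    n_rows: int,
    n_cols: int,
    k: int,
    row_range: tuple[int, int] | None = None,
    col_range: tuple[int, int] | None = None,
    bg_sd: float = 1.0,
    scale_range: tuple[float, float] = (0.5, 2.0),
    shift_range: tuple[float, float] = (-2.0, 2.0),
    neg_scale_prob: float = 0.2,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticDataset:
    """Matrix with ``k`` disjoint shift-scale blocks on Gaussian noise.

    Each block draws a base row ~ N(0,1) over its columns; block row r is
    ``scale_r · base + shift_r`` + N(0, noise_sd²) with scale_r drawn from
    ``scale_range`` (sign flipped with probability ``neg_scale_prob``) and
    shift_r from ``shift_range``.
    """
    rng = np.random.default_rng(seed)
    row_sizes = _block_sizes(n_rows, k, k + 2, rng, row_range)
    col_sizes = _block_sizes(n_cols, k, k + 1, rng, col_range)
    row_sets = _place_disjoint(n_rows, row_sizes, rng, "rows")
    col_sets = _place_disjoint(n_cols, col_sizes, rng, "columns")
    values = rng.normal(0.0, bg_sd, size=(n_rows, n_cols))
    for rows, cols in zip(row_sets, col_sets):
        base = rng.normal(0.0, 1.0, size=len(cols))
        scales = rng.uniform(*scale_range, size=len(rows))
        flips = rng.random(len(rows)) < neg_scale_prob
        scales[flips] *= -1.0
        shifts = rng.uniform(*shift_range, size=len(rows))
        block = scales[:, None] * base[None, :] + shifts[:, None]
        if noise_sd > 0:
            block = block + rng.normal(0.0, noise_sd, size=block.shape)
        values[np.ix_(rows, cols)] = block
    spec = dict(
        type="shift-scale", n_rows=n_rows, n_cols=n_cols, k=k,
        row_range=row_range, col_range=col_range, bg_sd=bg_sd,
        scale_range=scale_range, shift_range=shift_range,
        neg_scale_prob=neg_scale_prob, noise_sd=noise_sd, seed=seed,
    )
    return _finish(values, row_sets, col_sets, spec)


#: The five benchmark presets: (type, rows, columns, planted biclusters).
#: "SS.200.5" carries an SS name but is a constant-type benchmark; the preset
#: follows its declared type.
PRESETS: dict[str, tuple[str, int, int, int]] = {
    "CNST.100.3": ("constant", 100, 75, 3),
    "SS.150.4": ("shift-scale", 150, 100, 4),
    "SS.200.5": ("constant", 200, 120, 5),
    "SS.200.6": ("shift-scale", 200, 120, 6),
    "SS.250.7": ("shift-scale", 250, 120, 7),
}


def table1_preset(name: str, seed: int = 0, **overrides) -> SyntheticDataset:
    """Generate one of the named benchmark datasets.

    ``overrides`` are forwarded to the underlying generator (noise_sd,
    bg_sd, block size ranges, ...).
    """
    try:
        kind, n_rows, n_cols, k = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    gen = generate_constant if kind == "constant" else generate_shift_scale
    return gen(n_rows=n_rows, n_cols=n_cols, k=k, seed=seed, **overrides)
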