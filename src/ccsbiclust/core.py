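"""Domain types and the masked-correlation primitive.

A gene-expression dataset is a real matrix ``D`` of shape genes × samples.
A bicluster is a pair ``(I, J)`` of a gene subset and a sample subset such
that every gene pair in ``I`` is correlated (in absolute value, above a
threshold θ) over exactly the samples ``J``.  All correlation computation in
this package goes through :func:`masked_pearson`, a Pearson coefficient
restricted to a sample subset encoded as a bit mask: means and variances are
taken over the masked samples only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MIN_SAMPLES",
    "ExpressionMatrix",
    "SampleMask",
    "Bicluster",
    "BiclusterSet",
    "DegenerateVarianceError",
    "InsufficientSamplesError",
    "UnknownGeneError",
    "masked_pearson",
    "gene_std",
]

#: Minimum number of samples for any correlation computation.  A Pearson
#: coefficient over fewer than 3 points is meaningless (with 2 points it is
#: always ±1); sample sets smaller than this are discarded during search.
MIN_SAMPLES = 3


class DegenerateVarianceError(ValueError):
    """A masked vector is constant, so its correlation is undefined."""


class InsufficientSamplesError(ValueError):
    """Fewer masked samples than the minimum required for a correlation."""


class UnknownGeneError(KeyError):
    """A gene id not present in the matrix."""


class SampleMask:
    """A bit vector over the sample axis, selecting a sample subset J.

    Parameters
    ----------
    bits
        Length-m sequence of 0/1 (or booleans).
    """

    __slots__ = ("bits",)

    def __init__(self, bits: Sequence[int] | np.ndarray):
        arr = np.asarray(bits)
        if arr.dtype != bool:
            arr = arr.astype(bool)
        self.bits: np.ndarray = arr
        self.bits.setflags(write=False)

    @classmethod
    def from_indices(cls, indices: Iterable[int], m: int) -> "SampleMask":
        bits = np.zeros(m, dtype=bool)
        bits[list(indices)] = True
        return cls(bits)

    @classmethod
    def full(cls, m: int) -> "SampleMask":
        return cls(np.ones(m, dtype=bool))

    @property
    def count(self) -> int:
        return int(self.bits.sum())

    def __len__(self) -> int:
        return self.bits.size

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def complement(self) -> "SampleMask":
        return SampleMask(~self.bits)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleMask) and np.array_equal(self.bits, other.bits)

    def __hash__(self) -> int:
        return hash(self.bits.tobytes())

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"SampleMask(count={self.count}, m={len(self)})"


class ExpressionMatrix:
    """A genes × samples expression matrix with cached per-gene statistics.

    Gene and sample identifiers are unique strings; values are finite floats.
    Per-gene means and standard deviations over all samples are cached at
    construction (population convention: divide by the sample count), because
    the sample-selection rules and the variability sort both consume them.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
    ):
        gene_ids = [str(g) for g in gene_ids]
        sample_ids = [str(s) for s in sample_ids]
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, m = values.shape
        if len(gene_ids) != n:
            raise ValueError(f"{len(gene_ids)} gene ids for {n} rows")
        if len(sample_ids) != m:
            raise ValueError(f"{len(sample_ids)} sample ids for {m} columns")
        if len(set(gene_ids)) != n:
            raise ValueError("duplicate gene ids")
        if len(set(sample_ids)) != m:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {gene_ids[bad[0]]!r}, "
                f"sample {sample_ids[bad[1]]!r}"
            )
        self.gene_ids: list[str] = gene_ids
        self.sample_ids: list[str] = sample_ids
        self.values: np.ndarray = values
        self.values.setflags(write=False)
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(sample_ids)}
        self.gene_means: np.ndarray = values.mean(axis=1)
        self.gene_stds: np.ndarray = values.std(axis=1)  # population (ddof=0)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise UnknownGeneError(gene) from None

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise KeyError(f"unknown sample id {sample!r}") from None

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def mask_for_samples(self, samples: Iterable[str]) -> SampleMask:
        return SampleMask.from_indices(
            (self.sample_index(s) for s in samples), self.n_samples
        )

    def subset_genes(self, keep: Sequence[int]) -> "ExpressionMatrix":
        """New matrix with rows ``keep`` (positional), in the given order."""
        keep = list(keep)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in keep], self.sample_ids, self.values[keep]
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_dataframe(cls, df) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=np.float64))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"ExpressionMatrix({self.n_genes} genes × {self.n_samples} samples)"


@dataclass(frozen=True)
class Bicluster:
    """A bicluster C = (I, J): a gene set over a sample set.

    ``genes`` and ``samples`` hold identifiers (never positional indices), so
    serialized biclusters survive matrix reordering.  ``pattern_class`` records
    the similarity-pattern class of the winning seed: ``up-positive`` (both seed
    genes above their means), ``down-positive`` (both below), ``negative``
    (opposite sides), or ``merged`` for the union of overlapping biclusters.
    """

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    bscore: float
    base_gene: str | None = None
    pattern_class: str = "merged"

    def __post_init__(self):
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate gene ids in bicluster")
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("duplicate sample ids in bicluster")
        if self.base_gene is not None and self.base_gene not in self.genes:
            raise ValueError("base_gene must be a member of the bicluster")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_mask(self, matrix: ExpressionMatrix) -> SampleMask:
        return matrix.mask_for_samples(self.samples)

    def gene_set(self) -> frozenset:
        return frozenset(self.genes)

    def cells(self) -> int:
        """Number of matrix cells covered: |I| × |J|."""
        return len(self.genes) * len(self.samples)


@dataclass
class BiclusterSet:
    """The output of a biclustering run: biclusters plus the θ actually used."""

    biclusters: list[Bicluster] = field(default_factory=list)
    theta_used: float = 0.8
    source: str = ""

    def __post_init__(self):
        if not (0.0 < self.theta_used <= 1.0):
            raise ValueError("theta_used must be in (0, 1]")

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def __getitem__(self, i) -> Bicluster:
        return self.biclusters[i]


def _masked_stats(x: np.ndarray, bits: np.ndarray) -> tuple[np.ndarray, float, float]:
    sub = x[bits]
    mean = sub.mean()
    dev = sub - mean
    return dev, mean, float(np.sqrt((dev * dev).sum()))


def masked_pearson(x_i: np.ndarray, x_j: np.ndarray, mask: SampleMask) -> float:
    """Pearson correlation of two expression vectors over masked samples only.

    Means and deviations are computed over the samples whose mask bit is set;
    unmasked samples contribute nothing.

    Raises
    ------
    InsufficientSamplesError
        If fewer than :data:`MIN_SAMPLES` bits are set.
    DegenerateVarianceError
        If either masked vector is constant.
    """
    x_i = np.asarray(x_i, dtype=np.float64)
    x_j = np.asarray(x_j, dtype=np.float64)
    if x_i.shape != x_j.shape or x_i.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if len(mask) != x_i.size:
        raise ValueError("mask length does not match vector length")
    if mask.count < MIN_SAMPLES:
        raise InsufficientSamplesError(
            f"mask selects {mask.count} samples; need at least {MIN_SAMPLES}"
        )
    dev_i, _, norm_i = _masked_stats(x_i, mask.bits)
    dev_j, _, norm_j = _masked_stats(x_j, mask.bits)
    if norm_i == 0.0 or norm_j == 0.0:
        raise DegenerateVarianceError("constant masked vector: correlation undefined")
    r = float(np.dot(dev_i, dev_j) / (norm_i * norm_j))
    # guard against round-off straying outside [-1, 1]
    return max(-1.0, min(1.0, r))


def gene_std(matrix: ExpressionMatrix, gene: str) -> float:
    """Standard deviation of a gene's expression over all samples.

    Population convention (divide by the sample count), matching the cached
    statistics used for the variability sort.
    """
    return float(matrix.gene_stds[matrix.gene_index(gene)])


def standardized_rows(matrix_values: np.ndarray, bits: np.ndarray) -> np.ndarray:
    """Rows standardized over the masked columns, ready for correlation.

    Returns ``Z`` of shape (n_genes, mask.count) such that ``Z[i] @ Z[j]`` is
    the masked Pearson correlation of rows i and j.  Rows that are constant
    over the masked columns come back as all-NaN: any correlation involving
    them is undefined and callers must treat it as "not correlated".
    """
    sub = matrix_values[:, bits]
    dev = sub - sub.mean(axis=1, keepdims=True)
    norm = np.sqrt((dev * dev).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = dev / norm[:, None]
    z[norm == 0.0] = np.nan
    return z
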