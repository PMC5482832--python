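"""BScore: how condition-specific is a candidate bicluster's coexpression.

Let ``N`` be the set of gene pairs (from the candidate's gene set) whose
absolute masked correlation exceeds θ over the candidate's samples, and ``M``
the set of pairs exceeding θ over the remaining samples.  Then

    BScore = |N ∩ M| / |N ∪ M|

A small BScore means the coexpression holds inside the bicluster's samples
but not outside — the bicluster is condition-specific.  The search accepts
only candidates with BScore below 0.01.

Degenerate correlations (a masked vector that is constant, or a mask with
fewer than the minimum number of samples) count as "not correlated", which
keeps BScore well-defined when a candidate spans nearly all samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .core import MIN_SAMPLES, ExpressionMatrix, SampleMask, standardized_rows

__all__ = ["CorrelatedPairSet", "correlated_pairs", "bscore"]


@dataclass(frozen=True)
class CorrelatedPairSet:
    """Unordered gene-id pairs correlated above θ over a sample mask."""

    pairs: frozenset
    sample_mask: SampleMask
    theta: float

    def __len__(self) -> int:
        return len(self.pairs)


def _correlated_pair_indices(
    values: np.ndarray, row_indices: Sequence[int], bits: np.ndarray, theta: float
) -> set[tuple[int, int]]:
    """Index pairs (positions into row_indices) with |r| > theta over bits."""
    if bits.sum() < MIN_SAMPLES:
        return set()
    z = standardized_rows(values[list(row_indices)], bits)
    corr = z @ z.T
    out: set[tuple[int, int]] = set()
    k = len(row_indices)
    for a, b in combinations(range(k), 2):
        r = corr[a, b]
        if np.isfinite(r) and abs(r) > theta:
            out.add((a, b))
    return out


def correlated_pairs(
    matrix: ExpressionMatrix,
    genes: Iterable[str],
    mask: SampleMask,
    theta: float,
) -> CorrelatedPairSet:
    """All unordered pairs from ``genes`` with |masked Pearson| > θ over ``mask``.

    Pairs whose masked correlation is undefined (constant vector, too few
    samples) are counted as not correlated rather than raising.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if not (0.0 < theta <= 1.0):
        raise ValueError("theta must be in (0, 1]")
    idx = [matrix.gene_index(g) for g in genes]
    hits = _correlated_pair_indices(matrix.values, idx, mask.bits, theta)
    pairs = frozenset(frozenset((genes[a], genes[b])) for a, b in hits)
    return CorrelatedPairSet(pairs=pairs, sample_mask=mask, theta=theta)


def bscore(
    matrix: ExpressionMatrix,
    genes: Iterable[str],
    mask: SampleMask,
    theta: float,
) -> float:
    """BScore = |N ∩ M| / |N ∪ M| for a candidate (genes, mask) at threshold θ.

    ``N`` uses the mask, ``M`` its complement; the same θ applies to both.
    Returns 0 when both N and M are empty (an unverifiable candidate is
    treated as maximally condition-specific; the search itself never produces
    one, because a seed pair guarantees N is nonempty).
    """
    genes = list(genes)
    n_set = correlated_pairs(matrix, genes, mask, theta).pairs
    m_set = correlated_pairs(matrix, genes, mask.complement(), theta).pairs
    union = n_set | m_set
    if not union:
        return 0.0
    return len(n_set & m_set) / len(union)
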