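"""The CCS search: per-base-gene bicluster discovery, merging, adaptive θ.

For each *base gene* (taken from the matrix after sorting rows by expression
variability, most variable first), the search pairs the base with every later
gene, derives up to three candidate sample sets from the sample-selection
rules, and for each sample set whose seed correlation clears θ grows a gene
set greedily: a gene joins if its absolute masked correlation with EVERY
current member exceeds θ.  The sample set is frozen at seed time; growth
never re-selects samples.  Each grown candidate is scored with BScore, and
the base gene keeps its most condition-specific candidate (smallest BScore
below 0.01; ties broken by larger gene set, then by encounter order).
Finally, overlapping biclusters are merged whenever their union still scores
below the BScore bound.

The search is a pure function of (matrix, config): repeated runs are
bit-identical, and because per-base searches are independent and merging
happens in sorted base-gene order, any parallel execution order over base
genes yields the same result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Sequence

import numpy as np

from .core import (
    MIN_SAMPLES,
    Bicluster,
    BiclusterSet,
    ExpressionMatrix,
    SampleMask,
    standardized_rows,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "sort_by_variability",
    "grow_bicluster",
    "find_bicluster_for_base",
    "merge_biclusters",
    "run_ccs",
]

#: Pattern-class labels, indexed by rule number - 1.
_CLASS_LABELS = ("up-positive", "down-positive", "negative")


@dataclass(frozen=True)
class SearchConfig:
    """Tunable knobs of the CCS search.

    theta
        Minimum absolute pairwise correlation for bicluster membership.
    base_number
        How many of the most variable genes seed a search: a positive int,
        ``"all"``, or None for the default policy (all genes when the matrix
        has at most 2,000 rows, else 1,000 — a cap that bounds search time on
        large expression datasets).
    min_samples
        Smallest usable sample set; correlation needs at least 3 points.
    min_genes
        Smallest reportable bicluster (default 3).  A seed pair that attracts
        no further gene is discarded: its BScore is computed over a single
        gene pair and is 0 or 1 by construction, so condition specificity is
        unverifiable, and the sign-conditioned sample selection inflates pair
        correlations enough that pair-only candidates on noisy data are
        overwhelmingly selection artifacts.  Set to 2 to report bare pairs.
    bscore_threshold
        Candidates must score strictly below this to be kept (0.01).
    theta_step
        Decrement applied to θ when adaptive_theta is on and a run comes back
        empty (0.05).
    adaptive_theta
        Retry at θ − 0.05, θ − 0.10, … until a bicluster is found or θ ≤ 0.
    random_seed
        Unused by the search itself, which is deterministic; carried for
        provenance alongside synthetic-data generation.
    """

    theta: float = 0.8
    base_number: int | str | None = None
    min_samples: int = MIN_SAMPLES
    min_genes: int = 3
    bscore_threshold: float = 0.01
    theta_step: float = 0.05
    adaptive_theta: bool = True
    random_seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.theta <= 1.0):
            raise ValueError("theta must be in (0, 1]")
        if self.theta_step <= 0:
            raise ValueError("theta_step must be positive")
        if self.bscore_threshold <= 0:
            raise ValueError("bscore_threshold must be positive")
        if isinstance(self.base_number, str) and self.base_number != "all":
            raise ValueError("base_number must be an int, 'all', or None")
        if isinstance(self.base_number, int) and self.base_number < 1:
            raise ValueError("base_number must be >= 1")
        if self.min_samples < 3:
            raise ValueError("min_samples must be >= 3")
        if self.min_genes < 2:
            raise ValueError("min_genes must be >= 2")

    def resolve_base_number(self, n_genes: int) -> int:
        if self.base_number is None:
            return n_genes if n_genes <= 2000 else 1000
        if self.base_number == "all":
            return n_genes
        return min(self.base_number, n_genes)


def sort_by_variability(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Reorder rows by standard deviation, descending; stable on ties."""
    order = np.argsort(-matrix.gene_stds, kind="stable")
    return matrix.subset_genes(order.tolist())


def _grow_indices(
    z: np.ndarray, i: int, j: int, theta: float
) -> list[int]:
    """Greedy growth from seed rows (i, j) given mask-standardized rows z.

    Scans candidates in row order; a row joins iff its absolute correlation
    with every current member exceeds theta.  Rows that are constant over the
    mask are all-NaN in z, so every comparison involving them is False and
    they can never join.  Returns member row indices in increasing order.
    """
    n = z.shape[0]
    # ok[p] == True while p is correlated above theta with all members so far
    ok = (np.abs(z @ z[i]) > theta) & (np.abs(z @ z[j]) > theta)
    members = [i, j]
    member_set = {i, j}
    for p in range(n):
        if p in member_set or not ok[p]:
            continue
        members.append(p)
        member_set.add(p)
        ok &= np.abs(z @ z[p]) > theta
    members.sort()
    return members


def _pairs_above(z: np.ndarray, rows: Sequence[int], theta: float) -> set:
    """Unordered row-index pairs with |r| > theta, given standardized rows."""
    sub = z[list(rows)]
    corr = sub @ sub.T
    out = set()
    for a, b in combinations(range(len(rows)), 2):
        r = corr[a, b]
        if np.isfinite(r) and abs(r) > theta:
            out.add((rows[a], rows[b]))
    return out


def _bscore_indices(
    values: np.ndarray, rows: Sequence[int], bits: np.ndarray, theta: float
) -> float:
    """BScore on row indices; mirrors scoring.bscore on the fast path."""
    rows = list(rows)
    sub = values[rows]
    if bits.sum() >= MIN_SAMPLES:
        n_set = _pairs_above(standardized_rows(sub, bits), range(len(rows)), theta)
    else:
        n_set = set()
    cbits = ~bits
    if cbits.sum() >= MIN_SAMPLES:
        m_set = _pairs_above(standardized_rows(sub, cbits), range(len(rows)), theta)
    else:
        m_set = set()
    union = n_set | m_set
    if not union:
        return 0.0
    return len(n_set & m_set) / len(union)


def grow_bicluster(
    matrix: ExpressionMatrix,
    seed: tuple[str, str],
    mask: SampleMask,
    theta: float,
) -> tuple[str, ...]:
    """Grow a gene set from a seed pair over a fixed sample mask.

    The seed pair must already satisfy |r| > θ over the mask.  Candidate
    genes are scanned in matrix row order (the caller is expected to pass a
    variability-sorted matrix, so high-variability genes are considered
    first).  Returns gene ids in matrix row order.
    """
    i = matrix.gene_index(seed[0])
    j = matrix.gene_index(seed[1])
    z = standardized_rows(matrix.values, mask.bits)
    r = z[i] @ z[j]
    if not (np.isfinite(r) and abs(r) > theta):
        raise ValueError("seed pair does not satisfy |r| > theta over the mask")
    members = _grow_indices(z, i, j, theta)
    return tuple(matrix.gene_ids[p] for p in members)


def _split_bits(
    dev_i: np.ndarray, dev_j: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rule 1–3 sample sets as boolean arrays, from mean deviations."""
    return (
        (dev_i > 0) & (dev_j > 0),
        (dev_i < 0) & (dev_j < 0),
        dev_i * dev_j < 0,
    )


def _seed_corr(values: np.ndarray, i: int, j: int, bits: np.ndarray) -> float:
    """Masked correlation of rows i, j; NaN when degenerate."""
    z = standardized_rows(values[[i, j]], bits)
    return float(z[0] @ z[1])


def find_bicluster_for_base(
    matrix: ExpressionMatrix,
    base_index: int,
    config: SearchConfig | None = None,
) -> Bicluster | None:
    """Best (most condition-specific) bicluster seeded at one base gene.

    The matrix must already be variability-sorted.  Partners range over genes
    after the base in row order; for each partner the three rule-derived
    sample sets are tried.  Among grown candidates scoring below the BScore
    bound, the smallest BScore wins; ties go to the larger gene set, then to
    the earlier candidate in (partner, rule) encounter order.  Returns None
    when no candidate qualifies.
    """
    config = config or SearchConfig()
    values = matrix.values
    n = matrix.n_genes
    theta = config.theta
    dev = values - matrix.gene_means[:, None]
    i = base_index
    if matrix.gene_stds[i] == 0.0:
        return None

    best: tuple[float, tuple[int, ...], int] | None = None  # (score, rows, k)
    n_candidates = 0
    for j in range(i + 1, n):
        if matrix.gene_stds[j] == 0.0:
            continue
        for k, bits in enumerate(_split_bits(dev[i], dev[j])):
            if bits.sum() < config.min_samples:
                continue
            r = _seed_corr(values, i, j, bits)
            if not (np.isfinite(r) and abs(r) > theta):
                continue
            z = standardized_rows(values, bits)
            rows = tuple(_grow_indices(z, i, j, theta))
            if len(rows) < config.min_genes:
                continue
            score = _bscore_indices(values, rows, bits, theta)
            if score >= config.bscore_threshold:
                continue
            n_candidates += 1
            if (
                best is None
                or score < best[0]
                or (score == best[0] and len(rows) > len(best[1]))
            ):
                best = (score, rows, k)
                best_bits = bits
    if best is None:
        return None
    score, rows, k = best
    logger.debug(
        "base %s: best BScore %.4g from %d candidates",
        matrix.gene_ids[i], score, n_candidates,
    )
    return Bicluster(
        genes=tuple(matrix.gene_ids[p] for p in rows),
        samples=tuple(
            s for s, b in zip(matrix.sample_ids, best_bits) if b
        ),
        bscore=score,
        base_gene=matrix.gene_ids[i],
        pattern_class=_CLASS_LABELS[k],
    )


def _union_bicluster(
    matrix: ExpressionMatrix, a: Bicluster, b: Bicluster, score: float
) -> Bicluster:
    """Union of two biclusters, ids kept in matrix row/column order."""
    genes = set(a.genes) | set(b.genes)
    samples = set(a.samples) | set(b.samples)
    return Bicluster(
        genes=tuple(g for g in matrix.gene_ids if g in genes),
        samples=tuple(s for s in matrix.sample_ids if s in samples),
        bscore=score,
        base_gene=a.base_gene,
        pattern_class="merged" if a.genes != b.genes else a.pattern_class,
    )


def merge_biclusters(
    matrix: ExpressionMatrix,
    biclusters: Sequence[Bicluster],
    config: SearchConfig | None = None,
) -> list[Bicluster]:
    """Merge overlapping biclusters while the union stays condition-specific.

    A single outer pass in list order: for each live pair (A, B) with
    intersecting gene sets, if the BScore of (genes A ∪ B, samples A ∪ B)
    stays below the bound, A is replaced by the union (and used as such for
    the remaining comparisons of the pass) and B is dropped.  Surviving
    biclusters carry a BScore recomputed on their final gene and sample sets.
    No fixed-point iteration beyond what the nested loops produce.
    """
    config = config or SearchConfig()
    theta = config.theta
    live: list[Bicluster | None] = list(biclusters)
    for a_idx in range(len(live)):
        if live[a_idx] is None:
            continue
        for b_idx in range(len(live)):
            if b_idx == a_idx or live[b_idx] is None or live[a_idx] is None:
                continue
            a = live[a_idx]
            b = live[b_idx]
            if not (set(a.genes) & set(b.genes)):
                continue
            genes = set(a.genes) | set(b.genes)
            rows = [matrix.gene_index(g) for g in matrix.gene_ids if g in genes]
            bits = matrix.mask_for_samples(
                set(a.samples) | set(b.samples)
            ).bits
            score = _bscore_indices(matrix.values, rows, bits, theta)
            if score < config.bscore_threshold:
                live[a_idx] = _union_bicluster(matrix, a, b, score)
                live[b_idx] = None
    out = []
    for bc in live:
        if bc is None:
            continue
        rows = [matrix.gene_index(g) for g in bc.genes]
        bits = bc.sample_mask(matrix).bits
        final_score = _bscore_indices(matrix.values, rows, bits, theta)
        out.append(replace(bc, bscore=final_score))
    return out


def run_ccs(
    matrix: ExpressionMatrix,
    config: SearchConfig | None = None,
    source: str = "",
) -> BiclusterSet:
    """Full CCS run: variability sort, per-base search, merge, adaptive θ.

    When ``config.adaptive_theta`` is set and a pass finds nothing, θ is
    lowered by ``theta_step`` and the pass repeats, until a bicluster appears
    or θ would drop to 0; ``theta_used`` on the result records the θ of the
    final pass.
    """
    config = config or SearchConfig()
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise ValueError("matrix must be nonempty")
    sorted_matrix = sort_by_variability(matrix)
    base_number = config.resolve_base_number(matrix.n_genes)

    theta = config.theta
    step = 0
    while True:
        cfg = replace(config, theta=theta)
        logger.info("CCS pass at theta=%.2f over %d base genes", theta, base_number)
        found = []
        for i in range(base_number):
            bc = find_bicluster_for_base(sorted_matrix, i, cfg)
            if bc is not None:
                found.append(bc)
        merged = merge_biclusters(sorted_matrix, found, cfg)
        logger.info(
            "theta=%.2f: %d per-base biclusters, %d after merging",
            theta, len(found), len(merged),
        )
        if merged or not config.adaptive_theta:
            return BiclusterSet(biclusters=merged, theta_used=theta, source=source)
        step += 1
        next_theta = round(config.theta - step * config.theta_step, 10)
        if next_theta <= 0:
            return BiclusterSet(biclusters=[], theta_used=theta, source=source)
        theta = next_theta
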