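"""Recovery and Relevance: match scores against an expected bicluster set.

Given found biclusters F and expected (planted) biclusters E:

* **Recovery** = mean over E of the best similarity to any member of F —
  1 when every expected bicluster is found.
* **Relevance** = mean over F of the best similarity to any member of E —
  1 when every found bicluster is expected.

Similarity between two biclusters defaults to the Jaccard index of their
cell sets, where a bicluster (I, J) covers the cells I × J; a gene-set-only
Jaccard is available for cross-checking (``mode="genes"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import Bicluster, BiclusterSet

__all__ = [
    "EvaluationResult",
    "bicluster_similarity",
    "recovery",
    "relevance",
    "evaluate",
]


@dataclass
class EvaluationResult:
    recovery: float
    relevance: float
    per_expected_best: list[float] = field(default_factory=list)
    per_found_best: list[float] = field(default_factory=list)
    mode: str = "cells"


def bicluster_similarity(a: Bicluster, b: Bicluster, mode: str = "cells") -> float:
    """Jaccard index of two biclusters.

    ``mode="cells"`` (default): over gene×sample cell sets; because a
    bicluster's cells are a product set, |A ∩ B| = |genes∩| · |samples∩|.
    ``mode="genes"``: over gene sets only.
    """
    if mode == "cells":
        gi = len(set(a.genes) & set(b.genes))
        si = len(set(a.samples) & set(b.samples))
        inter = gi * si
        union = a.cells() + b.cells() - inter
    elif mode == "genes":
        inter = len(set(a.genes) & set(b.genes))
        union = len(set(a.genes) | set(b.genes))
    else:
        raise ValueError(f"unknown similarity mode {mode!r}")
    if union == 0:
        return 0.0
    return inter / union


def _as_list(biclusters: BiclusterSet | Iterable[Bicluster]) -> list[Bicluster]:
    return list(biclusters)


def _best_matches(
    targets: Sequence[Bicluster], pool: Sequence[Bicluster], mode: str
) -> list[float]:
    return [
        max((bicluster_similarity(t, p, mode) for p in pool), default=0.0)
        for t in targets
    ]


def _dedup(biclusters: Sequence[Bicluster]) -> list[Bicluster]:
    """Drop exact (gene set, sample set) duplicates, keeping first occurrence.

    Duplicate found biclusters carry no extra information, and without this
    the relevance mean would be reweighted by how often the search rediscovers
    the same bicluster from different base genes.
    """
    seen = set()
    out = []
    for bc in biclusters:
        key = (frozenset(bc.genes), frozenset(bc.samples))
        if key not in seen:
            seen.add(key)
            out.append(bc)
    return out


def recovery(
    found: BiclusterSet | Iterable[Bicluster],
    expected: Sequence[Bicluster],
    mode: str = "cells",
) -> float:
    """Mean best match of each expected bicluster among the found ones."""
    expected = list(expected)
    if not expected:
        raise ValueError("expected bicluster set must be nonempty")
    found = _as_list(found)
    if not found:
        return 0.0
    scores = _best_matches(expected, found, mode)
    return sum(scores) / len(scores)


def relevance(
    found: BiclusterSet | Iterable[Bicluster],
    expected: Sequence[Bicluster],
    mode: str = "cells",
) -> float:
    """Mean best match of each found bicluster among the expected ones.

    Returns 0 for an empty found set (an algorithm that reports nothing has
    found nothing relevant).
    """
    expected = list(expected)
    if not expected:
        raise ValueError("expected bicluster set must be nonempty")
    found = _dedup(_as_list(found))
    if not found:
        return 0.0
    scores = _best_matches(found, expected, mode)
    return sum(scores) / len(scores)


def evaluate(
    found: BiclusterSet | Iterable[Bicluster],
    expected: Sequence[Bicluster],
    mode: str = "cells",
) -> EvaluationResult:
    """Recovery and Relevance with the per-bicluster best-match breakdown."""
    expected = list(expected)
    if not expected:
        raise ValueError("expected bicluster set must be nonempty")
    found = _dedup(_as_list(found))
    per_expected = _best_matches(expected, found, mode) if found else [0.0] * len(expected)
    per_found = _best_matches(found, expected, mode)
    rec = sum(per_expected) / len(per_expected)
    rel = sum(per_found) / len(per_found) if per_found else 0.0
    return EvaluationResult(
        recovery=rec,
        relevance=rel,
        per_expected_best=per_expected,
        per_found_best=per_found,
        mode=mode,
    )
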