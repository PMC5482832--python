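"""Coexpression networks over chosen sample subsets.

A bicluster found by the condition-specific search is, by construction, a
complete subgraph of the coexpression network built over its own samples:
every gene pair inside it is correlated above θ there.  Built over other
sample subsets, the same gene set is typically sparsely connected — the
module is condition-dependent.  This module builds such networks, finds
neighboring genes (non-members correlated with at least one member), and
summarizes per-condition edge densities.

Edges use a closed threshold (|r| ≥ θ), as conventional for coexpression
network displays; the bicluster search itself uses a strict > θ, and the two
thresholds are configured independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .core import (
    MIN_SAMPLES,
    Bicluster,
    BiclusterSet,
    ExpressionMatrix,
    InsufficientSamplesError,
    SampleMask,
    standardized_rows,
)

__all__ = [
    "build_network",
    "neighboring_genes",
    "module_report",
    "write_edge_list",
    "write_graphml",
]


def build_network(
    matrix: ExpressionMatrix,
    genes: Iterable[str],
    mask: SampleMask,
    theta: float,
) -> nx.Graph:
    """Coexpression graph over ``genes``: edges where |r| ≥ θ over ``mask``.

    Edge weights are the signed masked correlations.  The graph records the
    condition (sample ids) and θ as graph attributes; node roles default to
    ``"member"`` and can be overlaid by callers.
    """
    if mask.count < MIN_SAMPLES:
        raise InsufficientSamplesError(
            f"mask selects {mask.count} samples; need at least {MIN_SAMPLES}"
        )
    genes = list(genes)
    rows = [matrix.gene_index(g) for g in genes]
    z = standardized_rows(matrix.values[rows], mask.bits)
    corr = z @ z.T
    g = nx.Graph(
        theta=theta,
        condition=",".join(s for s, b in zip(matrix.sample_ids, mask.bits) if b),
    )
    for gene in genes:
        g.add_node(gene, role="member")
    for a, b in combinations(range(len(genes)), 2):
        r = corr[a, b]
        if np.isfinite(r) and abs(r) >= theta:
            g.add_edge(genes[a], genes[b], weight=float(np.clip(r, -1.0, 1.0)))
    return g


def neighboring_genes(
    matrix: ExpressionMatrix,
    bicluster: Bicluster,
    mask: SampleMask,
    theta: float,
) -> tuple[str, ...]:
    """Genes outside the bicluster correlated (|r| ≥ θ) with ≥ 1 member.

    Correlations are computed over ``mask`` — typically the bicluster's own
    samples.  Returned in matrix row order.
    """
    members = [matrix.gene_index(g) for g in bicluster.genes]
    member_set = set(members)
    z = standardized_rows(matrix.values, mask.bits)
    zm = z[members]
    out = []
    for p in range(matrix.n_genes):
        if p in member_set:
            continue
        r = zm @ z[p]
        with np.errstate(invalid="ignore"):
            if np.any(np.abs(r) >= theta):
                out.append(matrix.gene_ids[p])
    return tuple(out)


@dataclass(frozen=True)
class ModuleDensity:
    """Edge density of one bicluster's gene set over one condition."""

    bicluster_index: int
    condition_index: int
    n_genes: int
    n_edges: int
    density: float


def module_report(
    matrix: ExpressionMatrix,
    biclusters: BiclusterSet | Sequence[Bicluster],
    conditions: Sequence[SampleMask],
    theta: float = 0.8,
) -> list[ModuleDensity]:
    """Within-gene-set edge density of each bicluster under each condition.

    Over a bicluster's own samples a pre-merge bicluster is fully connected
    (density 1); over unrelated conditions the density is typically much
    lower — which is what makes the module condition-dependent.
    """
    out = []
    for ci, mask in enumerate(conditions):
        for bi, bc in enumerate(biclusters):
            g = build_network(matrix, bc.genes, mask, theta)
            n = g.number_of_nodes()
            possible = n * (n - 1) // 2
            e = g.number_of_edges()
            out.append(
                ModuleDensity(
                    bicluster_index=bi,
                    condition_index=ci,
                    n_genes=n,
                    n_edges=e,
                    density=e / possible if possible else 0.0,
                )
            )
    return out


def annotate_roles(
    graph: nx.Graph, biclusters: Sequence[Bicluster]
) -> nx.Graph:
    """Label nodes as member-of-bicluster-k / shared / neighbor in place."""
    membership: dict[str, list[int]] = {}
    for k, bc in enumerate(biclusters):
        for gene in bc.genes:
            membership.setdefault(gene, []).append(k)
    for node in graph.nodes:
        ks = membership.get(node)
        if ks is None:
            graph.nodes[node]["role"] = "neighbor"
        elif len(ks) == 1:
            graph.nodes[node]["role"] = f"member-of-bicluster-{ks[0]}"
        else:
            graph.nodes[node]["role"] = "shared"
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    """Weighted edge list as 3-column TSV (gene_a, gene_b, correlation)."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['weight']:.6f}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
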