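"""Dependency calling, set overlap statistics and interaction-network summaries.

Dependencies are called from Chronos-style gene-effect matrices (score
strictly below -0.5 in at least 3 of the panel's cell lines by default, the
">2/7" rule for the seven-line medulloblastoma panel). Drug-downregulated
gene sets are intersected with the dependency set; overlap fractions between
treatments are compared by two-sided Fisher's exact test. Interaction
networks arrive as confidence-weighted edge lists (no remote service
queries); connectivity of a gene set is summarized on the induced subgraph
with a size-matched permutation null for the edge count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEPENDENCY_THRESHOLD = -0.5
MIN_DEPENDENT_LINES = 3  # ">2/7" of the seven-line panel
MEDIUM_CONFIDENCE = 0.4


def call_dependencies(
    dep: pd.DataFrame,
    threshold: float = DEPENDENCY_THRESHOLD,
    min_lines: int = MIN_DEPENDENT_LINES,
) -> set[str]:
    """Genes with effect score strictly below ``threshold`` in >= min_lines lines.

    NA scores are ignored per line (a line with a missing score neither
    supports nor blocks the call).
    """
    if dep.shape[0] == 0 or dep.shape[1] == 0:
        raise ValueError("empty dependency matrix")
    if min_lines > dep.shape[1]:
        raise ValueError("min_lines exceeds the number of cell lines")
    hits = (dep < threshold).sum(axis=1)  # NaN comparisons are False
    return set(dep.index[hits >= min_lines])


@dataclass(frozen=True)
class OverlapResult:
    query_size: int
    overlap: int
    fraction: float
    table: tuple[tuple[int, int], tuple[int, int]]
    fisher_p: float | None = None


def overlap_fraction(query_genes, dependency_set, universe=None) -> OverlapResult:
    """Fraction of the query falling in the dependency set, with 2x2 counts.

    The 2x2 table is (in query / not in query) x (dependent / not); rows
    outside an explicit universe are ignored when one is supplied.
    """
    query = set(query_genes)
    dep = set(dependency_set)
    if universe is not None:
        universe = set(universe)
        query &= universe
        dep &= universe
    if not query:
        raise ValueError("empty query gene set")
    overlap = len(query & dep)
    if universe is None:
        universe = query | dep
    a, b = overlap, len(query) - overlap
    c = len(dep - query)
    d = len(universe) - a - b - c
    return OverlapResult(
        query_size=len(query),
        overlap=overlap,
        fraction=overlap / len(query),
        table=((a, b), (c, d)),
    )


def compare_overlap_fractions(result_a: OverlapResult, result_b: OverlapResult) -> float:
    """Two-sided Fisher p for 'is the dependency fraction different?'.

    The compared table is overlap vs non-overlap counts of the two queries —
    the contrast behind statements like '19.4% of genes downregulated by one
    compound were dependencies vs 8.6% for another'.
    """
    table = [
        [result_a.overlap, result_a.query_size - result_a.overlap],
        [result_b.overlap, result_b.query_size - result_b.overlap],
    ]
    return fisher_two_sided(table)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p under the probability-ordering definition.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's (within
    a small relative tolerance against floating-point ties) — the convention
    of standard statistical software.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    t = t.astype(int)
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        warnings.warn("zero margin in 2x2 table; p = 1 by convention", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


@dataclass(frozen=True)
class SubgraphStats:
    n_genes: int
    n_edges: int
    mean_degree: float
    connected_fraction: float
    largest_component_fraction: float
    permutation_z: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None


def load_graph(edges: pd.DataFrame, min_confidence: float = MEDIUM_CONFIDENCE) -> nx.Graph:
    """Undirected graph from an edge list (gene_a, gene_b, confidence).

    Edges below ``min_confidence`` (the 'medium confidence' cut by default)
    and self-loops are dropped.
    """
    required = {"gene_a", "gene_b", "confidence"}
    if missing := required - set(edges.columns):
        raise ValueError(f"edge list missing columns: {sorted(missing)}")
    if ((edges["confidence"] < 0) | (edges["confidence"] > 1)).any():
        raise ValueError("confidence must lie in [0, 1]")
    keep = edges[(edges["confidence"] >= min_confidence) & (edges["gene_a"] != edges["gene_b"])]
    graph = nx.Graph()
    for a, b, c in keep[["gene_a", "gene_b", "confidence"]].itertuples(index=False):
        graph.add_edge(a, b, confidence=float(c))
    return graph


def _induced_edge_count(graph: nx.Graph, genes: set) -> int:
    return graph.subgraph([g for g in genes if g in graph]).number_of_edges()


def subgraph_stats(
    graph: nx.Graph,
    genes,
    n_permutations: int = 0,
    seed: int = 0,
) -> SubgraphStats:
    """Connectivity summary of the subgraph induced by a gene set.

    Genes absent from the graph count as isolated nodes. With
    ``n_permutations`` > 0, the induced edge count is compared with
    size-matched random gene draws from the graph's node universe and
    reported as a z-score (degree matching is not attempted).
    """
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise ValueError("empty gene set")
    present = [g for g in genes if g in graph]
    sub = graph.subgraph(present)
    n_edges = sub.number_of_edges()
    degrees = dict(sub.degree())
    connected = [g for g in present if degrees.get(g, 0) > 0]
    components = list(nx.connected_components(sub)) if present else []
    largest = max((len(c) for c in components), default=0)

    z = null_mean = null_sd = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        nodes = np.array(sorted(graph.nodes()))
        if len(nodes) < len(genes):
            raise ValueError("gene set larger than the graph's node universe")
        null_counts = np.array(
            [
                _induced_edge_count(graph, set(rng.choice(nodes, size=len(genes), replace=False)))
                for _ in range(n_permutations)
            ],
            dtype=float,
        )
        null_mean = float(null_counts.mean())
        null_sd = float(null_counts.std(ddof=1))
        z = float((n_edges - null_mean) / null_sd) if null_sd > 0 else float("inf")

    return SubgraphStats(
        n_genes=len(genes),
        n_edges=n_edges,
        mean_degree=2.0 * n_edges / len(genes),
        connected_fraction=len(connected) / len(genes),
        largest_component_fraction=largest / len(genes),
        permutation_z=z,
        null_mean=null_mean,
        null_sd=null_sd,
    )
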