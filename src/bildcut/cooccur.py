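"""Co-occurrence graph of reference sequences across outlier sets.

Two references that repeatedly land in the same query's outlier set are
candidates for taxonomic refinement: connected components of the
min-weight-filtered graph tend to track genera, and components mixing
genera flag regions of the gene (or of the taxonomy) that cannot be
told apart.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx

from bildcut.taxonomy import Lineage


def build_graph(
    outlier_sets: Iterable[Sequence[str]],
    min_weight: int = 20,
) -> nx.Graph:
    """Weighted undirected graph over reference ids.

    The weight of edge (u, v) is the number of outlier sets containing
    both u and v — membership per set is binary, so a duplicate id
    within one set still counts once.  Edges below ``min_weight`` are
    removed and isolated nodes dropped."""
    pair_counts: Counter[tuple[str, str]] = Counter()
    for s in outlier_sets:
        for u, v in combinations(sorted(set(s)), 2):
            pair_counts[(u, v)] += 1
    graph = nx.Graph()
    for (u, v), w in pair_counts.items():
        if w >= min_weight:
            graph.add_edge(u, v, weight=w)
    return graph


def annotate_genus(graph: nx.Graph, taxmap: Mapping[str, Lineage]) -> nx.Graph:
    """Attach a 'genus' node attribute from the deepest lineage label."""
    for node in graph.nodes:
        lineage = taxmap.get(node)
        graph.nodes[node]["genus"] = lineage.ranks[-1] if lineage and lineage.depth else ""
    return graph


def connected_components(graph: nx.Graph) -> list[set[str]]:
    """Components of the (filtered) graph, ordered by smallest member id.

    An edgeless graph yields an empty list, matching the convention that
    isolated nodes are dropped before component analysis."""
    comps = [
        set(c)
        for c in nx.connected_components(graph)
        if any(graph.degree(n) > 0 for n in c)
    ]
    return sorted(comps, key=lambda c: min(c))


def write_edge_list(graph: nx.Graph, handle) -> None:
    """TSV edge list: u, v, weight — deterministic lexicographic order."""
    for u, v, w in sorted(
        (min(a, b), max(a, b), d["weight"]) for a, b, d in graph.edges(data=True)
    ):
        handle.write(f"{u}\t{v}\t{w}\n")


def write_graphml(graph: nx.Graph, path: str) -> None:
    """GraphML export for external visualisation tools (Gephi-compatible)."""
    nx.write_graphml(graph, path)
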