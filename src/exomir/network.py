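"""Degree tabulation and hub identification on interaction networks.

Hubs — highly connected nodes in a protein-protein interaction network —
are taken as functionally central. The analysis here is deliberately
simple: the edge list is ingested as an undirected simple graph, the number
of interactions (degree) is tabulated per node, and nodes are ranked by
degree (ties broken lexicographically for determinism). Functional
categories (named gene sets) can be overlaid as node labels. Interaction-
enrichment statistics of network servers are not reimplemented; their
exported edge lists are the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from sklearn.base import BaseEstimator

from .io import EdgeList, GeneSet, ValidationError


@dataclass
class NetworkSummary:
    """Per-node degrees, hub ranking, and optional category labels."""

    degrees: pd.Series
    top_hubs: list[str]
    connected_node_count: int
    isolated_nodes: list[str] = field(default_factory=list)
    categories: dict[str, set[str]] = field(default_factory=dict)
    category_counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"degree": self.degrees})
        if self.categories:
            out["categories"] = [
                ",".join(sorted(self.categories.get(n, set()))) for n in out.index
            ]
        return out


def degree_table(
    g: EdgeList, universe: Iterable[str] | None = None, n_top: int | None = None
) -> NetworkSummary:
    """Tabulate the number of interactions for each node.

    Nodes with degree >= 1 are the interconnected set; nodes of a supplied
    ``universe`` absent from any edge are reported as isolated. Hubs are
    ranked by degree descending with lexicographic tie-breaks.
    """
    universe = list(universe) if universe is not None else []
    if len(g) == 0 and not universe:
        raise ValidationError("empty edge list and empty node universe")
    graph = nx.Graph()
    graph.add_nodes_from(universe)
    graph.add_edges_from(g.edges)
    degrees = pd.Series(dict(graph.degree()), dtype=int).sort_index()
    connected = degrees[degrees >= 1]
    ranked = sorted(connected.index, key=lambda n: (-connected[n], n))
    if n_top is not None:
        ranked = ranked[:n_top]
    return NetworkSummary(
        degrees=degrees,
        top_hubs=ranked,
        connected_node_count=int((degrees >= 1).sum()),
        isolated_nodes=sorted(degrees.index[degrees == 0]),
    )


def annotate_categories(s: NetworkSummary, categories: Mapping[str, GeneSet] | Sequence[GeneSet]) -> NetworkSummary:
    """Label each node with every functional category containing it.

    Nodes matching no category get empty label sets; per-category membership
    counts (over the tabulated nodes) are recorded in ``category_counts``.
    """
    if not isinstance(categories, Mapping):
        categories = {gs.name: gs for gs in categories}
    node_labels: dict[str, set[str]] = {n: set() for n in s.degrees.index}
    counts: dict[str, int] = {}
    for name, gs in categories.items():
        members = {g for g in gs}
        hit = [n for n in s.degrees.index if str(n).upper() in members]
        for n in hit:
            node_labels[n].add(name)
        counts[name] = len(hit)
    s.categories = node_labels
    s.category_counts = counts
    return s


class HubAnalyzer(BaseEstimator):
    """Degree tabulation and hub ranking, estimator-style.

    Attributes after ``fit``: ``summary_`` (NetworkSummary), ``degrees_``,
    ``top_hubs_`` (first ``n_top`` by degree desc, lexicographic ties).
    """

    def __init__(self, n_top: int = 10, categories: Sequence[GeneSet] = ()):
        self.n_top = n_top
        self.categories = tuple(categories)

    def fit(self, X: EdgeList, y: Iterable[str] | None = None) -> "HubAnalyzer":
        """Fit on an edge list; ``y`` optionally supplies the node universe."""
        summary = degree_table(X, universe=y)
        if self.categories:
            summary = annotate_categories(summary, self.categories)
        self.summary_ = summary
        self.degrees_ = summary.degrees
        self.top_hubs_ = summary.top_hubs[: self.n_top]
        return self
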