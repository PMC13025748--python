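"""Weighted, undirected co-occurrence network construction.

Nodes are ingredients (or categories); an edge (i, j) exists if the two
items appear together in at least one recipe and its integer weight counts
the recipes containing both.  Presence/absence semantics within a recipe
means a recipe contributes at most 1 to any edge regardless of how many
ingredients of each endpoint it holds.  Isolated nodes (items that never
co-occur) are retained by default because the node set is defined as the
item vocabulary, not the edge endpoints; this affects the density
denominator and is configurable via ``include_isolated``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .corpus import Corpus, Recipe
from .errors import EmptyCorpusError, EmptySubsetError

INGREDIENT = "ingredient"
CATEGORY = "category"


@dataclass
class CooccurrenceNetwork:
    """A weighted undirected co-occurrence graph with provenance labels."""

    graph: nx.Graph
    level: str
    subset_label: tuple[str, str] = ("all", "all")

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def m(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> dict[tuple[str, str], int]:
        """Canonical edge map: lexicographically sorted pair -> weight."""
        return {
            tuple(sorted((u, v))): int(d["weight"])
            for u, v, d in self.graph.edges(data=True)
        }

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(tuple(sorted((u, v))) for u, v in self.graph.edges)

    def weight(self, u: str, v: str) -> int:
        return int(self.graph[u][v]["weight"])

    def total_strength(self) -> int:
        """Sum of node strengths (= twice the total edge weight)."""
        return 2 * sum(int(d["weight"]) for _, _, d in self.graph.edges(data=True))


def _build(
    item_sets: Iterable[frozenset[str]],
    level: str,
    subset_label: tuple[str, str],
    include_isolated: bool,
) -> CooccurrenceNetwork:
    weights: Counter[tuple[str, str]] = Counter()
    nodes: set[str] = set()
    for items in item_sets:
        nodes |= items
        for u, v in combinations(sorted(items), 2):
            weights[(u, v)] += 1
    g = nx.Graph()
    if include_isolated:
        g.add_nodes_from(sorted(nodes))
    g.add_weighted_edges_from((u, v, w) for (u, v), w in sorted(weights.items()))
    return CooccurrenceNetwork(graph=g, level=level, subset_label=subset_label)


def build_ingredient_network(
    recipes: Sequence[Recipe],
    subset_label: tuple[str, str] = ("all", "all"),
    include_isolated: bool = True,
) -> CooccurrenceNetwork:
    """Ingredient-level network: weight = recipes containing both endpoints."""
    if not recipes:
        raise EmptyCorpusError("cannot build a network from zero recipes")
    return _build(
        (r.ingredients for r in recipes), INGREDIENT, subset_label, include_isolated
    )


def build_category_network(
    recipes: Sequence[Recipe],
    subset_label: tuple[str, str] = ("all", "all"),
    include_isolated: bool = True,
) -> CooccurrenceNetwork:
    """Category-level network.

    A category is present in a recipe iff at least one of its ingredients
    is; two categories' co-occurrence therefore counts recipes, not
    ingredient pairs, and same-category ingredient pairs create no
    self-loop.
    """
    if not recipes:
        raise EmptyCorpusError("cannot build a network from zero recipes")
    return _build(
        (r.categories for r in recipes), CATEGORY, subset_label, include_isolated
    )


def subset_network(
    corpus: Corpus,
    cuisine: str = "all",
    course: str = "all",
    level: str = INGREDIENT,
    include_isolated: bool = True,
) -> CooccurrenceNetwork:
    """Network of one cuisine x course subset (or pooled with "all")."""
    recipes = corpus.subset(cuisine, course)
    if not recipes:
        raise EmptySubsetError(f"no recipes for cuisine={cuisine!r}, course={course!r}")
    builder = build_category_network if level == CATEGORY else build_ingredient_network
    return builder(recipes, subset_label=(cuisine, course), include_isolated=include_isolated)


def write_graphml(net: CooccurrenceNetwork, path: str | Path) -> None:
    g = net.graph.copy()
    g.graph["level"] = net.level
    g.graph["cuisine"], g.graph["course"] = net.subset_label
    nx.write_graphml(g, str(path))


def write_edgelist_csv(net: CooccurrenceNetwork, path: str | Path) -> None:
    rows = [(u, v, w) for (u, v), w in sorted(net.edges.items())]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, index=False
    )


def read_edgelist_csv(
    path: str | Path,
    level: str = INGREDIENT,
    subset_label: tuple[str, str] = ("all", "all"),
) -> CooccurrenceNetwork:
    df = pd.read_csv(path, dtype={"source": str, "target": str})
    g = nx.Graph()
    g.add_weighted_edges_from(
        (r.source, r.target, int(r.weight)) for r in df.itertuples(index=False)
    )
    return CooccurrenceNetwork(graph=g, level=level, subset_label=subset_label)
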