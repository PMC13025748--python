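"""Node- and network-level metrics for co-occurrence networks.

Conventions:

* weighted degree wd_i = sum_j w_ij, reported alongside its share (% of the
  total strength of the network, so shares sum to 100).
* betweenness is computed on the binarized graph by default -- the path-count
  definition carries no weight term; pass ``use_weights=True`` to use
  shortest paths under distance 1/w_ij as a sensitivity check.  Normalized
  by (n-1)(n-2)/2.
* eigenvector centrality uses the weighted adjacency, power iteration, and
  is reported on the largest connected component (other nodes get 0),
  scaled to unit Euclidean norm by default (``norm="max"`` rescales so the
  top node is 1).
* average clustering is the unweighted local coefficient averaged over all
  n nodes, counting degree-<2 nodes as 0; a weighted geometric-mean variant
  sits behind ``weighted=True``.
* communities come from seeded weighted Louvain with restarts; modularity is
  the weighted Newman modularity of the best partition found.

Degenerate networks (n < 2, or no edges where the metric needs one) raise
:class:`UndefinedMetricError` or carry explicit ``None`` markers in the
report -- never a silent zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConvergenceError, UndefinedMetricError
from .networks import CooccurrenceNetwork


def density(net: CooccurrenceNetwork) -> float:
    """2m / (n(n-1)): realized fraction of possible item pairings."""
    n, m = net.n, net.m
    if n < 2:
        raise UndefinedMetricError(f"density undefined for n={n}")
    return 2.0 * m / (n * (n - 1))


def weighted_degree(net: CooccurrenceNetwork) -> pd.DataFrame:
    """Per-node strength and its percentage share of total strength."""
    if net.n == 0:
        raise UndefinedMetricError("weighted degree undefined on empty network")
    wd = {node: 0.0 for node in net.graph.nodes}
    for u, v, d in net.graph.edges(data=True):
        wd[u] += d["weight"]
        wd[v] += d["weight"]
    total = sum(wd.values())
    share = {
        node: (100.0 * w / total if total > 0 else float("nan"))
        for node, w in wd.items()
    }
    df = pd.DataFrame(
        {"weighted_degree": pd.Series(wd), "share": pd.Series(share)}
    ).sort_values("weighted_degree", ascending=False)
    df.index.name = "node"
    return df


def betweenness(net: CooccurrenceNetwork, use_weights: bool = False) -> dict[str, float]:
    """Normalized betweenness centrality; unweighted shortest paths by default."""
    g = net.graph
    if use_weights:
        g = g.copy()
        for _, _, d in g.edges(data=True):
            d["distance"] = 1.0 / d["weight"]
        return nx.betweenness_centrality(g, normalized=True, weight="distance")
    return nx.betweenness_centrality(g, normalized=True, weight=None)


def eigenvector_centrality(
    net: CooccurrenceNetwork,
    norm: str = "l2",
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> dict[str, float]:
    """Principal eigenvector of the weighted adjacency on the largest component.

    Nodes outside the largest connected component score 0.  ``norm="l2"``
    scales the reported vector to unit Euclidean norm; ``norm="max"`` to a
    maximum of 1.
    """
    if net.n == 0:
        raise UndefinedMetricError("eigenvector centrality undefined on empty network")
    components = sorted(nx.connected_components(net.graph), key=len, reverse=True)
    giant = net.graph.subgraph(components[0])
    if giant.number_of_edges() == 0:
        raise UndefinedMetricError(
            "eigenvector centrality undefined: largest component has no edges"
        )
    try:
        x = nx.eigenvector_centrality(
            giant, max_iter=max_iter, tol=tol, weight="weight"
        )
    except nx.PowerIterationFailedConvergence as exc:
        raise ConvergenceError(
            f"power iteration did not converge in {max_iter} iterations "
            f"(tol={tol}, n={giant.number_of_nodes()})"
        ) from exc
    scale = 1.0
    if norm == "max":
        scale = 1.0 / max(x.values())
    elif norm == "l2":
        scale = 1.0 / math.sqrt(sum(v * v for v in x.values()))
    elif norm is not None:
        raise ValueError(f"unknown norm {norm!r}")
    out = {node: 0.0 for node in net.graph.nodes}
    out.update({node: v * scale for node, v in x.items()})
    return out


def avg_clustering(net: CooccurrenceNetwork, weighted: bool = False) -> float:
    """Mean local clustering over all n nodes (degree-<2 nodes count as 0)."""
    if net.n == 0:
        raise UndefinedMetricError("clustering undefined on empty network")
    return nx.average_clustering(
        net.graph, weight="weight" if weighted else None, count_zeros=True
    )


@dataclass
class Partition:
    """Node -> community labels, contiguous integers starting at 0."""

    community_of: dict[str, int]
    n_communities: int

    @classmethod
    def from_communities(cls, communities: list[set[str]]) -> "Partition":
        ordered = sorted(communities, key=lambda c: min(c))
        labels = {node: i for i, comm in enumerate(ordered) for node in comm}
        return cls(community_of=labels, n_communities=len(ordered))

    def as_sets(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_communities)]
        for node, label in self.community_of.items():
            out[label].add(node)
        return out

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.community_of.items()), columns=["node", "community"]
        ).to_csv(path, index=False)


def modularity(net: CooccurrenceNetwork, partition: Partition) -> float:
    """Weighted Newman modularity of a given partition."""
    return nx.community.modularity(
        net.graph, partition.as_sets(), weight="weight"
    )


def louvain_modularity(
    net: CooccurrenceNetwork, seed: int = 0, n_restarts: int = 20
) -> tuple[Partition, float]:
    """Best weighted-Louvain partition over seeded restarts.

    Louvain is order-dependent, so the partition is the max-modularity one
    over ``n_restarts`` runs with seed-derived sub-seeds; ties keep the
    first occurrence.  Deterministic given ``seed``.
    """
    if net.m < 1:
        raise UndefinedMetricError("modularity undefined on a network with no edges")
    sub_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_restarts)
    best: tuple[Partition, float] | None = None
    for s in sub_seeds:
        communities = nx.community.louvain_communities(
            net.graph, weight="weight", seed=int(s)
        )
        part = Partition.from_communities([set(c) for c in communities])
        q = modularity(net, part)
        if best is None or q > best[1]:
            best = (part, q)
    assert best is not None
    return best


@dataclass
class NodeCentralityRecord:
    node: str
    weighted_degree: float
    weighted_degree_share: float
    betweenness: float
    eigenvector: float


@dataclass
class MetricsReport:
    """All network- and node-level metrics for one network.

    Degenerate networks (n < 2 or m = 0) get ``None`` metric fields and an
    explanatory ``note`` instead of fabricated zeros.
    """

    level: str
    subset_label: tuple[str, str]
    n: int
    m: int
    density: float | None = None
    avg_clustering: float | None = None
    modularity: float | None = None
    partition: Partition | None = None
    nodes: list[NodeCentralityRecord] = field(default_factory=list)
    note: str = ""

    def nodes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    r.node,
                    r.weighted_degree,
                    r.weighted_degree_share,
                    r.betweenness,
                    r.eigenvector,
                )
                for r in self.nodes
            ],
            columns=[
                "node",
                "weighted_degree",
                "weighted_degree_share",
                "betweenness",
                "eigenvector",
            ],
        ).set_index("node")

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "cuisine": self.subset_label[0],
            "course": self.subset_label[1],
            "n": self.n,
            "m": self.m,
            "density": self.density,
            "avg_clustering": self.avg_clustering,
            "modularity": self.modularity,
            "n_communities": self.partition.n_communities if self.partition else None,
            "note": self.note,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def metrics_report(
    net: CooccurrenceNetwork,
    seed: int = 0,
    use_weights_betweenness: bool = False,
    eigenvector_norm: str = "l2",
) -> MetricsReport:
    """Compute the full metric profile of one network."""
    if net.n < 2 or net.m == 0:
        return MetricsReport(
            level=net.level,
            subset_label=net.subset_label,
            n=net.n,
            m=net.m,
            note=f"undefined: degenerate network (n={net.n}, m={net.m})",
        )
    wd = weighted_degree(net)
    bc = betweenness(net, use_weights=use_weights_betweenness)
    ev = eigenvector_centrality(net, norm=eigenvector_norm)
    part, q = louvain_modularity(net, seed=seed)
    records = [
        NodeCentralityRecord(
            node=node,
            weighted_degree=float(wd.loc[node, "weighted_degree"]),
            weighted_degree_share=float(wd.loc[node, "share"]),
            betweenness=float(bc[node]),
            eigenvector=float(ev[node]),
        )
        for node in sorted(net.graph.nodes)
    ]
    records.sort(key=lambda r: r.weighted_degree, reverse=True)
    return MetricsReport(
        level=net.level,
        subset_label=net.subset_label,
        n=net.n,
        m=net.m,
        density=density(net),
        avg_clustering=avg_clustering(net),
        modularity=q,
        partition=part,
        nodes=records,
    )
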