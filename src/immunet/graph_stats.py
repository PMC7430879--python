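"""The directed immune network object and its summary statistics.

The network is a directed multigraph: a pair of components may be joined by
several edges that differ in effect (a dendritic cell can activate, polarize
and inhibit the same T-cell subset). Edge-count statistics (density, degrees,
cross-tabulations) are computed on distinct (source, target, effect) triples;
path metrics (diameter, mean geodesic, shortest-path counts) are computed on
the simple digraph obtained by collapsing parallel effects, since parallel
effects do not create new routes between components.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .records import EdgeRecord, NodeRecord
from .network_io import validate_network


class ConstructionError(ValueError):
    """The edge table refers to nodes missing from the node table."""


class ImmuneNetwork:
    """Directed multigraph over typed immune components.

    Thin wrapper around :class:`networkx.MultiDiGraph` with edges keyed by
    effect, so no two edges share the full (source, target, effect) triple.
    Node attributes come from the curated node table.
    """

    def __init__(self, graph: Optional[nx.MultiDiGraph] = None):
        self.graph = graph if graph is not None else nx.MultiDiGraph()

    # -- basic counts ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def m(self) -> int:
        """Number of distinct (source, target, effect) triples."""
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def node_type(self, name: str) -> str:
        return self.graph.nodes[name]["node_type"]

    def node_record(self, name: str) -> NodeRecord:
        return self.graph.nodes[name]["record"]

    def has_node(self, name: str) -> bool:
        return self.graph.has_node(name)

    def edges(self) -> list[tuple[str, str, str]]:
        """All (source, target, effect) triples."""
        return [(u, v, k) for u, v, k in self.graph.edges(keys=True)]

    def nodes_of_type(self, node_type: str) -> list[str]:
        return [n for n, t in self.graph.nodes(data="node_type") if t == node_type]

    # -- collapsed simple digraph for path metrics ----------------------
    def simple_digraph(self) -> nx.DiGraph:
        """Parallel effects collapsed; self-loops removed (no route value)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from(
            (u, v) for u, v in self.graph.edges(keys=False) if u != v
        )
        return g

    def distance_matrix(self) -> tuple[np.ndarray, list[str]]:
        """All-pairs directed hop distances (inf where unreachable)."""
        order = self.nodes
        index = {v: i for i, v in enumerate(order)}
        rows, cols = [], []
        for u, v in {(u, v) for u, v, _ in self.graph.edges(keys=True) if u != v}:
            rows.append(index[u])
            cols.append(index[v])
        adj = csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(self.n, self.n)
        )
        dist = shortest_path(adj, method="D", unweighted=True, directed=True)
        return dist, order


@dataclass
class NetworkSummary:
    """Whole-network descriptive statistics.

    ``density`` is m / (n(n-1)) over distinct non-self triples. ``diameter``
    is the longest finite directed geodesic (hops); ``avg_path_length`` the
    mean geodesic over ordered reachable non-self pairs. Both are ``None``
    for edgeless networks.
    """

    n: int
    m: int
    density: float
    diameter: Optional[int]
    avg_path_length: Optional[float]
    node_type_counts: dict[str, int]
    n_reachable_pairs: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "m": self.m,
            "density": self.density,
            "diameter": self.diameter,
            "avg_path_length": self.avg_path_length,
            "node_type_counts": self.node_type_counts,
            "n_reachable_pairs": self.n_reachable_pairs,
        }


def build_network(
    edges: Sequence[EdgeRecord],
    nodes: Sequence[NodeRecord],
    *,
    force: bool = False,
    validate: bool = False,
) -> ImmuneNetwork:
    """Assemble the directed network from curated records.

    Every edge endpoint must appear in the node table unless ``force`` adds
    missing endpoints as untyped nodes. With ``validate``, the default QC
    rule set must pass first.
    """
    if validate:
        report = validate_network(edges, nodes)
        if not report.passed and not force:
            raise ConstructionError(
                f"validation failed with {len(report.errors)} errors; "
                "fix the tables or pass force=True"
            )
    g = nx.MultiDiGraph()
    for rec in nodes:
        g.add_node(rec.name, node_type=rec.node_type, subtype=rec.subtype,
                   record=rec)
    known = set(g.nodes)
    for rec in edges:
        for endpoint in (rec.source_node, rec.target_node):
            if endpoint not in known:
                if not force:
                    raise ConstructionError(
                        f"edge endpoint {endpoint!r} missing from node table"
                    )
                g.add_node(endpoint, node_type="unknown", subtype="",
                           record=NodeRecord(endpoint, "unknown"))
                known.add(endpoint)
        g.add_edge(rec.source_node, rec.target_node, key=rec.edge_effect,
                   record=rec)
    return ImmuneNetwork(g)


def summarize_network(net: ImmuneNetwork) -> NetworkSummary:
    """Compute n, m, density, diameter and mean directed path length.

    Density uses distinct non-self triples over n(n-1) ordered pairs. Path
    metrics use hop counts on the collapsed simple digraph; unreachable and
    self pairs are dropped from the mean; diameter is the longest *finite*
    geodesic, so disconnected networks still report a number.
    """
    n = net.n
    if n < 2:
        raise ValueError("density is undefined for networks with fewer than 2 nodes")
    m_nonself = sum(1 for u, v, _ in net.graph.edges(keys=True) if u != v)
    density = m_nonself / (n * (n - 1))
    type_counts: dict[str, int] = {}
    for _, t in net.graph.nodes(data="node_type"):
        type_counts[t] = type_counts.get(t, 0) + 1

    diameter: Optional[int] = None
    avg_pl: Optional[float] = None
    n_pairs = 0
    if net.m > 0:
        dist, _ = net.distance_matrix()
        np.fill_diagonal(dist, np.inf)  # exclude self-pairs
        finite = dist[np.isfinite(dist)]
        if finite.size:
            diameter = int(finite.max())
            avg_pl = float(finite.mean())
            n_pairs = int(finite.size)
    return NetworkSummary(
        n=n,
        m=net.m,
        density=density,
        diameter=diameter,
        avg_path_length=avg_pl,
        node_type_counts=type_counts,
        n_reachable_pairs=n_pairs,
    )


def degree_profile(net: ImmuneNetwork) -> pd.DataFrame:
    """Per-node multigraph degrees (parallel effects each count once).

    Returns a DataFrame indexed by node with columns ``node_type``,
    ``subtype``, ``in_degree``, ``out_degree``, ``total``. Group with
    ``df.groupby("node_type")`` for the per-class views.
    """
    rows = []
    for node, data in net.graph.nodes(data=True):
        rows.append({
            "node": node,
            "node_type": data.get("node_type", ""),
            "subtype": data.get("subtype", ""),
            "in_degree": net.graph.in_degree(node),
            "out_degree": net.graph.out_degree(node),
        })
    df = pd.DataFrame(
        rows, columns=["node", "node_type", "subtype", "in_degree", "out_degree"]
    ).set_index("node")
    df["total"] = df["in_degree"] + df["out_degree"]
    return df


def edge_type_crosstab(net: ImmuneNetwork) -> pd.DataFrame:
    """Edge counts by (source node type, target node type, effect).

    The returned DataFrame has columns ``source_type``, ``target_type``,
    ``edge_effect``, ``count`` and sums to m. Sorted by descending count,
    then lexicographically for determinism.
    """
    counts: dict[tuple[str, str, str], int] = {}
    for u, v, effect in net.graph.edges(keys=True):
        key = (net.node_type(u), net.node_type(v), effect)
        counts[key] = counts.get(key, 0) + 1
    df = pd.DataFrame(
        [(s, t, e, c) for (s, t, e), c in counts.items()],
        columns=["source_type", "target_type", "edge_effect", "count"],
    )
    return df.sort_values(
        ["count", "source_type", "target_type", "edge_effect"],
        ascending=[False, True, True, True],
    ).reset_index(drop=True)


def cell_involvement_share(net: ImmuneNetwork) -> float:
    """Fraction of edges with a cell as source or target."""
    if net.m == 0:
        return 0.0
    k = sum(
        1
        for u, v, _ in net.graph.edges(keys=True)
        if net.node_type(u) == "cell" or net.node_type(v) == "cell"
    )
    return k / net.m


def multi_effect_pairs(
    net: ImmuneNetwork,
) -> list[tuple[tuple[str, str], set[str]]]:
    """Ordered node pairs joined by two or more distinct effects.

    Sorted by descending effect count, then by pair name. Mirrors the query
    that finds, e.g., a dendritic cell that can activate, polarize *and*
    inhibit the same naive T-cell population.
    """
    effects: dict[tuple[str, str], set[str]] = {}
    for u, v, effect in net.graph.edges(keys=True):
        effects.setdefault((u, v), set()).add(effect)
    multi = [(pair, effs) for pair, effs in effects.items() if len(effs) >= 2]
    return sorted(multi, key=lambda kv: (-len(kv[1]), kv[0]))


def write_graphml(net: ImmuneNetwork, path: Union[str, Path]) -> None:
    """GraphML export for Cytoscape and igraph interoperability."""
    g = nx.MultiDiGraph()
    for node, data in net.graph.nodes(data=True):
        g.add_node(node, node_type=data.get("node_type", ""),
                   subtype=data.get("subtype", ""))
    for u, v, effect in net.graph.edges(keys=True):
        g.add_edge(u, v, key=effect, edge_effect=effect)
    nx.write_graphml(g, path)


def write_sif(net: ImmuneNetwork, path: Union[str, Path]) -> None:
    """SIF export: one ``source<TAB>effect<TAB>target`` line per edge."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, effect in sorted(net.graph.edges(keys=True)):
            fh.write(f"{u}\t{effect}\t{v}\n")
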