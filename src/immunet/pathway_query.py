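"""Pathway coverage, shortest-path sets, and two-network overlap.

A literature pathway is a named set of claimed directed interactions. Coverage
against the curated network partitions the claims into present and absent and
additionally lists network edges among the pathway's nodes that the source
publication did not report — the candidates for unreported crosstalk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .graph_stats import ImmuneNetwork


class NodeLookupError(KeyError):
    """A queried node is not in the network."""


@dataclass
class PathwayDefinition:
    """A named list of claimed (source, target, optional effect) edges."""

    name: str
    claimed_edges: list[tuple[str, str, Optional[str]]]

    @property
    def node_set(self) -> set[str]:
        out: set[str] = set()
        for s, t, _ in self.claimed_edges:
            out.add(s)
            out.add(t)
        return out

    @classmethod
    def from_csv(cls, source: Union[str, Path], name: Optional[str] = None
                 ) -> "PathwayDefinition":
        """Read claimed edges from a CSV with source/target[/effect] columns."""
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
        cols = {c.strip().lower().replace(" ", "_"): c for c in df.columns}
        s_col = cols.get("source_node") or cols.get("source")
        t_col = cols.get("target_node") or cols.get("target")
        e_col = cols.get("edge_effect") or cols.get("effect")
        if s_col is None or t_col is None:
            raise ValueError("pathway CSV needs source and target columns")
        edges = []
        for _, row in df.iterrows():
            effect = str(row[e_col]).strip() if e_col else ""
            edges.append(
                (str(row[s_col]).strip(), str(row[t_col]).strip(), effect or None)
            )
        return cls(name=name or str(source), claimed_edges=edges)


@dataclass
class CoverageReport:
    """Partition of a pathway's claims against the network.

    ``present`` + ``absent`` = claimed edges; ``additional`` lists network
    edges among the pathway's nodes that were not claimed. ``missing_nodes``
    are pathway nodes absent from the network (reported, not raised).
    """

    pathway: str
    present: list[tuple[str, str, Optional[str]]]
    absent: list[tuple[str, str, Optional[str]]]
    additional: list[tuple[str, str, str]]
    missing_nodes: list[str] = field(default_factory=list)

    @property
    def n_present(self) -> int:
        return len(self.present)

    @property
    def n_absent(self) -> int:
        return len(self.absent)

    @property
    def n_additional(self) -> int:
        return len(self.additional)

    def to_markdown(self) -> str:
        lines = [
            f"## Pathway coverage: {self.pathway}",
            "",
            f"{self.n_present} of {self.n_present + self.n_absent} claimed "
            f"interactions present; {self.n_additional} additional network "
            "edges among the pathway nodes.",
            "",
            "| status | source | effect | target |",
            "|---|---|---|---|",
        ]
        for s, t, e in self.present:
            lines.append(f"| present | {s} | {e or '(any)'} | {t} |")
        for s, t, e in self.absent:
            lines.append(f"| absent | {s} | {e or '(any)'} | {t} |")
        for s, t, e in self.additional:
            lines.append(f"| additional | {s} | {e} | {t} |")
        if self.missing_nodes:
            lines += ["", "Nodes absent from network: " + ", ".join(self.missing_nodes)]
        return "\n".join(lines)


def pathway_coverage(
    net: ImmuneNetwork,
    pathway: PathwayDefinition,
    *,
    match_effect: bool = False,
) -> CoverageReport:
    """Check which claimed pathway edges exist in the network.

    A claim is present iff some network edge joins the same (source, target)
    pair — with the same effect too when ``match_effect``. ``additional``
    edges are network edges between pathway nodes matching no claim (compared
    at the same granularity).
    """
    pairs_in_net: set[tuple[str, str]] = set()
    triples_in_net: set[tuple[str, str, str]] = set()
    pathway_nodes = pathway.node_set
    for u, v, e in net.edges():
        pairs_in_net.add((u, v))
        triples_in_net.add((u, v, e))

    present, absent = [], []
    for s, t, e in pathway.claimed_edges:
        if match_effect and e is not None:
            hit = (s, t, e) in triples_in_net
        else:
            hit = (s, t) in pairs_in_net
        (present if hit else absent).append((s, t, e))

    claimed_pairs = {(s, t) for s, t, _ in pathway.claimed_edges}
    claimed_triples = {(s, t, e) for s, t, e in pathway.claimed_edges}
    additional = []
    for u, v, e in sorted(net.edges()):
        if u in pathway_nodes and v in pathway_nodes:
            claimed = (
                (u, v, e) in claimed_triples if match_effect else (u, v) in claimed_pairs
            )
            if not claimed:
                additional.append((u, v, e))

    missing = sorted(n for n in pathway_nodes if not net.has_node(n))
    return CoverageReport(
        pathway=pathway.name,
        present=present,
        absent=absent,
        additional=additional,
        missing_nodes=missing,
    )


def shortest_path_set(
    net: ImmuneNetwork,
    source: str,
    target: str,
    *,
    max_paths: Optional[int] = None,
) -> tuple[Optional[int], list[list[str]], int]:
    """Distance, all shortest directed paths, and their count.

    Returns ``(distance, paths, count)`` where distance is the minimal hop
    count respecting edge direction, paths are all distinct node sequences of
    that length, and count is their number (computed by dynamic programming,
    exact even when ``max_paths`` truncates the enumerated list). Unreachable:
    ``(None, [], 0)``. Source equal to target: ``(0, [[source]], 1)`` — the
    empty path. Parallel effects between a pair contribute one route.
    """
    for name in (source, target):
        if not net.has_node(name):
            raise NodeLookupError(f"node {name!r} not in network")
    if source == target:
        return 0, [[source]], 1
    g = net.simple_digraph()
    # BFS computing distance and number-of-shortest-paths DP
    dist = {source: 0}
    npaths = {source: 1}
    preds: dict[str, list[str]] = {source: []}
    frontier = [source]
    while frontier and target not in dist:
        nxt = []
        for u in frontier:
            for v in g.successors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    npaths[v] = npaths[u]
                    preds[v] = [u]
                    nxt.append(v)
                elif dist[v] == dist[u] + 1:
                    npaths[v] += npaths[u]
                    preds[v].append(u)
        frontier = nxt
    if target not in dist:
        return None, [], 0
    # enumerate node sequences by backtracking the shortest-path DAG
    paths: list[list[str]] = []

    def backtrack(node: str, suffix: list[str]) -> None:
        if max_paths is not None and len(paths) >= max_paths:
            return
        if node == source:
            paths.append([source, *suffix])
            return
        for p in preds[node]:
            backtrack(p, [node, *suffix])

    backtrack(target, [])
    return dist[target], paths, npaths[target]


def count_shortest_paths_from(
    net: ImmuneNetwork, source: str
) -> dict[str, tuple[Optional[int], int]]:
    """Distances and shortest-path counts from ``source`` to every node.

    One BFS+DP pass; used by the stimulus-response analysis where only
    (distance, count) pairs are needed for many targets.
    """
    if not net.has_node(source):
        raise NodeLookupError(f"node {source!r} not in network")
    g = net.simple_digraph()
    dist: dict[str, int] = {source: 0}
    npaths: dict[str, int] = {source: 1}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in g.successors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    npaths[v] = npaths[u]
                    nxt.append(v)
                elif dist[v] == dist[u] + 1:
                    npaths[v] += npaths[u]
        frontier = nxt
    return {
        node: (dist.get(node), npaths.get(node, 0)) for node in net.nodes
    }


def network_overlap(
    net_a: ImmuneNetwork,
    net_b: ImmuneNetwork,
    *,
    match_effect: bool = False,
) -> dict:
    """Partition the union of two networks' edge keys and compute Jaccard.

    Edge keys are (source, target) pairs by default, (source, target, effect)
    triples with ``match_effect``. An empty union yields Jaccard 1.0 (two
    empty networks are identical).
    """

    def keys(net: ImmuneNetwork) -> set:
        if match_effect:
            return set(net.edges())
        return {(u, v) for u, v, _ in net.edges()}

    a, b = keys(net_a), keys(net_b)
    union = a | b
    shared = a & b
    return {
        "shared": sorted(shared),
        "unique_to_a": sorted(a - b),
        "unique_to_b": sorted(b - a),
        "jaccard": len(shared) / len(union) if union else 1.0,
    }
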