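"""Shared fixtures: tiny hand-built networks and random-fixture builders."""

from __future__ import annotations

import numpy as np
import pytest

from immunet import EdgeRecord, NodeRecord, build_network


def make_edge(src, tgt, effect="activate", reference="p. 1", **kw) -> EdgeRecord:
    return EdgeRecord(source_node=src, target_node=tgt, edge_effect=effect,
                      reference=reference, **kw)


def make_nodes(names, node_type="cell"):
    return [NodeRecord(name=n, node_type=node_type, subtype="generic")
            for n in names]


def random_digraph_records(n_nodes: int, n_edges: int, seed: int,
                           effects=("activate", "inhibit")):
    """Random simple digraph as edge/node records (distinct triples)."""
    rng = np.random.default_rng(seed)
    names = [f"N{i}" for i in range(n_nodes)]
    triples = set()
    while len(triples) < n_edges:
        u, v = rng.integers(0, n_nodes, size=2)
        if u == v:
            continue
        e = effects[rng.integers(len(effects))]
        triples.add((names[u], names[v], e))
    edges = [make_edge(u, v, e) for u, v, e in sorted(triples)]
    return edges, make_nodes(names)


@pytest.fixture
def path_net():
    """A -> B -> C path graph."""
    edges = [make_edge("A", "B"), make_edge("B", "C")]
    return build_network(edges, make_nodes("ABC"))


@pytest.fixture
def diamond_net():
    """A -> {B, C} -> D diamond: two shortest A-to-D routes."""
    edges = [make_edge("A", "B"), make_edge("A", "C"),
             make_edge("B", "D"), make_edge("C", "D")]
    return build_network(edges, make_nodes("ABCD"))
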