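"""Synthetic immune-network, activation and difference-catalog generators.

The generators emulate the statistical structure of a curated immune
interaction network so every analysis stage can be exercised without any
external download: typed nodes in the five component classes with a
cytokine-heavy mix (109 cytokines, 51 cells, 59 effector molecules, 30
antigens, 4 antibodies by default), eight edge effects whose class
composition is dominated by cytokine-on-cell action followed by cellular
cytokine secretion, right-skewed degree distributions produced by
preferential attachment, and activation datasets with a planted linear
dependence of the composite activation score on the stimulus-to-cell
shortest-path count.

Every generator is deterministic given its seed and its output passes the
corresponding loader and validator with zero errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .graph_stats import ImmuneNetwork, build_network
from .pathway_query import count_shortest_paths_from
from .records import EdgeRecord, NodeRecord, SpeciesDifferenceRecord

# ---------------------------------------------------------------------------
# name pools — realistic immune component names, padded deterministically
# when a configuration asks for more nodes than the pool holds
# ---------------------------------------------------------------------------

_CELLS = [
    "B cell", "NK cell", "naive CD4 T cell", "naive CD8 T cell", "Th1 cell",
    "Th2 cell", "Th17 cell", "Treg", "effector CD8 T cell", "memory B cell",
    "plasma cell", "dendritic cell", "plasmacytoid dendritic cell",
    "macrophage", "monocyte", "neutrophil", "eosinophil", "basophil",
    "mast cell", "NKT cell", "gamma-delta T cell", "ILC1", "ILC2", "ILC3",
    "hematopoietic stem cell", "common lymphoid progenitor",
    "common myeloid progenitor", "megakaryocyte", "platelet",
    "epithelial cell", "endothelial cell", "fibroblast",
    "follicular dendritic cell", "Langerhans cell", "Kupffer cell",
    "microglia", "thymocyte", "pro-B cell", "pre-B cell", "immature B cell",
    "marginal zone B cell", "germinal center B cell", "Tfh cell", "Th9 cell",
    "Th22 cell", "memory CD4 T cell", "memory CD8 T cell", "MDSC",
    "red pulp macrophage", "alveolar macrophage", "stromal cell",
]

_CYTOKINES = (
    [f"IL{i}" for i in range(1, 41)]
    + [f"CCL{i}" for i in range(1, 29)]
    + [f"CXCL{i}" for i in range(1, 18)]
    + ["IFNa", "IFNb", "IFNg", "TNFa", "TGFb", "GMCSF", "MCSF", "GCSF",
       "LTa", "TSLP", "LIF", "OSM", "EPO", "TPO", "SCF", "FLT3L", "BAFF",
       "APRIL", "RANKL", "TRAIL", "OX40L", "CD40L", "41BBL", "LIGHT"]
)

_EFFECTORS = (
    [f"C{i}" for i in range(1, 10)]
    + ["C3a", "C3b", "C5a", "MBL", "CRP", "SAP", "granzyme A", "granzyme B",
       "perforin", "granulysin", "alpha-defensin", "beta-defensin",
       "lysozyme", "cathelicidin", "lactoferrin", "reactive oxygen species",
       "nitric oxide", "histamine", "heparin", "tryptase", "leukotriene B4",
       "prostaglandin E2", "platelet-activating factor", "elastase",
       "myeloperoxidase", "properdin", "factor B", "factor D", "factor H"]
)

_ANTIGENS = [
    "LPS", "peptidoglycan", "flagellin", "dsRNA", "ssRNA", "CpG DNA",
    "zymosan", "mannan", "lipoteichoic acid", "beta-glucan", "viral capsid",
    "bacterial DNA", "fungal spore", "helminth antigen", "allergen",
    "superantigen", "tumor antigen", "alloantigen", "hapten",
]

_ANTIBODIES = ["IgM", "IgG", "IgA", "IgE", "IgD"]

_POOLS = {
    "cell": _CELLS,
    "cytokine": _CYTOKINES,
    "effector molecule": _EFFECTORS,
    "antigen": _ANTIGENS,
    "antibody": _ANTIBODIES,
}

_SUBTYPES = {
    "cell": "immune cell",
    "cytokine": "cytokine",
    "effector molecule": "effector",
    "antigen": "pathogen-associated molecule",
    "antibody": "immunoglobulin isotype",
}

_PROCESSES = [
    "inflammation", "antigen presentation", "B cell development",
    "NK cytotoxicity", "innate recognition", "antibody production",
    "T cell activation", "barrier immunity",
]

# edge-class sampling weights: cytokine action on cells dominates, cellular
# cytokine secretion second, direct cell:cell contact third, the remainder
# spread over antibody/effector/antigen classes
DEFAULT_TYPE_PAIR_WEIGHTS: dict[tuple[str, str], float] = {
    ("cytokine", "cell"): 0.40,
    ("cell", "cytokine"): 0.33,
    ("cell", "cell"): 0.12,
    ("cell", "effector molecule"): 0.04,
    ("effector molecule", "cell"): 0.04,
    ("antigen", "cell"): 0.03,
    ("cell", "antibody"): 0.015,
    ("antibody", "cell"): 0.01,
    ("effector molecule", "antigen"): 0.005,
    ("antibody", "antigen"): 0.005,
}

# effect distribution conditioned on (source type, target type); secretion is
# only emitted from cell sources onto non-cell targets, matching rule R2
DEFAULT_EFFECT_PROBS: dict[tuple[str, str], dict[str, float]] = {
    ("cytokine", "cell"): {"activate": 0.45, "inhibit": 0.20, "recruit": 0.12,
                           "promote survival": 0.10, "differentiate": 0.08,
                           "polarize": 0.05},
    ("cell", "cytokine"): {"secrete": 1.0},
    ("cell", "cell"): {"activate": 0.35, "inhibit": 0.20, "kill": 0.15,
                       "recruit": 0.10, "differentiate": 0.12,
                       "polarize": 0.08},
    ("cell", "effector molecule"): {"secrete": 1.0},
    ("effector molecule", "cell"): {"activate": 0.40, "inhibit": 0.30,
                                    "kill": 0.30},
    ("antigen", "cell"): {"activate": 1.0},
    ("cell", "antibody"): {"secrete": 1.0},
    ("antibody", "cell"): {"activate": 0.60, "inhibit": 0.40},
    ("effector molecule", "antigen"): {"kill": 1.0},
    ("antibody", "antigen"): {"inhibit": 0.50, "kill": 0.50},
}

DEFAULT_NODE_COUNTS = {
    "cytokine": 109,
    "cell": 51,
    "effector molecule": 59,
    "antigen": 30,
    "antibody": 4,
}

DEFAULT_MARKERS = ["pSTAT1", "pSTAT3", "pSTAT5", "pNFkB", "CD69"]


@dataclass
class SimulationConfig:
    """Study conditions for the generators.

    ``node_counts`` and ``m`` default to the curated network's scale
    (253 nodes in the published type mix, 1112 unique interactions);
    ``gamma`` is the preferential-attachment strength (node sampling weight
    proportional to (1 + degree)^gamma; 0 = uniform, larger = heavier hubs);
    ``beta`` is the planted slope of expected activation score (arcsinh
    units) per shortest path; ``sigma`` the Gaussian noise s.d. per marker
    per replicate (same units).
    """

    node_counts: dict[str, int] = dc_field(
        default_factory=lambda: dict(DEFAULT_NODE_COUNTS))
    m: int = 1112
    gamma: float = 1.5
    type_pair_weights: dict[tuple[str, str], float] = dc_field(
        default_factory=lambda: dict(DEFAULT_TYPE_PAIR_WEIGHTS))
    effect_probs: dict[tuple[str, str], dict[str, float]] = dc_field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_EFFECT_PROBS.items()})
    beta: float = 1.0
    sigma: float = 1.0
    markers: list[str] = dc_field(default_factory=lambda: list(DEFAULT_MARKERS))
    n_replicates: int = 4

    def __post_init__(self) -> None:
        n = sum(self.node_counts.values())
        if not 0 <= self.m <= n * (n - 1):
            raise ValueError(f"m={self.m} outside [0, n(n-1)={n * (n - 1)}]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for pair, probs in self.effect_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"effect probabilities for {pair} do not sum to 1")

    @property
    def n(self) -> int:
        return sum(self.node_counts.values())


@dataclass
class GroundTruth:
    """Recomputable bookkeeping of what the generator planted."""

    seed: int
    expected_scores: dict[tuple[str, str], float] = dc_field(default_factory=dict)
    degrees: dict[str, int] = dc_field(default_factory=dict)


def _node_names(node_type: str, count: int) -> list[str]:
    pool = _POOLS[node_type]
    names = list(pool[:count])
    for i in range(len(pool), count):
        names.append(f"{node_type} {i + 1}")
    return names


def _make_nodes(node_counts: dict[str, int]) -> list[NodeRecord]:
    records = []
    for node_type in ("cytokine", "cell", "effector molecule", "antigen",
                      "antibody"):
        count = node_counts.get(node_type, 0)
        for name in _node_names(node_type, count):
            records.append(NodeRecord(name=name, node_type=node_type,
                                      subtype=_SUBTYPES[node_type]))
    return records


def generate_network(
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
) -> tuple[list[EdgeRecord], list[NodeRecord], GroundTruth]:
    """Generate a typed directed multigraph edge/node table pair.

    Edges are drawn class-by-class: an (source type, target type) class from
    ``type_pair_weights``, endpoints within the class with probability
    proportional to (1 + current total degree)^gamma (preferential
    attachment, producing right-skewed degree distributions), and an effect
    from the class-conditional distribution. Self-loops and repeated
    (source, target, effect) triples are rejected. Deterministic given seed;
    the output passes the default validation rule set with zero errors.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    nodes = _make_nodes(config.node_counts)
    by_type: dict[str, list[str]] = {}
    for n in nodes:
        by_type.setdefault(n.node_type, []).append(n.name)

    pairs = [p for p in config.type_pair_weights
             if config.node_counts.get(p[0], 0) and config.node_counts.get(p[1], 0)]
    weights = np.array([config.type_pair_weights[p] for p in pairs], float)
    if not pairs or weights.sum() <= 0:
        if config.m > 0:
            raise ValueError("no admissible edge classes for requested node counts")
    capacity = sum(
        (len(by_type[s]) * len(by_type[t]) - (len(by_type[s]) if s == t else 0))
        * len(config.effect_probs.get((s, t), {}))
        for s, t in pairs
    )
    if config.m > capacity:
        raise ValueError(
            f"m={config.m} exceeds the {capacity} admissible "
            "(source, target, effect) triples under the type constraints"
        )
    weights = weights / weights.sum() if config.m else weights

    degree: dict[str, int] = {n.name: 0 for n in nodes}
    existing: set[tuple[str, str, str]] = set()
    edges: list[EdgeRecord] = []
    attempts = 0
    max_attempts = 500 * max(config.m, 1)
    class_tries = 0
    s_type = t_type = None
    while len(edges) < config.m:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "edge sampling stalled; the configuration leaves too few "
                "admissible triples for the requested m"
            )
        # keep the drawn class across duplicate rejections so the realized
        # class composition tracks the configured weights even when
        # preferential attachment concentrates collisions in one class
        if s_type is None or class_tries > 30:
            s_type, t_type = pairs[rng.choice(len(pairs), p=weights)]
            class_tries = 0
        class_tries += 1
        src = _weighted_node(rng, by_type[s_type], degree, config.gamma)
        tgt = _weighted_node(rng, by_type[t_type], degree, config.gamma)
        if src == tgt:
            continue
        probs = config.effect_probs[(s_type, t_type)]
        effs = sorted(probs)
        effect = effs[rng.choice(len(effs), p=np.array([probs[e] for e in effs]))]
        if (src, tgt, effect) in existing:
            continue
        s_type = None
        existing.add((src, tgt, effect))
        page = int(rng.integers(1, 900))
        edges.append(EdgeRecord(
            source_node=src, target_node=tgt, edge_effect=effect,
            reference=f"p. {page}",
        ))
        degree[src] += 1
        degree[tgt] += 1
    truth = GroundTruth(seed=seed, degrees=dict(degree))
    return edges, nodes, truth


def _weighted_node(rng: np.random.Generator, names: list[str],
                   degree: dict[str, int], gamma: float) -> str:
    if gamma == 0:
        return names[rng.integers(len(names))]
    w = np.array([(1 + degree[n]) ** gamma for n in names], float)
    return names[rng.choice(len(names), p=w / w.sum())]


def expand_mentions(
    edges: Sequence[EdgeRecord],
    total_rows: int,
    seed: int = 0,
) -> list[EdgeRecord]:
    """Inflate a unique edge list into a raw-mentions table.

    Emulates the repeated textbook mentions of the same interaction: the
    returned table has ``total_rows`` rows whose distinct (source, target,
    effect) triples are exactly the input edges, each duplicate carrying its
    own reference. Row order is shuffled. Deduplication recovers exactly
    ``len(edges)`` records.
    """
    if total_rows < len(edges):
        raise ValueError("total_rows must be >= the number of unique edges")
    rng = np.random.default_rng(seed)
    mentions = [e.copy() for e in edges]
    if edges:
        extra_idx = rng.integers(0, len(edges), size=total_rows - len(edges))
        for i in extra_idx:
            dup = edges[i].copy()
            dup.reference = f"p. {int(rng.integers(1, 900))}"
            mentions.append(dup)
    order = rng.permutation(len(mentions))
    return [mentions[i] for i in order]


def generate_stimulus_network(
    n_cells: int = 24,
    n_intermediates: int = 8,
    seed: int = 0,
) -> tuple[ImmuneNetwork, str, list[str]]:
    """A layered network with controlled stimulus-to-cell path counts.

    An antigen stimulus activates ``n_intermediates`` sentinel cells; each
    sentinel secretes one cytokine; each cytokine activates a random subset
    of ``n_cells`` responder cells. Every responder sits at distance 3 from
    the stimulus with a shortest-path count equal to its number of incoming
    cytokine edges (1 to ``n_intermediates``), and no responder is directly
    activated by the stimulus. Returns (network, stimulus name, responder
    names).
    """
    rng = np.random.default_rng(seed)
    stimulus = "LPS"
    sentinels = [f"sentinel cell {i + 1}" for i in range(n_intermediates)]
    cytokines = [f"IL{i + 1}" for i in range(n_intermediates)]
    responders = [f"responder cell {i + 1}" for i in range(n_cells)]
    nodes = [NodeRecord(stimulus, "antigen", "pathogen-associated molecule")]
    nodes += [NodeRecord(s, "cell", "sentinel") for s in sentinels]
    nodes += [NodeRecord(c, "cytokine", "cytokine") for c in cytokines]
    nodes += [NodeRecord(r, "cell", "responder") for r in responders]
    edges = []
    for s, c in zip(sentinels, cytokines):
        edges.append(EdgeRecord(stimulus, s, "activate", reference="synthetic"))
        edges.append(EdgeRecord(s, c, "secrete", reference="synthetic"))
    for r in responders:
        k = int(rng.integers(1, n_intermediates + 1))
        chosen = rng.choice(n_intermediates, size=k, replace=False)
        for idx in sorted(chosen):
            edges.append(EdgeRecord(cytokines[idx], r, "activate",
                                    reference="synthetic"))
    net = build_network(edges, nodes)
    return net, stimulus, responders


def generate_activation_dataset(
    net: ImmuneNetwork,
    stimulus: str,
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
    *,
    cells: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Marker-summary table with a planted path-count/activation dependence.

    For each cell, the expected composite activation score is
    beta * n_shortest(stimulus, cell); the expectation is split equally
    across the activation markers, and Gaussian noise of s.d. ``sigma`` is
    added independently per marker, replicate and condition. Unstimulated
    means sit on fixed per-marker baselines, so with ``sigma=0`` the score
    computed from the table equals the planted value exactly.

    Returns (marker summaries, ground truth with the planted expected
    scores). Deterministic given seed.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    if cells is None:
        cells = [c for c in net.nodes_of_type("cell") if c != stimulus]
    reach = count_shortest_paths_from(net, stimulus)
    truth = GroundTruth(seed=seed)
    markers = config.markers
    baselines = {mk: 1.0 + 0.5 * i for i, mk in enumerate(markers)}
    rows = []
    any_reachable = False
    for cell in cells:
        _, n_shortest = reach[cell]
        any_reachable = any_reachable or n_shortest > 0
        expected = config.beta * n_shortest
        truth.expected_scores[(cell, stimulus)] = expected
        per_marker = expected / len(markers)
        for mk in markers:
            for rep in range(1, config.n_replicates + 1):
                unstim = baselines[mk] + rng.normal(0.0, config.sigma)
                stim = baselines[mk] + per_marker + rng.normal(0.0, config.sigma)
                rows.append({"cell_type": cell, "condition": "unstimulated",
                             "marker": mk, "mean_expression": unstim,
                             "replicate": rep})
                rows.append({"cell_type": cell, "condition": stimulus,
                             "marker": mk, "mean_expression": stim,
                             "replicate": rep})
    if config.beta != 0 and not any_reachable:
        import warnings

        warnings.warn(
            f"stimulus {stimulus!r} reaches no requested cell; all planted "
            "scores are 0", stacklevel=2)
    return pd.DataFrame(rows), truth


def generate_difference_catalog(
    n_records: int = 59,
    category_weights: Sequence[float] = (0.45, 0.25, 0.20, 0.10),
    node_pool: Optional[Sequence[str]] = None,
    seed: int = 0,
    *,
    node_weights: Optional[dict[str, float]] = None,
) -> list[SpeciesDifferenceRecord]:
    """Generate a mouse/human difference catalog.

    Category counts and per-node assignment counts both follow their weight
    vectors by largest-remainder quota, so the configured composition — the
    ranking of category frequencies, and the concentration of differences on
    B and NK cells that mirrors where mouse/human divergence accumulates in
    the curated catalog — is reproduced exactly at any size; only the
    pairing and ordering of records is randomized by the seed.
    """
    weights = np.asarray(list(category_weights), float)
    if weights.size != 4 or (weights < 0).any():
        raise ValueError("category_weights must be four non-negative numbers")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("category_weights must sum to 1")
    if node_pool is None:
        node_pool = list(_CELLS[:20]) + ["SAP", "granulysin", "CCL12"]
    node_pool = list(node_pool)
    if not node_pool and n_records > 0:
        raise ValueError("node pool is empty but records were requested")
    if node_weights is None:
        node_weights = {"B cell": 8.0, "NK cell": 6.0}
    rng = np.random.default_rng(seed)

    def quota_allocate(w: np.ndarray, total: int) -> np.ndarray:
        quota = w / w.sum() * total
        counts = np.floor(quota).astype(int)
        for i in np.argsort(-(quota - counts))[: total - counts.sum()]:
            counts[i] += 1
        return counts

    categories = np.repeat([1, 2, 3, 4],
                           quota_allocate(weights, n_records))
    rng.shuffle(categories)

    w = np.array([node_weights.get(n, 1.0) for n in node_pool], float)
    node_assignment = np.repeat(np.arange(len(node_pool)),
                                quota_allocate(w, n_records))
    rng.shuffle(node_assignment)
    records = []
    for i, cat in enumerate(categories):
        node = node_pool[node_assignment[i]]
        process = _PROCESSES[rng.integers(len(_PROCESSES))]
        records.append(SpeciesDifferenceRecord(
            description=f"synthetic difference {i + 1} affecting {node}",
            category=int(cat),
            affected_nodes=[node],
            immune_process=process,
            reference=f"p. {int(rng.integers(1, 900))}",
        ))
    return records
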