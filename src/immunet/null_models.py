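"""Erdős–Rényi G(n, m) null model for the mean directed path length.

The observed immune network's mean geodesic is compared against random
digraphs with the same number of labelled nodes and directed edges. A mean
path length below the null mean indicates that the curated topology (hubs
such as broadly acting inflammatory cytokines) disseminates signals faster
than size alone would predict.

G(n, m) — exactly m distinct directed non-self edges chosen uniformly — is
the default because the comparison holds edge count fixed; a binomial
G(n, p) variant with p = m / (n(n-1)) is available behind a flag. Replicate
path lengths use the same convention as the observed statistic: hop counts,
unreachable and self pairs dropped from the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .graph_stats import ImmuneNetwork, summarize_network


def _mean_path_length(n: int, rows: np.ndarray, cols: np.ndarray) -> float:
    """Mean finite directed geodesic over ordered non-self pairs; NaN if none."""
    adj = csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="D", unweighted=True, directed=True)
    np.fill_diagonal(dist, np.inf)
    finite = dist[np.isfinite(dist)]
    return float(finite.mean()) if finite.size else float("nan")


def sample_er_path_lengths(
    n: int,
    m: int,
    reps: int,
    seed: int,
    *,
    model: str = "gnm",
) -> list[float]:
    """Average path lengths of ``reps`` random digraphs.

    Each replicate draws directed non-self edges among ``n`` labelled nodes:
    exactly ``m`` distinct edges uniformly at random (``model="gnm"``), or
    each of the n(n-1) possible edges independently with probability
    m / (n(n-1)) (``model="gnp"``). Deterministic given ``seed``. Replicates
    where no ordered pair is reachable yield NaN.
    """
    max_m = n * (n - 1)
    if not 0 <= m <= max_m:
        raise ValueError(f"m must satisfy 0 <= m <= n(n-1) = {max_m}, got {m}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if model not in ("gnm", "gnp"):
        raise ValueError(f"model must be 'gnm' or 'gnp', got {model!r}")
    rng = np.random.default_rng(seed)
    out: list[float] = []
    for _ in range(reps):
        if model == "gnm":
            codes = rng.choice(max_m, size=m, replace=False)
        else:
            p = m / max_m if max_m else 0.0
            codes = np.flatnonzero(rng.random(max_m) < p)
        # decode ordered non-self pair index -> (row, col) skipping the diagonal
        rows = codes // (n - 1)
        offs = codes % (n - 1)
        cols = offs + (offs >= rows)
        out.append(_mean_path_length(n, rows, cols))
    return out


@dataclass
class NullComparison:
    """Observed mean path length against its G(n, m) reference distribution.

    ``quantile`` is the add-one-smoothed empirical quantile of the observed
    value among the replicates, (#{L_rep <= L_obs} + 1) / (R + 1), so it is
    never exactly 0 or 1.
    """

    observed: float
    replicates: list[float] = field(repr=False, default_factory=list)
    null_mean: float = float("nan")
    null_std: float = float("nan")
    quantile: float = float("nan")
    reps: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "observed_avg_path_length": self.observed,
            "null_mean": self.null_mean,
            "null_std": self.null_std,
            "quantile": self.quantile,
            "reps": self.reps,
            "seed": self.seed,
        }


def compare_to_null(
    net: ImmuneNetwork,
    reps: int = 1000,
    seed: int = 0,
    *,
    model: str = "gnm",
) -> NullComparison:
    """Compare the network's mean path length to matched ER digraphs."""
    if net.n < 2 or net.m < 1:
        raise ValueError("null comparison requires at least 2 nodes and 1 edge")
    summary = summarize_network(net)
    observed = summary.avg_path_length
    # match the reported edge count (distinct triples); parallel effects make
    # the ER reference slightly denser than the collapsed digraph, which only
    # shortens null paths and so is conservative for the hub-shortening claim
    m_matched = min(net.m, net.n * (net.n - 1))
    reps_l = sample_er_path_lengths(net.n, m_matched, reps, seed, model=model)
    arr = np.asarray(reps_l, dtype=float)
    valid = arr[np.isfinite(arr)]
    k = int((valid <= observed).sum())
    return NullComparison(
        observed=observed,
        replicates=reps_l,
        null_mean=float(valid.mean()) if valid.size else float("nan"),
        null_std=float(valid.std(ddof=1)) if valid.size > 1 else float("nan"),
        quantile=(k + 1) / (len(reps_l) + 1),
        reps=reps,
        seed=seed,
    )
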