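"""Activation scores and their correlation with stimulus-to-cell path counts.

A cell type's composite activation score for a stimulus is the sum, over a
panel of activation markers, of the difference in mean (arcsinh-scale) marker
expression between the stimulated and unstimulated conditions, after
averaging biological replicates. The analysis then asks whether, among cell
types not directly targeted by the stimulus, the number of distinct shortest
directed paths from the stimulus node to the cell node predicts that score —
Pearson correlation with a permutation test for significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph_stats import ImmuneNetwork
from .pathway_query import NodeLookupError, count_shortest_paths_from

#: expected columns of a marker-summary table
MARKER_COLUMNS = ("cell_type", "condition", "marker", "mean_expression")
UNSTIMULATED = "unstimulated"


class MissingBaselineError(ValueError):
    """A (cell type, stimulus) pair lacks stimulated or unstimulated means."""


class InsufficientDataError(ValueError):
    """Fewer than three paired observations after exclusions."""


@dataclass
class PathStatistics:
    """Shortest-path structure between one stimulus and one cell node."""

    stimulus: str
    cell: str
    distance: Optional[int]
    n_shortest: int

    @property
    def direct(self) -> bool:
        return self.distance == 1


@dataclass
class CorrelationResult:
    """Pearson correlation of activation scores with shortest-path counts."""

    r: float
    p_parametric: float
    n_pairs: int
    p_empirical: Optional[float] = None
    reps: Optional[int] = None
    seed: Optional[int] = None
    excluded_direct: list[tuple[str, str]] = field(default_factory=list)
    excluded_unreachable: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p_parametric": self.p_parametric,
            "p_empirical": self.p_empirical,
            "n_pairs": self.n_pairs,
            "reps": self.reps,
            "seed": self.seed,
            "excluded_direct": self.excluded_direct,
            "excluded_unreachable": self.excluded_unreachable,
        }


def _replicate_means(summaries: pd.DataFrame) -> pd.DataFrame:
    """Average replicates within (cell_type, condition, marker)."""
    df = summaries.copy()
    for col in MARKER_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"marker summary table lacks column {col!r}")
    df["mean_expression"] = df["mean_expression"].astype(float)
    return (
        df.groupby(["cell_type", "condition", "marker"], as_index=False)
        ["mean_expression"].mean()
    )


def compute_activation_scores(
    summaries: pd.DataFrame,
    activation_markers: Sequence[str],
    stimuli: Sequence[str],
) -> pd.DataFrame:
    """Composite activation score per (cell type, stimulus).

    Replicates are averaged first; the score is
    sum over activation markers of (mean stimulated - mean unstimulated).
    Markers outside ``activation_markers`` are ignored. A pair missing the
    stimulated or unstimulated mean of any activation marker raises
    :class:`MissingBaselineError` listing the missing markers.

    Returns a DataFrame with columns ``cell_type``, ``stimulus``, ``score``.
    """
    activation_markers = list(activation_markers)
    means = _replicate_means(summaries)
    means = means[means["marker"].isin(activation_markers)]
    table = means.set_index(["cell_type", "condition", "marker"])["mean_expression"]
    cell_types = sorted(means["cell_type"].unique())
    rows = []
    for stimulus in stimuli:
        for cell in cell_types:
            missing = [
                mk
                for mk in activation_markers
                if (cell, stimulus, mk) not in table.index
                or (cell, UNSTIMULATED, mk) not in table.index
            ]
            if missing:
                raise MissingBaselineError(
                    f"({cell!r}, {stimulus!r}): missing stimulated or "
                    f"unstimulated means for marker(s) {missing}"
                )
            score = sum(
                table[(cell, stimulus, mk)] - table[(cell, UNSTIMULATED, mk)]
                for mk in activation_markers
            )
            rows.append({"cell_type": cell, "stimulus": stimulus,
                         "score": float(score)})
    return pd.DataFrame(rows, columns=["cell_type", "stimulus", "score"])


def path_statistics(
    net: ImmuneNetwork,
    stimulus: str,
    cell_nodes: Sequence[str],
) -> list[PathStatistics]:
    """Distance and shortest-path count from a stimulus to each cell node.

    Self-pairs are excluded. Unreachable cells get distance ``None`` and
    count 0.
    """
    if not net.has_node(stimulus):
        raise NodeLookupError(f"stimulus node {stimulus!r} not in network")
    missing = [c for c in cell_nodes if not net.has_node(c)]
    if missing:
        raise NodeLookupError(f"cell node(s) not in network: {missing}")
    reach = count_shortest_paths_from(net, stimulus)
    out = []
    for cell in cell_nodes:
        if cell == stimulus:
            continue
        d, k = reach[cell]
        out.append(PathStatistics(stimulus=stimulus, cell=cell,
                                  distance=d, n_shortest=k))
    return out


def _paired_arrays(
    scores: pd.DataFrame,
    path_stats: Sequence[PathStatistics],
    exclude_direct: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list, list]:
    """Match scores to path statistics on (cell_type, stimulus)."""
    by_pair = {(p.cell, p.stimulus): p for p in path_stats}
    xs, ys, strata = [], [], []
    dropped_direct, dropped_unreachable = [], []
    for row in scores.itertuples(index=False):
        p = by_pair.get((row.cell_type, row.stimulus))
        if p is None:
            continue
        if p.distance is None:
            dropped_unreachable.append((row.cell_type, row.stimulus))
            continue
        if exclude_direct and p.direct:
            dropped_direct.append((row.cell_type, row.stimulus))
            continue
        xs.append(p.n_shortest)
        ys.append(row.score)
        strata.append(row.stimulus)
    return (np.asarray(xs, float), np.asarray(ys, float),
            np.asarray(strata), dropped_direct, dropped_unreachable)


def correlate_scores_with_paths(
    scores: pd.DataFrame,
    path_stats: Sequence[PathStatistics],
    *,
    exclude_direct: bool = True,
) -> CorrelationResult:
    """Pearson r between shortest-path counts and activation scores.

    Pairs are matched on (cell_type, stimulus). ``exclude_direct`` drops
    cells the stimulus reaches in one hop — the directly activated cells
    whose strong responses follow from the direct interaction rather than
    network position. Unreachable pairs are dropped and reported.
    """
    x, y, _, dropped_direct, dropped_unreachable = _paired_arrays(
        scores, path_stats, exclude_direct
    )
    if x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 paired observations, have {x.size}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson r undefined: zero variance in one variable")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(r),
        p_parametric=float(p),
        n_pairs=int(x.size),
        excluded_direct=dropped_direct,
        excluded_unreachable=dropped_unreachable,
    )


def _pearson_many(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Pearson r of x against each row of ys (vectorized)."""
    xc = x - x.mean()
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = yc @ xc
    den = np.sqrt((xc @ xc) * (yc * yc).sum(axis=1))
    return num / den


def permutation_pvalue(
    scores: pd.DataFrame,
    path_stats: Sequence[PathStatistics],
    reps: int = 10_000,
    seed: int = 0,
    *,
    exclude_direct: bool = True,
    alternative: str = "two-sided",
    stratify_by_stimulus: bool = False,
) -> CorrelationResult:
    """Permutation test of the path-count/activation-score correlation.

    Activation scores are shuffled uniformly across the retained pairs
    (within each stimulus stratum when ``stratify_by_stimulus``) and r is
    recomputed; the empirical p-value is add-one smoothed,
    (1 + #{|r*| >= |r|}) / (reps + 1) for the two-sided default, with
    ``alternative="greater"`` comparing r* >= r. Deterministic given seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    result = correlate_scores_with_paths(
        scores, path_stats, exclude_direct=exclude_direct
    )
    x, y, strata, _, _ = _paired_arrays(scores, path_stats, exclude_direct)
    rng = np.random.default_rng(seed)
    perms = np.empty((reps, y.size))
    if stratify_by_stimulus:
        for i in range(reps):
            perm = y.copy()
            for s in np.unique(strata):
                idx = np.flatnonzero(strata == s)
                perm[idx] = perm[idx][rng.permutation(idx.size)]
            perms[i] = perm
    else:
        perms[:] = y
        perms = rng.permuted(perms, axis=1)
    r_null = _pearson_many(x, perms)
    if alternative == "two-sided":
        k = int((np.abs(r_null) >= abs(result.r) - 1e-12).sum())
    else:
        k = int((r_null >= result.r - 1e-12).sum())
    result.p_empirical = (1 + k) / (reps + 1)
    result.reps = reps
    result.seed = seed
    return result
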