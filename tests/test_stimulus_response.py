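"""Activation scores and the path-count correlation with permutation test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from immunet import (
    build_network,
    compute_activation_scores,
    correlate_scores_with_paths,
    generate_activation_dataset,
    generate_stimulus_network,
    path_statistics,
    permutation_pvalue,
    SimulationConfig,
)
from immunet.stimulus_response import (
    InsufficientDataError,
    MissingBaselineError,
    PathStatistics,
)

from conftest import make_edge, make_nodes


def summaries_from(rows):
    return pd.DataFrame(rows, columns=["cell_type", "condition", "marker",
                                       "mean_expression", "replicate"])


class TestScores:
    def test_identical_conditions_score_zero(self):
        rows = []
        for cond in ("unstimulated", "LPS"):
            for mk in ("CD69", "pSTAT1"):
                rows.append(("B cell", cond, mk, 2.5, 1))
        scores = compute_activation_scores(summaries_from(rows),
                                           ["CD69", "pSTAT1"], ["LPS"])
        assert scores["score"].tolist() == [0.0]

    def test_two_marker_sum_of_differences(self):
        rows = [("B cell", "unstimulated", "CD69", 1.0, 1),
                ("B cell", "LPS", "CD69", 2.0, 1),
                ("B cell", "unstimulated", "pSTAT1", 1.5, 1),
                ("B cell", "LPS", "pSTAT1", 1.1, 1)]
        scores = compute_activation_scores(summaries_from(rows),
                                           ["CD69", "pSTAT1"], ["LPS"])
        assert scores["score"].iloc[0] == pytest.approx(1.0 - 0.4)

    def test_replicates_averaged_before_differencing(self):
        rows = [("B cell", "unstimulated", "CD69", 1.0, 1),
                ("B cell", "unstimulated", "CD69", 3.0, 2),
                ("B cell", "LPS", "CD69", 4.0, 1),
                ("B cell", "LPS", "CD69", 2.0, 2)]
        scores = compute_activation_scores(summaries_from(rows), ["CD69"],
                                           ["LPS"])
        assert scores["score"].iloc[0] == pytest.approx(3.0 - 2.0)

    def test_non_activation_markers_ignored(self):
        rows = [("B cell", "unstimulated", "CD69", 1.0, 1),
                ("B cell", "LPS", "CD69", 2.0, 1),
                ("B cell", "unstimulated", "CD19", 0.0, 1),
                ("B cell", "LPS", "CD19", 9.0, 1)]
        scores = compute_activation_scores(summaries_from(rows), ["CD69"],
                                           ["LPS"])
        assert scores["score"].iloc[0] == pytest.approx(1.0)

    def test_missing_baseline_lists_markers(self):
        rows = [("B cell", "LPS", "CD69", 2.0, 1)]
        with pytest.raises(MissingBaselineError, match="CD69"):
            compute_activation_scores(summaries_from(rows), ["CD69"], ["LPS"])

    def test_generator_scores_recovered_exactly_without_noise(self):
        net, stim, cells = generate_stimulus_network(n_cells=10, seed=1)
        cfg = SimulationConfig(beta=0.7, sigma=0.0)
        df, truth = generate_activation_dataset(net, stim, cfg, seed=2,
                                                cells=cells)
        scores = compute_activation_scores(df, cfg.markers, [stim])
        for row in scores.itertuples(index=False):
            planted = truth.expected_scores[(row.cell_type, stim)]
            assert row.score == pytest.approx(planted, abs=1e-9)


class TestPathStatistics:
    def test_direct_unreachable_and_self_pairs(self):
        nodes = make_nodes(["LPS"], "antigen") + make_nodes(["A", "B", "C"])
        edges = [make_edge("LPS", "A"), make_edge("A", "B")]
        net = build_network(edges, nodes)
        stats = path_statistics(net, "LPS", ["A", "B", "C", "LPS"])
        by_cell = {p.cell: p for p in stats}
        assert "LPS" not in by_cell  # self-pair excluded
        assert by_cell["A"].direct and by_cell["A"].distance == 1
        assert by_cell["B"].distance == 2 and by_cell["B"].n_shortest == 1
        assert by_cell["C"].distance is None and by_cell["C"].n_shortest == 0

    def test_layered_generator_counts_equal_cytokine_in_edges(self):
        net, stim, cells = generate_stimulus_network(n_cells=12,
                                                     n_intermediates=5, seed=3)
        stats = path_statistics(net, stim, cells)
        in_deg = {c: net.graph.in_degree(c) for c in cells}  # oracle
        for p in stats:
            assert p.distance == 3
            assert p.n_shortest == in_deg[p.cell]


class TestCorrelation:
    def pairs_to_inputs(self, pairs, stimulus="LPS", distance=2):
        scores = pd.DataFrame([
            {"cell_type": f"c{i}", "stimulus": stimulus, "score": y}
            for i, (_, y) in enumerate(pairs)])
        stats = [PathStatistics(stimulus, f"c{i}", distance, x)
                 for i, (x, _) in enumerate(pairs)]
        return scores, stats

    def test_perfect_positive_and_negative_collinearity(self):
        scores, stats = self.pairs_to_inputs([(1, 1), (2, 2), (3, 3)])
        assert correlate_scores_with_paths(scores, stats).r == pytest.approx(1.0)
        scores, stats = self.pairs_to_inputs([(1, 3), (2, 2), (3, 1)])
        assert correlate_scores_with_paths(scores, stats).r == pytest.approx(-1.0)

    def test_matches_textbook_pearson_formula(self):
        rng = np.random.default_rng(5)
        xs = rng.integers(1, 9, size=10)
        ys = rng.normal(size=10)
        scores, stats = self.pairs_to_inputs(list(zip(xs, ys)))
        r = correlate_scores_with_paths(scores, stats).r
        xc, yc = xs - xs.mean(), ys - ys.mean()  # oracle: direct formula
        expected = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(expected)

    def test_direct_pairs_excluded_and_reported(self):
        scores = pd.DataFrame([
            {"cell_type": c, "stimulus": "LPS", "score": s}
            for c, s in [("a", 9.0), ("b", 1.0), ("c", 2.0), ("d", 3.3)]])
        stats = [PathStatistics("LPS", "a", 1, 4),
                 PathStatistics("LPS", "b", 2, 1),
                 PathStatistics("LPS", "c", 3, 2),
                 PathStatistics("LPS", "d", 2, 3),
                 PathStatistics("LPS", "e", None, 0)]
        res = correlate_scores_with_paths(scores, stats)
        assert res.n_pairs == 3
        assert res.excluded_direct == [("a", "LPS")]
        res_all = correlate_scores_with_paths(scores, stats,
                                              exclude_direct=False)
        assert res_all.n_pairs == 4

    def test_too_few_pairs_and_zero_variance_raise(self):
        scores, stats = self.pairs_to_inputs([(1, 1), (2, 2)])
        with pytest.raises(InsufficientDataError):
            correlate_scores_with_paths(scores, stats)
        scores, stats = self.pairs_to_inputs([(1, 5), (2, 5), (3, 5)])
        with pytest.raises(ValueError, match="zero variance"):
            correlate_scores_with_paths(scores, stats)

    def test_affine_invariance_of_r(self):
        rng = np.random.default_rng(6)
        pairs = list(zip(rng.integers(1, 9, 8), rng.normal(size=8)))
        scores, stats = self.pairs_to_inputs(pairs)
        r0 = correlate_scores_with_paths(scores, stats).r
        scaled = [(x, 3.5 * y + 11) for x, y in pairs]
        scores2, stats2 = self.pairs_to_inputs(scaled)
        assert correlate_scores_with_paths(scores2, stats2).r == pytest.approx(r0)


class TestPermutation:
    def exact_p(self, xs, ys):
        """Oracle: enumerate all |y|! score permutations, two-sided on |r|."""

        def pearson(a, b):
            a, b = np.asarray(a, float), np.asarray(b, float)
            ac, bc = a - a.mean(), b - b.mean()
            return (ac * bc).sum() / math.sqrt((ac**2).sum() * (bc**2).sum())

        r_obs = abs(pearson(xs, ys))
        hits = sum(abs(pearson(xs, p)) >= r_obs - 1e-12
                   for p in itertools.permutations(ys))
        return hits / math.factorial(len(ys))

    def test_small_case_against_exhaustive_enumeration(self):
        xs, ys = [1, 2, 4], [0.3, 1.9, 1.1]
        scores = pd.DataFrame([{"cell_type": f"c{i}", "stimulus": "LPS",
                                "score": y} for i, y in enumerate(ys)])
        stats = [PathStatistics("LPS", f"c{i}", 2, x)
                 for i, x in enumerate(xs)]
        res = permutation_pvalue(scores, stats, reps=6000, seed=7)
        exact = self.exact_p(xs, ys)
        # add-one estimator concentrates on the exact enumeration value
        assert res.p_empirical == pytest.approx(exact, abs=0.03)

    def test_determinism_and_reps_recorded(self):
        net, stim, cells = generate_stimulus_network(seed=8)
        cfg = SimulationConfig(beta=0.5, sigma=1.0)
        df, _ = generate_activation_dataset(net, stim, cfg, seed=9,
                                            cells=cells)
        scores = compute_activation_scores(df, cfg.markers, [stim])
        stats = path_statistics(net, stim, cells)
        a = permutation_pvalue(scores, stats, reps=200, seed=10)
        b = permutation_pvalue(scores, stats, reps=200, seed=10)
        assert a.p_empirical == b.p_empirical
        assert a.reps == 200 and a.seed == 10

    def test_constant_scores_surface_zero_variance_error(self):
        scores = pd.DataFrame([{"cell_type": f"c{i}", "stimulus": "LPS",
                                "score": 2.0} for i in range(5)])
        stats = [PathStatistics("LPS", f"c{i}", 2, i + 1) for i in range(5)]
        with pytest.raises(ValueError, match="zero variance"):
            permutation_pvalue(scores, stats, reps=10, seed=0)

    def test_one_sided_never_exceeds_two_sided_for_positive_r(self):
        net, stim, cells = generate_stimulus_network(seed=11)
        cfg = SimulationConfig(beta=1.0, sigma=1.0)
        df, _ = generate_activation_dataset(net, stim, cfg, seed=12,
                                            cells=cells)
        scores = compute_activation_scores(df, cfg.markers, [stim])
        stats = path_statistics(net, stim, cells)
        two = permutation_pvalue(scores, stats, reps=500, seed=13)
        one = permutation_pvalue(scores, stats, reps=500, seed=13,
                                 alternative="greater")
        assert two.r > 0
        assert one.p_empirical <= two.p_empirical

    def test_stratified_shuffle_runs_and_is_deterministic(self):
        rng = np.random.default_rng(14)
        rows, stats = [], []
        for stim in ("LPS", "TNFa"):
            for i in range(6):
                x = int(rng.integers(1, 6))
                rows.append({"cell_type": f"c{i}", "stimulus": stim,
                             "score": x + rng.normal()})
                stats.append(PathStatistics(stim, f"c{i}", 2, x))
        scores = pd.DataFrame(rows)
        a = permutation_pvalue(scores, stats, reps=300, seed=15,
                               stratify_by_stimulus=True)
        b = permutation_pvalue(scores, stats, reps=300, seed=15,
                               stratify_by_stimulus=True)
        assert a.p_empirical == b.p_empirical
        assert 0 < a.p_empirical <= 1
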