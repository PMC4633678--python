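"""Scoring pipeline: pairs, stacks, sweeps, rank statistics, leaderboard."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from emscore import (
    BoundaryMap,
    MetricResult,
    ProbBoundaryMap,
    ScoreConfig,
    ScoringError,
    generate_ground_truth,
    leaderboard,
    report_frame,
    score_pair,
    score_stack,
    spearman_rank,
    threshold_sweep,
    wilcoxon_signed_rank,
)
from emscore.evaluation import ScoreReport
from emscore.synthetic import PerturbSpec, perturb


class TestScorePair:
    def test_identity_scores_one_on_synthetic_maps(self):
        for seed in range(3):
            _, gt = generate_ground_truth(32, 32, 5, seed)
            res = score_pair(gt, gt)
            assert res.rand.fscore == res.info.fscore == 1.0
            assert res.pixel_err == 0.0

    def test_worked_example_composition(self, worked_gt, all_ones_pred):
        res = score_pair(all_ones_pred, worked_gt)
        assert res.rand.fscore == pytest.approx(5 / 7, abs=1e-15)
        assert res.info.fscore == 0.0

    def test_thinning_restores_a_double_width_border(self, worked_gt):
        # prediction with a 2-px border straddling the ground-truth border
        pred = BoundaryMap(np.array([[1, 0, 0, 1]] * 4))
        raw = score_pair(pred, worked_gt)
        thinned = score_pair(pred, worked_gt, ScoreConfig(thin=True))
        assert raw.rand.fscore < 1.0
        assert thinned.rand.fscore == thinned.info.fscore == 1.0

    def test_unrestricted_mask_counts_border_pixels(self, worked_gt):
        res = score_pair(worked_gt, worked_gt, ScoreConfig(foreground_restricted=False))
        # gt border singletons match their own singletons exactly
        assert res.rand.fscore == 1.0

    def test_probabilistic_prediction_requires_threshold(self, worked_gt):
        prob = ProbBoundaryMap(worked_gt.pixels.astype(float))
        with pytest.raises(ScoringError, match="threshold"):
            score_pair(prob, worked_gt)
        res = score_pair(prob, worked_gt, ScoreConfig(threshold=0.5))
        assert res.rand.fscore == 1.0


class TestScoreStack:
    def test_three_perfect_slices(self, worked_gt):
        reports = score_stack([worked_gt] * 3, [worked_gt] * 3)
        for rep in reports.values():
            assert (rep.mean, rep.stderr) == (1.0, 0.0)

    def test_mean_and_stderr_formula(self):
        cfg = ScoreConfig()
        results = [
            MetricResult(1.0, 1.0, 0.8, 0.5),
            MetricResult(1.0, 1.0, 1.0, 0.5),
        ]
        rep = ScoreReport.from_results("rand", results, cfg)
        assert rep.mean == pytest.approx(0.9)
        assert rep.stderr == pytest.approx(0.1)  # sd(0.8, 1.0)/sqrt(2)

    def test_empty_stack_errors(self):
        with pytest.raises(ScoringError, match="empty stack"):
            score_stack([], [])

    def test_length_mismatch_errors(self, worked_gt):
        with pytest.raises(ScoringError, match="2 predictions vs 1"):
            score_stack([worked_gt, worked_gt], [worked_gt])

    def test_public_private_split_consistency(self):
        # scoring disjoint halves of a homogeneous synthetic stack gives
        # means within twice the combined standard error
        gts, preds = [], []
        for seed in range(8):
            _, gt = generate_ground_truth(48, 48, 6, seed)
            gts.append(gt)
            preds.append(perturb(gt, PerturbSpec("gap", 2, rng_seed=seed + 100)))
        pub = score_stack(preds[:4], gts[:4])["rand"]
        priv = score_stack(preds[4:], gts[4:])["rand"]
        tol = 2.0 * np.hypot(pub.stderr, priv.stderr)
        assert abs(pub.mean - priv.mean) <= tol


class TestThresholdSweep:
    def test_binary_input_gives_constant_curve(self, worked_gt):
        prob = ProbBoundaryMap(worked_gt.pixels.astype(float))
        curve = threshold_sweep([prob], [worked_gt], [0.25, 0.5, 0.75])
        assert curve.points["fscore"].nunique() == 1
        assert curve.best["fscore"] == 1.0

    def test_constant_probability_map_binarizes_both_ways(self, worked_gt):
        prob = ProbBoundaryMap(np.full(worked_gt.shape, 0.6))
        curve = threshold_sweep([prob], [worked_gt], [0.5, 0.7])
        all_ones = score_pair(BoundaryMap(np.ones(worked_gt.shape, int)), worked_gt)
        all_zeros = score_pair(BoundaryMap(np.zeros(worked_gt.shape, int)), worked_gt)
        assert curve.points.loc[0, "fscore"] == pytest.approx(all_ones.rand.fscore)
        assert curve.points.loc[1, "fscore"] == pytest.approx(all_zeros.rand.fscore)

    def test_best_point_maximizes_fscore(self, worked_gt):
        noisy = np.where(worked_gt.pixels > 0, 0.9, 0.3)
        curve = threshold_sweep([ProbBoundaryMap(noisy)], [worked_gt], [0.1, 0.5, 0.95])
        assert curve.best["fscore"] == curve.points["fscore"].max()
        assert curve.best["threshold"] == 0.5

    @pytest.mark.parametrize("grid", [[], [0.5, 0.5], [0.7, 0.3], [-0.1, 0.5]])
    def test_bad_threshold_grids_rejected(self, worked_gt, grid):
        prob = ProbBoundaryMap(worked_gt.pixels.astype(float))
        with pytest.raises(ScoringError):
            threshold_sweep([prob], [worked_gt], grid)


class TestSpearman:
    def test_identical_and_reversed_orderings(self):
        assert spearman_rank([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0
        assert spearman_rank([1, 2, 3, 4], [4, 3, 2, 1]) == -1.0

    def test_single_swap_gives_point_eight(self):
        assert spearman_rank([1, 2, 3, 4], [1, 2, 4, 3]) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ScoringError, match="constant"):
            spearman_rank([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ScoringError):
            spearman_rank([1, 2], [2, 1])


class TestWilcoxon:
    def test_five_positive_differences_exact(self):
        p = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert p == 0.0625  # 2 / 2^5 by enumeration

    def test_single_nonzero_pair_is_uninformative(self):
        assert wilcoxon_signed_rank([1.0, 2.0, 3.5], [1.0, 2.0, 3.0]) == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(31)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert wilcoxon_signed_rank(a, b) == wilcoxon_signed_rank(b, a)

    def test_matches_scipy_exact_distribution(self):
        rng = np.random.default_rng(32)
        for _ in range(10):
            a, b = rng.normal(size=9), rng.normal(size=9)
            ours = wilcoxon_signed_rank(a, b)
            ref = stats.wilcoxon(a, b, method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_large_sample_matches_scipy_approximation(self):
        rng = np.random.default_rng(33)
        a, b = rng.normal(size=40), rng.normal(size=40)
        ours = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, method="approx", correction=False).pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ScoringError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestLeaderboard:
    def test_single_perfect_submission(self, worked_gt):
        table = leaderboard({"solo": [worked_gt]}, [worked_gt])
        row = table.iloc[0]
        assert row["rank"] == 1
        assert row["rand_fscore"] == row["info_fscore"] == 1.0
        assert row["rand_fscore_thinned"] == 1.0

    def test_dominating_submission_ranks_first_under_both_metrics(self):
        _, gt = generate_ground_truth(48, 48, 6, 41)
        good = perturb(gt, PerturbSpec("gap", 1, rng_seed=1))
        bad = perturb(gt, PerturbSpec("gap", 4, rng_seed=2))
        table = leaderboard({"bad": [bad], "good": [good]}, [gt])
        assert table.iloc[0]["submission"] == "good"
        assert (
            table.iloc[0]["info_fscore"] >= table.iloc[1]["info_fscore"]
        )

    def test_equal_scores_break_ties_alphabetically(self, worked_gt):
        table = leaderboard({"zeta": [worked_gt], "alpha": [worked_gt]}, [worked_gt])
        assert list(table["submission"]) == ["alpha", "zeta"]

    def test_ordering_invariant_under_slice_permutation(self):
        gts, preds = [], []
        for seed in range(3):
            _, gt = generate_ground_truth(32, 32, 5, seed)
            gts.append(gt)
            preds.append(perturb(gt, PerturbSpec("spurious", 1, rng_seed=seed)))
        fwd = leaderboard({"a": preds, "b": gts}, gts)
        rev = leaderboard({"a": preds[::-1], "b": gts[::-1]}, gts[::-1])
        assert list(fwd["submission"]) == list(rev["submission"])
        assert fwd["rand_fscore"].tolist() == pytest.approx(rev["rand_fscore"].tolist())


class TestReportFrame:
    def test_stable_columns_and_values(self, worked_gt):
        reports = score_stack([worked_gt], [worked_gt])
        frame = report_frame("sub", reports)
        assert list(frame.columns) == [
            "submission", "slice", "metric", "split", "merge", "fscore", "thinned", "alpha",
        ]
        assert set(frame["metric"]) == {"rand", "info"}
        assert (frame["fscore"] == 1.0).all()
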