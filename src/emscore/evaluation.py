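"""Challenge-style scoring pipeline: per-slice scores, sweeps, ranking, tests.

The 2D challenge scores each slice of an image stack independently and
aggregates per-slice F-scores as mean +/- standard error.  Probabilistic
boundary maps are swept over a threshold grid, reporting the point of maximal
F-score.  Ranking comparisons use Spearman's rank-order correlation; paired
score comparisons use the Wilcoxon signed-rank test (exact for small n).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    BoundaryMap,
    EvalMask,
    ProbBoundaryMap,
    ScoringError,
    build_contingency,
    foreground_mask,
)
from .metrics import MetricResult, info_scores, pixel_error, rand_scores
from .morphology import segment_boundary_map, thin_borders

logger = logging.getLogger("emscore")

__all__ = [
    "ScoreConfig",
    "PairResult",
    "ScoreReport",
    "SweepCurve",
    "score_pair",
    "score_stack",
    "threshold_sweep",
    "spearman_rank",
    "wilcoxon_signed_rank",
    "leaderboard",
    "report_frame",
]

DEFAULT_THRESHOLDS: Tuple[float, ...] = tuple(np.round(np.arange(0.01, 1.00, 0.01), 2))

# exact Wilcoxon null distribution is enumerated up to this many nonzero pairs
_WILCOXON_EXACT_N = 12


@dataclasses.dataclass(frozen=True)
class ScoreConfig:
    """Pipeline configuration shared by all scoring entry points.

    thin
        Apply non-merging border thinning to the prediction before scoring.
    foreground_restricted
        Restrict pair counting to ground-truth foreground pixels (the
        challenge convention).  When off, all pixels are counted and border
        pixels score as singleton segments on both sides.
    connectivity
        4 or 8, used both for segmentation components and for thinning.
    alpha
        Split/merge weight of the F-scores; 0.5 weights them equally.
    threshold
        Binarization threshold applied to probabilistic predictions.
    """

    thin: bool = False
    foreground_restricted: bool = True
    connectivity: int = 4
    alpha: float = 0.5
    threshold: Optional[float] = None

    def as_dict(self) -> Dict[str, object]:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class PairResult:
    """Scores of one predicted slice against one ground-truth slice."""

    rand: MetricResult
    info: MetricResult
    pixel_err: float

    def metric(self, name: str) -> MetricResult:
        if name not in ("rand", "info"):
            raise ScoringError(f"unknown metric {name!r}")
        return getattr(self, name)


@dataclasses.dataclass(frozen=True)
class ScoreReport:
    """Per-slice results and their aggregate for one metric family.

    ``mean`` is the arithmetic mean of per-slice F-scores and ``stderr`` their
    sample standard deviation divided by sqrt(n).  The challenge tables print
    "score +/- uncertainty" without defining the uncertainty; this package
    reports the standard error across slices and labels it as such.
    """

    metric_name: str
    per_image: Tuple[MetricResult, ...]
    mean: float
    stderr: float
    config: ScoreConfig

    @classmethod
    def from_results(
        cls, metric_name: str, results: Sequence[MetricResult], config: ScoreConfig
    ) -> "ScoreReport":
        if not results:
            raise ScoringError("cannot aggregate an empty sequence of scores")
        f = np.array([r.fscore for r in results], dtype=np.float64)
        stderr = 0.0 if len(f) < 2 else float(np.std(f, ddof=1) / math.sqrt(len(f)))
        return cls(metric_name, tuple(results), float(f.mean()), stderr, config)

    def fscores(self) -> np.ndarray:
        return np.array([r.fscore for r in self.per_image])


@dataclasses.dataclass(frozen=True)
class SweepCurve:
    """Mean split/merge/F score per binarization threshold, plus the best point."""

    points: pd.DataFrame  # columns: threshold, split, merge, fscore
    metric_name: str

    @property
    def best(self) -> pd.Series:
        """The sweep point of maximal F-score (lowest threshold on ties)."""
        return self.points.loc[self.points["fscore"].idxmax()]


def _binarize_pred(pred, config: ScoreConfig) -> BoundaryMap:
    if isinstance(pred, ProbBoundaryMap):
        if config.threshold is None:
            raise ScoringError("probabilistic prediction requires a threshold")
        return pred.binarize(config.threshold)
    return pred


def score_pair(pred, gt: BoundaryMap, config: ScoreConfig = ScoreConfig()) -> PairResult:
    """Score one predicted boundary map against one ground-truth map.

    Pipeline order: binarize (if probabilistic), optionally thin the
    prediction, segment both maps (connected components of 1s plus singleton
    0-pixels), build the evaluation mask from the ground truth, accumulate the
    contingency table and evaluate both metric families.  The prediction is
    segmented on the full image; the mask restricts pair counting only.
    """
    pred_map = _binarize_pred(pred, config)
    if pred_map.shape != gt.shape:
        raise ScoringError(f"dimension mismatch: pred {pred_map.shape} vs gt {gt.shape}")
    if config.thin:
        pred_map = thin_borders(pred_map, config.connectivity)
    seg_pred = segment_boundary_map(pred_map, config.connectivity)
    seg_gt = segment_boundary_map(gt, config.connectivity)
    mask = foreground_mask(gt) if config.foreground_restricted else EvalMask.full(gt.shape)
    ct = build_contingency(seg_pred, seg_gt, mask)
    return PairResult(
        rand=rand_scores(ct, config.alpha),
        info=info_scores(ct, config.alpha),
        pixel_err=pixel_error(pred_map, gt),
    )


def score_stack(
    preds: Sequence, gts: Sequence[BoundaryMap], config: ScoreConfig = ScoreConfig()
) -> Dict[str, ScoreReport]:
    """Score a stack slice by slice; returns one :class:`ScoreReport` per
    metric family (keys ``"rand"`` and ``"info"``).  Slices are scored
    independently, as in the 2D challenge."""
    if len(preds) == 0:
        raise ScoringError("empty stack")
    if len(preds) != len(gts):
        raise ScoringError(f"stack length mismatch: {len(preds)} predictions vs {len(gts)} ground truths")
    results = [score_pair(p, g, config) for p, g in zip(preds, gts)]
    return {
        name: ScoreReport.from_results(name, [r.metric(name) for r in results], config)
        for name in ("rand", "info")
    }


def threshold_sweep(
    probs: Sequence[ProbBoundaryMap],
    gts: Sequence[BoundaryMap],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    config: ScoreConfig = ScoreConfig(),
    metric: str = "rand",
) -> SweepCurve:
    """Binarize a probabilistic stack at each threshold and score it.

    Each point records the across-slice mean split, merge and F score of the
    chosen metric family; ``best`` is the point of maximal F-score, which is
    how probabilistic submissions are placed in the ranking tables.
    """
    thresholds = [float(t) for t in thresholds]
    if not thresholds:
        raise ScoringError("empty threshold list")
    if any(not 0.0 <= t <= 1.0 for t in thresholds):
        raise ScoringError("thresholds must lie within [0, 1]")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ScoringError("thresholds must be strictly increasing")
    rows = []
    for t in thresholds:
        cfg = dataclasses.replace(config, threshold=t)
        reports = score_stack(probs, gts, cfg)
        rep = reports[metric]
        rows.append(
            {
                "threshold": t,
                "split": float(np.mean([r.split for r in rep.per_image])),
                "merge": float(np.mean([r.merge for r in rep.per_image])),
                "fscore": rep.mean,
            }
        )
    return SweepCurve(points=pd.DataFrame(rows), metric_name=metric)


def spearman_rank(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Spearman's rank-order correlation (Pearson correlation of average
    ranks).  Requires at least 3 paired values and non-constant inputs."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ScoringError("spearman_rank requires two equal-length 1D sequences")
    if len(a) < 3:
        raise ScoringError("spearman_rank requires at least 3 paired values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ScoringError("spearman_rank undefined for constant input (zero rank variance)")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def wilcoxon_signed_rank(per_image_a: Sequence[float], per_image_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-slice scores.

    Zero differences are dropped.  For n <= 12 remaining pairs the null
    distribution of the positive-rank sum is enumerated exactly over all 2^n
    sign assignments (ties in |differences| receive average ranks and are
    handled naturally by the enumeration); beyond that the tie-corrected
    normal approximation is used.  The two-sided p-value is
    ``min(1, 2 * min(P(W <= w), P(W >= w)))``.
    """
    a = np.asarray(per_image_a, dtype=np.float64)
    b = np.asarray(per_image_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ScoringError("wilcoxon_signed_rank requires two equal-length 1D sequences")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ScoringError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= _WILCOXON_EXACT_N:
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        sums = signs @ ranks
        p = 2.0 * min(np.mean(sums <= w), np.mean(sums >= w))
        return float(min(1.0, p))
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var == 0:
        raise ScoringError("zero variance in signed ranks")
    z = (w - mean) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _submission_row(
    name: str, preds: Sequence, gts: Sequence[BoundaryMap], config: ScoreConfig
) -> Dict[str, object]:
    row: Dict[str, object] = {"submission": name}
    for thinned in (False, True):
        cfg = dataclasses.replace(config, thin=thinned)
        reports = score_stack(preds, gts, cfg)
        suffix = "_thinned" if thinned else ""
        for metric in ("rand", "info"):
            rep = reports[metric]
            row[f"{metric}_fscore{suffix}"] = rep.mean
            row[f"{metric}_stderr{suffix}"] = rep.stderr
    return row


def leaderboard(
    submissions: Mapping[str, Sequence],
    gts: Sequence[BoundaryMap],
    config: ScoreConfig = ScoreConfig(),
) -> pd.DataFrame:
    """Rank named submissions against one ground-truth stack.

    The table is sorted by the raw (un-thinned) Rand F-score — the challenge's
    historical official ranking — with deterministic alphabetical tie-breaks,
    and reports both metric families raw and thinned.
    """
    if not submissions:
        raise ScoringError("leaderboard requires at least one submission")
    rows = [_submission_row(name, preds, gts, config) for name, preds in sorted(submissions.items())]
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["rand_fscore", "submission"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


def report_frame(
    submission: str,
    reports: Mapping[str, ScoreReport],
) -> pd.DataFrame:
    """Long-form per-slice score table with the package's stable CSV columns:
    submission, slice, metric, split, merge, fscore, thinned, alpha."""
    rows = []
    for metric_name, rep in reports.items():
        for i, res in enumerate(rep.per_image):
            rows.append(
                {
                    "submission": submission,
                    "slice": i,
                    "metric": metric_name,
                    "split": res.split,
                    "merge": res.merge,
                    "fscore": res.fscore,
                    "thinned": rep.config.thin,
                    "alpha": res.alpha,
                }
            )
    return pd.DataFrame(rows, columns=["submission", "slice", "metric", "split", "merge", "fscore", "thinned", "alpha"])
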