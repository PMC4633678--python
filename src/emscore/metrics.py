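"""Scoring formulas: pixel error, Rand and information-theoretic split/merge/F.

Both metric families are computed from the contingency table of joint pixel
probabilities ``p_ij`` with marginals ``s_i`` (predicted) and ``t_j`` (true).

Rand family (pair-counting precision/recall):

    split  = sum p_ij^2 / sum t_j^2          merge = sum p_ij^2 / sum s_i^2
    F_a    = sum p_ij^2 / (a sum s_i^2 + (1-a) sum t_j^2)

Information-theoretic family, with I = I(S;T) mutual information:

    split  = I / H(S)                        merge = I / H(T)
    F_a    = I / ((1-a) H(S) + a H(T))

In both families ``a = 0`` recovers the split score, ``a = 1`` the merge score,
and ``a = 0.5`` (the default) weights split and merge errors equally.  Rand
sums are computed from exact integer pair counts, so identities such as
``F_0 == split`` hold to the bit.  Logarithms are natural; every
information-theoretic score is a ratio of log sums, so the base cancels (a
tested property).

Degenerate partitions (paper-silent corner cases, our conventions):

* H(S) = 0 (single predicted segment): I = 0 and split := 1 with flag
  ``zero_entropy_pred`` — a one-segment prediction asserts nothing false about
  splits.  Symmetrically for H(T) = 0 (``zero_entropy_truth``).
* The F-score is always evaluated directly from its own formula, so it
  degrades gracefully (an all-merged prediction gets info F = 0 at a = 0.5);
  only when its denominator is exactly 0 is it set to 1 (both partitions are
  then the trivial single segment, or the weight of the nonzero entropy is 0).
* A one-to-one table (each predicted segment matching exactly one true segment
  and vice versa) scores exactly 1.0 in every score, detected structurally so
  that no floating-point rounding leaks into perfect scores.
"""

from __future__ import annotations

import dataclasses
import math
from typing import FrozenSet

import numpy as np

from .core import BoundaryMap, ContingencyTable, ScoringError, _check_same_shape

__all__ = ["MetricResult", "rand_scores", "info_scores", "pixel_error"]

ZERO_ENTROPY_PRED = "zero_entropy_pred"
ZERO_ENTROPY_TRUTH = "zero_entropy_truth"


@dataclasses.dataclass(frozen=True)
class MetricResult:
    """Split, merge and F score of one metric family at one weight ``alpha``."""

    split: float
    merge: float
    fscore: float
    alpha: float
    degenerate_flags: FrozenSet[str] = frozenset()

    def __iter__(self):
        yield from (self.split, self.merge, self.fscore)


def _check_alpha(alpha: float) -> None:
    if not 0.0 <= alpha <= 1.0:
        raise ScoringError(f"alpha must be in [0, 1], got {alpha}")


def rand_scores(ct: ContingencyTable, alpha: float = 0.5) -> MetricResult:
    """Foreground-restricted Rand split/merge/F scores of a contingency table.

    The split score is the probability that two random in-mask pixels are
    co-segmented in the prediction given that they are co-segmented in the
    truth (pair-counting precision); the merge score is the converse
    (recall).  Denominators are at least ``1/N^2 > 0``, so no degenerate
    conventions are needed.
    """
    _check_alpha(alpha)
    if ct.is_one_to_one():
        return MetricResult(1.0, 1.0, 1.0, alpha)
    joint, rows, cols = ct.pair_sums()
    split = joint / cols
    merge = joint / rows
    fscore = joint / (alpha * rows + (1.0 - alpha) * cols)
    return MetricResult(split, merge, fscore, alpha)


def info_scores(ct: ContingencyTable, alpha: float = 0.5, base: float | None = None) -> MetricResult:
    """Information-theoretic split/merge/F scores of a contingency table.

    ``base`` selects the logarithm base (natural log when ``None``); it is
    exposed only because base invariance of the ratios is a tested property.
    """
    _check_alpha(alpha)
    if ct.is_one_to_one():
        return MetricResult(1.0, 1.0, 1.0, alpha)
    scale = 1.0 if base is None else 1.0 / math.log(base)
    mi = ct.mutual_information() * scale
    h_pred = ct.entropy_pred() * scale
    h_true = ct.entropy_true() * scale

    flags = set()
    if h_pred == 0.0:
        flags.add(ZERO_ENTROPY_PRED)
        mi = 0.0
        split = 1.0
    else:
        split = min(1.0, mi / h_pred)
    if h_true == 0.0:
        flags.add(ZERO_ENTROPY_TRUTH)
        mi = 0.0
        merge = 1.0
    else:
        merge = min(1.0, mi / h_true)

    denom = (1.0 - alpha) * h_pred + alpha * h_true
    fscore = 1.0 if denom == 0.0 else min(1.0, mi / denom)
    return MetricResult(split, merge, fscore, alpha, frozenset(flags))


def pixel_error(pred: BoundaryMap, gt: BoundaryMap) -> float:
    """Fraction of pixels where the two binary maps disagree."""
    _check_same_shape(pred.pixels, gt.pixels, "pixel_error")
    return float(np.mean(pred.pixels != gt.pixels))
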