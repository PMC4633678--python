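"""Domain containers and the contingency table for region-based segmentation scoring.

The scoring pipeline works on 2D neurite cross-section segmentations encoded as
boundary maps: binary images in which 1 marks a pixel inside a cell and 0 marks
a pixel on the border between cells.  All region metrics (Rand and
information-theoretic split/merge/F-scores) are functions of a single
sufficient statistic, the contingency table of joint pixel counts over
(predicted segment, true segment) pairs within an evaluation mask.  Foreground
restriction — excluding ground-truth border pixels from that mask — is what
makes the scores tolerant of border-width disagreements.

Conventions used throughout the package:

* coordinates are row-major and 0-based, pixel ``(r, c)``;
* label 0 in a :class:`LabelImage` means "unlabeled / excluded", positive
  integers are segment ids;
* the evaluation mask restricts pair counting only; segmentations are always
  computed on the full image first.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterator, Mapping, Tuple

import numpy as np

logger = logging.getLogger("emscore")

__all__ = [
    "ScoringError",
    "BoundaryMap",
    "ProbBoundaryMap",
    "LabelImage",
    "EvalMask",
    "ContingencyTable",
    "foreground_mask",
    "build_contingency",
]


class ScoringError(ValueError):
    """Raised for invalid inputs to any scoring operation."""


def _as_2d(pixels, name: str) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.size == 0:
        raise ScoringError(f"{name} must be a non-empty 2D array, got shape {arr.shape}")
    return arr


def _check_same_shape(a, b, what: str) -> None:
    if a.shape != b.shape:
        raise ScoringError(f"dimension mismatch in {what}: {a.shape} vs {b.shape}")


@dataclasses.dataclass(frozen=True)
class BoundaryMap:
    """Binary boundary map: 1 = inside a cell, 0 = border between cells."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_2d(self.pixels, "BoundaryMap.pixels")
        if not np.isin(arr, (0, 1)).all():
            raise ScoringError("BoundaryMap pixels must be exactly 0 or 1")
        object.__setattr__(self, "pixels", arr.astype(np.uint8, copy=False))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def foreground(self) -> np.ndarray:
        """Boolean array, True where the map is inside a cell."""
        return self.pixels.astype(bool)

    def inverted(self) -> "BoundaryMap":
        """Swap polarity (for datasets using 1 = membrane)."""
        return BoundaryMap(1 - self.pixels)


@dataclasses.dataclass(frozen=True)
class ProbBoundaryMap:
    """Probabilistic boundary map: values in [0, 1], higher = more interior-like."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_2d(self.pixels, "ProbBoundaryMap.pixels").astype(np.float64, copy=False)
        if np.isnan(arr).any() or arr.min() < 0.0 or arr.max() > 1.0:
            raise ScoringError("ProbBoundaryMap pixels must lie within [0, 1]")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def binarize(self, threshold: float) -> BoundaryMap:
        """Threshold into a binary map: pixel >= threshold becomes 1 (interior)."""
        if not 0.0 <= threshold <= 1.0:
            raise ScoringError(f"threshold must be in [0, 1], got {threshold}")
        return BoundaryMap((self.pixels >= threshold).astype(np.uint8))


@dataclasses.dataclass(frozen=True)
class LabelImage:
    """Integer segment labels; 0 is reserved for unlabeled/excluded pixels.

    All metrics are invariant under any bijective relabeling of the positive
    labels (tested property).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_2d(self.labels, "LabelImage.labels")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ScoringError("LabelImage labels must be integers")
        if arr.min() < 0:
            raise ScoringError("LabelImage labels must be non-negative")
        object.__setattr__(self, "labels", arr.astype(np.int64, copy=False))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape

    def segment_ids(self) -> np.ndarray:
        """Sorted positive labels present in the image."""
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclasses.dataclass(frozen=True)
class EvalMask:
    """Pixel set over which the contingency table is accumulated."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_2d(self.pixels, "EvalMask.pixels").astype(bool)
        if not arr.any():
            raise ScoringError("empty foreground: evaluation mask has no 'in' pixels")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def n_in(self) -> int:
        return int(self.pixels.sum())

    @classmethod
    def full(cls, shape: Tuple[int, int]) -> "EvalMask":
        return cls(np.ones(shape, dtype=bool))


def foreground_mask(gt: BoundaryMap) -> EvalMask:
    """Evaluation mask of the ground truth's foreground (cell-interior) pixels.

    Border (0) pixels of the ground truth are excluded from scoring, which is
    what makes the scores robust to small border-width variations.  An all-zero
    ground truth has no foreground and raises :class:`ScoringError`.
    """
    fg = gt.foreground()
    if not fg.any():
        raise ScoringError("empty foreground: ground truth boundary map is all zeros")
    return EvalMask(fg)


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """Sparse joint pixel counts over (predicted segment, true segment) pairs.

    With ``N`` in-mask pixels, ``p_ij = n_ij / N`` is the probability that a
    randomly chosen in-mask pixel carries predicted label ``i`` and true label
    ``j``; ``s_i`` and ``t_j`` are its marginals.  Stored sparsely because the
    singleton convention (each border pixel of a boundary map is its own
    one-pixel segment) creates many segments.

    Pair-count sums (``sum n_ij^2`` and the marginal analogues) are returned as
    exact Python integers so that downstream ratios are computed without
    accumulation error.
    """

    pred_labels: np.ndarray  # (K,) sorted unique predicted labels
    true_labels: np.ndarray  # (L,) sorted unique true labels
    row: np.ndarray  # (M,) index into pred_labels per nonzero entry
    col: np.ndarray  # (M,) index into true_labels per nonzero entry
    counts: np.ndarray  # (M,) positive int64 pixel counts
    n_pixels: int

    def __post_init__(self) -> None:
        if self.counts.min(initial=1) <= 0:
            raise ScoringError("contingency counts must be positive")
        if int(self.counts.sum()) != self.n_pixels:
            raise ScoringError("contingency counts do not sum to the mask size")

    # -- probabilities ----------------------------------------------------

    @property
    def p(self) -> np.ndarray:
        """Joint probabilities p_ij for the nonzero entries."""
        return self.counts / self.n_pixels

    def row_counts(self) -> np.ndarray:
        """Pixel count per predicted segment (aligned with ``pred_labels``)."""
        out = np.zeros(len(self.pred_labels), dtype=np.int64)
        np.add.at(out, self.row, self.counts)
        return out

    def col_counts(self) -> np.ndarray:
        """Pixel count per true segment (aligned with ``true_labels``)."""
        out = np.zeros(len(self.true_labels), dtype=np.int64)
        np.add.at(out, self.col, self.counts)
        return out

    @property
    def s(self) -> np.ndarray:
        """Marginal probabilities s_i of the predicted segmentation."""
        return self.row_counts() / self.n_pixels

    @property
    def t(self) -> np.ndarray:
        """Marginal probabilities t_j of the true segmentation."""
        return self.col_counts() / self.n_pixels

    # -- exact pair-count sums --------------------------------------------

    def pair_sums(self) -> Tuple[int, int, int]:
        """``(sum n_ij^2, sum row_i^2, sum col_j^2)`` as exact integers.

        Dividing each by ``N^2`` gives ``sum p_ij^2``, ``sum s_i^2`` and
        ``sum t_j^2``: the probabilities that two independently chosen in-mask
        pixels agree in both / the predicted / the true segmentation.
        """
        joint = int(np.sum(self.counts.astype(object) ** 2))
        rows = int(np.sum(self.row_counts().astype(object) ** 2))
        cols = int(np.sum(self.col_counts().astype(object) ** 2))
        return joint, rows, cols

    def sum_p2(self) -> float:
        joint, _, _ = self.pair_sums()
        return joint / (self.n_pixels**2)

    # -- information-theoretic sums ---------------------------------------

    @staticmethod
    def _sum_nlogn(counts: np.ndarray) -> float:
        c = counts.astype(np.float64)
        return float(np.sum(c * np.log(c)))

    def entropy_pred(self) -> float:
        """H(S) in nats (0 log 0 := 0; exact 0.0 for a single segment)."""
        rows = self.row_counts()
        if len(rows) == 1:
            return 0.0
        return float(np.log(self.n_pixels) - self._sum_nlogn(rows) / self.n_pixels)

    def entropy_true(self) -> float:
        """H(T) in nats."""
        cols = self.col_counts()
        if len(cols) == 1:
            return 0.0
        return float(np.log(self.n_pixels) - self._sum_nlogn(cols) / self.n_pixels)

    def mutual_information(self) -> float:
        """I(S;T) = sum p log p - sum s log s - sum t log t, in nats, >= 0."""
        if len(self.pred_labels) == 1 or len(self.true_labels) == 1:
            return 0.0
        n = self.n_pixels
        value = (
            self._sum_nlogn(self.counts)
            - self._sum_nlogn(self.row_counts())
            - self._sum_nlogn(self.col_counts())
        ) / n + np.log(n)
        return max(0.0, float(value))

    # -- structure ---------------------------------------------------------

    def is_one_to_one(self) -> bool:
        """True when every predicted segment meets exactly one true segment
        and vice versa (the contingency is a relabeled identity)."""
        return (
            len(self.counts) == len(self.pred_labels) == len(self.true_labels)
        )

    def items(self) -> Iterator[Tuple[Tuple[int, int], int]]:
        """Iterate ``((pred_label, true_label), count)`` over nonzero entries."""
        for r, c, n in zip(self.row, self.col, self.counts):
            yield (int(self.pred_labels[r]), int(self.true_labels[c])), int(n)

    def to_dict(self) -> Mapping[Tuple[int, int], int]:
        return dict(self.items())

    @classmethod
    def from_counts(cls, counts: Mapping[Tuple[int, int], int]) -> "ContingencyTable":
        """Build a table directly from a ``{(pred, true): count}`` mapping."""
        if not counts:
            raise ScoringError("contingency table must have at least one entry")
        pred = np.array([k[0] for k in counts], dtype=np.int64)
        true = np.array([k[1] for k in counts], dtype=np.int64)
        vals = np.array(list(counts.values()), dtype=np.int64)
        if (vals <= 0).any():
            raise ScoringError("contingency counts must be positive")
        pred_labels, row = np.unique(pred, return_inverse=True)
        true_labels, col = np.unique(true, return_inverse=True)
        order = np.lexsort((col, row))
        return cls(
            pred_labels=pred_labels,
            true_labels=true_labels,
            row=row[order],
            col=col[order],
            counts=vals[order],
            n_pixels=int(vals.sum()),
        )


def build_contingency(pred: LabelImage, truth: LabelImage, mask: EvalMask) -> ContingencyTable:
    """Accumulate the joint pixel counts of ``pred`` vs ``truth`` inside ``mask``.

    Both label images must be fully labeled (positive) inside the mask; the
    ground-truth mask construction (:func:`foreground_mask`) guarantees this
    for the standard pipeline.
    """
    _check_same_shape(pred.labels, truth.labels, "pred vs truth")
    _check_same_shape(pred.labels, mask.pixels, "labels vs mask")
    p = pred.labels[mask.pixels]
    t = truth.labels[mask.pixels]
    if (t == 0).any():
        raise ScoringError("truth label 0 (unlabeled) occurs inside the evaluation mask")
    if (p == 0).any():
        raise ScoringError("pred label 0 (unlabeled) occurs inside the evaluation mask")
    pred_labels, row_full = np.unique(p, return_inverse=True)
    true_labels, col_full = np.unique(t, return_inverse=True)
    # encode each (row, col) pair as one integer to count sparse entries
    code = row_full.astype(np.int64) * len(true_labels) + col_full
    uniq, counts = np.unique(code, return_counts=True)
    return ContingencyTable(
        pred_labels=pred_labels,
        true_labels=true_labels,
        row=(uniq // len(true_labels)).astype(np.intp),
        col=(uniq % len(true_labels)).astype(np.intp),
        counts=counts.astype(np.int64),
        n_pixels=int(len(p)),
    )
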