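"""Boundary-map geometry: segmentation, non-merging border thinning, dilation.

A boundary map is turned into a segmentation by taking connected components of
its 1-pixels, with the convention that every 0-pixel forms a one-pixel segment
of its own.  Border thinning flips border pixels back to foreground wherever
doing so cannot connect two distinct segments, equalising border widths before
scoring; border dilation is the converse perturbation used to study robustness
to border-width variations.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .core import BoundaryMap, LabelImage, ScoringError

logger = logging.getLogger("emscore")

__all__ = ["segment_boundary_map", "thin_borders", "dilate_borders"]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)
_OFFS4 = ((-1, 0), (0, -1), (0, 1), (1, 0))
_OFFS8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return _STRUCT4
    if connectivity == 8:
        return _STRUCT8
    raise ScoringError(f"connectivity must be 4 or 8, got {connectivity}")


def _offsets(connectivity: int):
    return _OFFS4 if connectivity == 4 else _OFFS8


def _shift(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Array of each pixel's neighbour value at offset ``(dr, dc)``, 0 outside."""
    h, w = arr.shape
    out = np.zeros_like(arr)
    rs = slice(max(0, -dr), min(h, h - dr))
    cs = slice(max(0, -dc), min(w, w - dc))
    rt = slice(max(0, dr), min(h, h + dr))
    ct = slice(max(0, dc), min(w, w + dc))
    out[rs, cs] = arr[rt, ct]
    return out


def segment_boundary_map(bmap: BoundaryMap, connectivity: int = 4) -> LabelImage:
    """Convert a boundary map into a segmentation label image.

    Connected components of 1-pixels (under ``connectivity``) become segments
    with labels ``1..K``; every 0-pixel then receives its own fresh singleton
    label ``K+1, K+2, ...`` in row-major order.  No label is ever reused, so
    all-zero and all-one inputs are both valid.

    The default connectivity is 4: with 8-connectivity a one-pixel diagonal
    border fails to separate the cells on either side of it, defeating the
    boundary-map representation.
    """
    struct = _structure(connectivity)
    fg = bmap.foreground()
    labels, n_fg = ndimage.label(fg, structure=struct)
    labels = labels.astype(np.int64)
    flat = labels.ravel()
    zeros = np.flatnonzero(~fg.ravel())
    flat[zeros] = n_fg + 1 + np.arange(len(zeros), dtype=np.int64)
    return LabelImage(labels)


def thin_borders(bmap: BoundaryMap, connectivity: int = 4) -> BoundaryMap:
    """Thin borders to about one pixel without ever merging segments.

    The output only ever flips 0-pixels to 1, and the partition of the input's
    foreground into segments is exactly preserved: no two input segments are
    connected in the output (tested as a diagonal-contingency property).

    Algorithm: segments are grown back over the border one adjacency layer per
    pass.  Each pass collects the 0-pixels that were adjacent to foreground at
    the start of the pass and scans them in row-major order; a pixel is flipped
    iff all its current foreground neighbours (under ``connectivity``) carry
    one and the same segment label, and the label array is updated immediately
    so later pixels in the same pass see the flip.  Passes repeat until no
    pixel flips.  Freezing each pass's candidate set is what makes opposite
    sides of a widened border advance symmetrically, so a border dilated by
    ``r`` is restored to its original position wherever no segment was
    destroyed; the immediate in-pass update is what guarantees that no flip
    can connect two distinct labels.  The scan order makes the output
    deterministic.

    At the fixpoint every remaining 0-pixel either touches two distinct
    segments or touches no foreground at all (isolated 0-blocks at segment
    junctions may remain locally two pixels wide).
    """
    struct = _structure(connectivity)
    offs = _offsets(connectivity)
    fg = bmap.foreground().copy()
    labels, _ = ndimage.label(fg, structure=struct)
    labels = labels.astype(np.int64)
    h, w = labels.shape

    while True:
        candidates = ndimage.binary_dilation(fg, structure=struct) & ~fg
        if not candidates.any():
            break
        # Proposal per candidate from the pass-start state: the unique label
        # among its foreground neighbours, or 0 on a tie or no contact.
        proposal = np.zeros_like(labels)
        mixed = np.zeros((h, w), dtype=bool)
        for dr, dc in offs:
            nl = _shift(labels, dr, dc)
            take = (proposal == 0) & (nl != 0)
            proposal[take] = nl[take]
            mixed |= (nl != 0) & (proposal != 0) & (nl != proposal)
        proposal[mixed | ~candidates] = 0
        flippable = proposal != 0
        if not flippable.any():
            break
        # Candidates whose neighbourhood contains a candidate proposing a
        # different label sit where two growth fronts meet; only they depend
        # on scan order and are resolved sequentially below.  Everything else
        # flips in bulk, which is equivalent to the sequential scan because a
        # flip can only ever add a neighbour of the flipped pixel's own label
        # to a non-conflicting candidate.
        contested = np.zeros((h, w), dtype=bool)
        for dr, dc in offs:
            np_ = _shift(proposal, dr, dc)
            contested |= flippable & (np_ != 0) & (np_ != proposal)
        bulk = flippable & ~contested
        labels[bulk] = proposal[bulk]
        fg |= bulk
        changed = bool(bulk.any())
        for r, c in np.argwhere(contested):
            first = 0
            ok = False
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    lab = labels[rr, cc]
                    if lab:
                        if first == 0:
                            first = lab
                            ok = True
                        elif lab != first:
                            ok = False
                            break
            if ok:
                labels[r, c] = first
                fg[r, c] = True
                changed = True
        if not changed:
            break
    return BoundaryMap(fg.astype(np.uint8))


def dilate_borders(bmap: BoundaryMap, radius: int) -> BoundaryMap:
    """Widen every border: pixels within Chebyshev distance ``radius`` of a
    0-pixel become 0.  The perturbation primitive for border-width robustness
    experiments; pixels outside the image are treated as foreground so the
    image edge creates no border."""
    if int(radius) != radius or radius < 1:
        raise ScoringError(f"dilation radius must be a positive integer, got {radius}")
    size = 2 * int(radius) + 1
    fg = ndimage.binary_erosion(
        bmap.foreground(), structure=np.ones((size, size), dtype=bool), border_value=1
    )
    return BoundaryMap(fg.astype(np.uint8))
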