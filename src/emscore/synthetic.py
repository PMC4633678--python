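"""Synthetic ground truth and perturbations for exercising the metrics.

Real EM ground truth is a dense tessellation of neurite cross-sections.  A
Voronoi tessellation of random seed points reproduces the properties that
matter for the region metrics — convex, space-filling segments with a spread
of sizes and one-pixel borders between them — while remaining geometry-exact
and fully seeded.  Controlled perturbations then induce each error type:

* ``widen`` — dilate borders (border-width variation; no split/merge),
* ``gap`` — punch holes in borders (merge errors),
* ``spurious`` — cut straight border lines across cells (split errors).

``simulate_challenge`` crosses segmentation quality (gap + spurious counts)
with border width over a grid of synthetic "teams" and measures how each
metric's ranking responds to border thinning, mirroring the retrospective
ranking-robustness analysis of the challenge.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BoundaryMap, LabelImage, ScoringError
from .evaluation import ScoreConfig, score_pair
from .morphology import _structure, dilate_borders, thin_borders

logger = logging.getLogger("emscore")

__all__ = [
    "PerturbSpec",
    "SimulationReport",
    "generate_ground_truth",
    "perturb",
    "simulate_challenge",
]

_MODES = ("widen", "gap", "spurious")


@dataclasses.dataclass(frozen=True)
class PerturbSpec:
    """One perturbation: ``mode`` in {widen, gap, spurious}, integer
    ``magnitude`` >= 1 (radius for widen, event count otherwise) and the seed
    of the perturbation's own random generator."""

    mode: str
    magnitude: int
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ScoringError(f"perturbation mode must be one of {_MODES}, got {self.mode!r}")
        if int(self.magnitude) != self.magnitude or self.magnitude < 1:
            raise ScoringError(f"perturbation magnitude must be a positive integer, got {self.magnitude}")


def generate_ground_truth(
    height: int,
    width: int,
    n_cells: int,
    rng_seed: int,
    connectivity: int = 4,
    max_attempts: int = 10,
) -> Tuple[LabelImage, BoundaryMap]:
    """Voronoi ground truth: ``n_cells`` cells with one-pixel borders.

    Seed points are sampled without replacement from the pixel grid (so
    duplicates cannot occur); each pixel joins its nearest seed (squared
    Euclidean distance, ties broken by lowest seed index).  A pixel whose
    right or down 4-neighbour belongs to a different cell is marked as border,
    and the marked map is then thinned so the result is a fixpoint of
    :func:`~emscore.morphology.thin_borders` (spur pixels inside a single cell
    are absorbed).  Degenerate tessellations — a cell losing its whole
    interior to border marking, or being split — are resampled with a logged
    warning.  Deterministic given ``rng_seed``.

    Returns the label image (component labels, 0 on borders) and the boundary
    map; the map has exactly ``n_cells`` foreground segments under the chosen
    connectivity.
    """
    if n_cells < 2:
        raise ScoringError("n_cells must be at least 2")
    if n_cells > height * width // 4:
        raise ScoringError("image too small for the requested number of cells")
    rng = np.random.default_rng(rng_seed)
    rr, cc = np.mgrid[0:height, 0:width]
    for attempt in range(max_attempts):
        flat = rng.choice(height * width, size=n_cells, replace=False)
        pr, pc = flat // width, flat % width
        d2 = (rr[..., None] - pr) ** 2 + (cc[..., None] - pc) ** 2
        voronoi = d2.argmin(axis=-1)  # first occurrence = lowest seed index

        border = np.ones((height, width), dtype=np.uint8)
        border[:, :-1][voronoi[:, :-1] != voronoi[:, 1:]] = 0
        border[:-1, :][voronoi[:-1, :] != voronoi[1:, :]] = 0
        bmap = thin_borders(BoundaryMap(border), connectivity)

        labels, n_found = ndimage.label(bmap.foreground(), structure=_structure(connectivity))
        if n_found == n_cells:
            return LabelImage(labels.astype(np.int64)), bmap
        logger.warning(
            "degenerate tessellation (attempt %d: %d components for %d cells); resampling seeds",
            attempt + 1,
            n_found,
            n_cells,
        )
    raise ScoringError(
        f"could not place {n_cells} cells on a {height}x{width} image in {max_attempts} attempts"
    )


def _punch_gaps(pixels: np.ndarray, centers: np.ndarray, radius: int) -> None:
    """Flip to foreground every 0-pixel within Chebyshev ``radius`` of each
    center (in place).  Only 0 -> 1 flips occur."""
    h, w = pixels.shape
    for r, c in centers:
        r0, r1 = max(0, r - radius), min(h, r + radius + 1)
        c0, c1 = max(0, c - radius), min(w, c + radius + 1)
        pixels[r0:r1, c0:c1] = 1


def _cut_chord(pixels: np.ndarray, comp_mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Cut one straight 0-line across a foreground component (in place).

    Picks a random orientation and a random interior row (or column) of the
    component and zeroes the component's pixels on that line; because the
    synthetic cells are convex this chord crosses the whole cell and splits it
    in two.  Returns the flipped pixel coordinates.
    """
    rows = np.flatnonzero(comp_mask.any(axis=1))
    cols = np.flatnonzero(comp_mask.any(axis=0))
    options = []
    if len(rows) >= 3:
        options.append("h")
    if len(cols) >= 3:
        options.append("v")
    if not options:
        return np.empty((0, 2), dtype=np.int64)
    orient = options[rng.integers(len(options))]
    if orient == "h":
        line = rng.choice(rows[1:-1])
        hit = comp_mask[line, :]
        coords = np.stack([np.full(hit.sum(), line), np.flatnonzero(hit)], axis=1)
    else:
        line = rng.choice(cols[1:-1])
        hit = comp_mask[:, line]
        coords = np.stack([np.flatnonzero(hit), np.full(hit.sum(), line)], axis=1)
    pixels[coords[:, 0], coords[:, 1]] = 0
    return coords


def perturb(bmap: BoundaryMap, spec: PerturbSpec, connectivity: int = 4) -> BoundaryMap:
    """Apply one controlled perturbation to a boundary map.

    * ``widen``: dilate all borders by Chebyshev radius ``magnitude`` (flips
      1 -> 0 near existing borders only; introduces no splits or merges
      relative to the thinned comparison).
    * ``gap``: pick ``magnitude`` random border pixels and flip each together
      with its bordering 8-neighbours to foreground — can merge cells.
    * ``spurious``: cut ``magnitude`` straight border chords across randomly
      chosen cells — can split cells.
    """
    rng = np.random.default_rng(spec.rng_seed)
    if spec.mode == "widen":
        if 2 * spec.magnitude + 1 > min(bmap.shape):
            raise ScoringError("widen magnitude exceeds the image extent")
        return dilate_borders(bmap, spec.magnitude)

    pixels = bmap.pixels.copy()
    if spec.mode == "gap":
        border = np.argwhere(pixels == 0)
        if len(border) == 0:
            return BoundaryMap(pixels)
        k = min(spec.magnitude, len(border))
        centers = border[rng.choice(len(border), size=k, replace=False)]
        _punch_gaps(pixels, centers, radius=1)
        return BoundaryMap(pixels)

    # spurious
    labels, n_comp = ndimage.label(pixels.astype(bool), structure=_structure(connectivity))
    if n_comp == 0:
        return BoundaryMap(pixels)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
    eligible = np.flatnonzero(sizes >= 3) + 1
    if len(eligible) == 0:
        return BoundaryMap(pixels)
    for _ in range(spec.magnitude):
        comp = eligible[rng.integers(len(eligible))]
        _cut_chord(pixels, labels == comp, rng)
    return BoundaryMap(pixels)


@dataclasses.dataclass(frozen=True)
class SimulationReport:
    """Outcome of one synthetic challenge: per-team scores and the four
    Spearman correlations between rankings."""

    scores: pd.DataFrame  # per team: quality, width, rand/info x raw/thinned
    correlations: Dict[str, float]
    rng_seed: int
    config: Dict[str, object]


def _safe_rho(a: np.ndarray, b: np.ndarray, name: str) -> float:
    from .evaluation import spearman_rank

    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("correlation %s undefined (constant scores); reporting NaN", name)
        return float("nan")
    return spearman_rank(a, b)


def simulate_challenge(
    n_teams: int = 12,
    quality_grid: Sequence[Tuple[int, int]] = ((1, 1), (2, 2), (4, 4)),
    border_width_grid: Sequence[int] = (1, 2, 3, 4),
    rng_seed: int = 0,
    n_slices: int = 2,
    height: int = 256,
    width: int = 256,
    n_cells: int = 12,
    connectivity: int = 4,
    alpha: float = 0.5,
) -> SimulationReport:
    """Synthetic rank-robustness experiment.

    Builds a ground-truth stack plus ``n_teams`` submissions on the cross of
    ``quality_grid`` (pairs of per-slice gap and spurious-line counts) with
    ``border_width_grid`` (total border width in pixels; width 1 is the
    un-widened ground truth geometry).  Teams sharing a quality level share
    the same error realisation, and gaps are punched with a hole radius one
    larger than the widening radius, so the split/merge error set of a team is
    identical at every width — the width axis varies border geometry only.

    Scores every team with both metric families, raw and thinned, ranks by
    mean F-score, and reports the four Spearman rank correlations:
    ``rand_info_raw``, ``rand_info_thinned``, ``rand_raw_thinned``,
    ``info_raw_thinned``.  Deterministic per ``rng_seed``.
    """
    if n_teams < 5:
        raise ScoringError("simulate_challenge requires at least 5 teams")
    if min(border_width_grid) < 1:
        raise ScoringError("border widths must be >= 1 pixel")
    root = np.random.default_rng(rng_seed)
    gt_pairs = [
        generate_ground_truth(height, width, n_cells, int(root.integers(2**31)), connectivity)
        for _ in range(n_slices)
    ]
    gts = [bm for _, bm in gt_pairs]
    struct = _structure(connectivity)

    # Error plans are drawn per (quality level, slice): gap centres on the thin
    # ground-truth border and spurious chord pixel sets.
    plans: List[List[Dict[str, np.ndarray]]] = []
    for n_gap, n_spur in quality_grid:
        level_rng = np.random.default_rng(root.integers(2**31))
        per_slice = []
        for gt in gts:
            border = np.argwhere(gt.pixels == 0)
            k = min(n_gap, len(border))
            centers = (
                border[level_rng.choice(len(border), size=k, replace=False)]
                if k
                else np.empty((0, 2), dtype=np.int64)
            )
            chord_map = gt.pixels.copy()
            labels, n_comp = ndimage.label(chord_map.astype(bool), structure=struct)
            chords = []
            for _ in range(n_spur):
                comp = 1 + level_rng.integers(n_comp)
                chords.append(_cut_chord(chord_map, labels == comp, level_rng))
            per_slice.append(
                {
                    "centers": centers,
                    "chords": np.concatenate(chords) if chords else np.empty((0, 2), dtype=np.int64),
                }
            )
        plans.append(per_slice)

    teams = list(
        (qi, w)
        for qi in range(len(quality_grid))
        for w in border_width_grid
    )
    if len(teams) < n_teams:
        raise ScoringError(
            f"quality x width grid provides only {len(teams)} distinct teams for n_teams={n_teams}"
        )
    teams = teams[:n_teams]

    raw_cfg = ScoreConfig(thin=False, connectivity=connectivity, alpha=alpha)
    thin_cfg = ScoreConfig(thin=True, connectivity=connectivity, alpha=alpha)
    rows = []
    for team_idx, (qi, w) in enumerate(teams):
        radius = w - 1
        per_metric: Dict[str, List[float]] = {k: [] for k in ("rand_raw", "info_raw", "rand_thinned", "info_thinned")}
        for s, gt in enumerate(gts):
            plan = plans[qi][s]
            pixels = gt.pixels.copy()
            if len(plan["chords"]):
                pixels[plan["chords"][:, 0], plan["chords"][:, 1]] = 0
            pred = BoundaryMap(pixels)
            if radius >= 1:
                pred = dilate_borders(pred, radius)
            pixels = pred.pixels.copy()
            _punch_gaps(pixels, plan["centers"], radius=radius + 1)
            pred = BoundaryMap(pixels)
            raw = score_pair(pred, gt, raw_cfg)
            thinned = score_pair(pred, gt, thin_cfg)
            per_metric["rand_raw"].append(raw.rand.fscore)
            per_metric["info_raw"].append(raw.info.fscore)
            per_metric["rand_thinned"].append(thinned.rand.fscore)
            per_metric["info_thinned"].append(thinned.info.fscore)
        rows.append(
            {
                "team": f"team{team_idx:02d}",
                "quality_level": qi,
                "n_gaps": quality_grid[qi][0],
                "n_spurious": quality_grid[qi][1],
                "border_width": w,
                **{k: float(np.mean(v)) for k, v in per_metric.items()},
            }
        )
    scores = pd.DataFrame(rows)
    if len(np.unique(scores["rand_raw"].round(12))) < 3:
        raise ScoringError("fewer than 3 distinct raw scores; rank correlations undefined")

    correlations = {
        "rand_info_raw": _safe_rho(scores["rand_raw"].to_numpy(), scores["info_raw"].to_numpy(), "rand_info_raw"),
        "rand_info_thinned": _safe_rho(
            scores["rand_thinned"].to_numpy(), scores["info_thinned"].to_numpy(), "rand_info_thinned"
        ),
        "rand_raw_thinned": _safe_rho(
            scores["rand_raw"].to_numpy(), scores["rand_thinned"].to_numpy(), "rand_raw_thinned"
        ),
        "info_raw_thinned": _safe_rho(
            scores["info_raw"].to_numpy(), scores["info_thinned"].to_numpy(), "info_raw_thinned"
        ),
    }
    config = {
        "n_teams": n_teams,
        "quality_grid": tuple(map(tuple, quality_grid)),
        "border_width_grid": tuple(border_width_grid),
        "n_slices": n_slices,
        "height": height,
        "width": width,
        "n_cells": n_cells,
        "connectivity": connectivity,
        "alpha": alpha,
    }
    logger.info("simulate_challenge seed=%d correlations=%s", rng_seed, correlations)
    return SimulationReport(scores=scores, correlations=correlations, rng_seed=rng_seed, config=config)
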