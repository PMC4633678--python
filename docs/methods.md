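# Methods

## Scope and model

`emscore` scores 2D segmentations of neurite cross-sections that are encoded
as binary boundary maps (1 = cell interior, 0 = border).  Slices of a stack
are scored independently — there is no 3D continuity model.  All region
scores are functions of one sufficient statistic: the contingency table of
joint pixel counts over (predicted segment, true segment) pairs inside an
evaluation mask.

Conventions, fixed across the package:

* coordinates are row-major and 0-based;
* segments are connected components of 1-pixels; **every 0-pixel is its own
  one-pixel segment**.  This convention is what makes over-wide predicted
  borders visible to the scores: border pixels that intrude into ground-truth
  foreground become in-mask singletons and fragment the prediction;
* default connectivity is 4.  With 8-connectivity a one-pixel diagonal border
  fails to separate the cells on either side, defeating the representation;
  8 remains available everywhere via a flag;
* *foreground restriction* (default on): ground-truth border pixels are
  excluded from the mask.  The prediction is always segmented on the full
  image first — the mask restricts pair counting only, so a prediction cannot
  be rewarded for errors it hides outside the ground-truth foreground;
* label images reserve 0 for "unlabeled/excluded"; every score is invariant
  under bijective relabeling of positive labels (tested).

## Score formulas and numerical policy

Rand family: `split = Σp²/Σt²`, `merge = Σp²/Σs²`,
`F_α = Σp²/(αΣs² + (1−α)Σt²)`.  The three pair-count sums are accumulated as
exact Python integers (`Σn_ij²` etc.) and divided once, so `F_0 == split` and
`F_1 == merge` hold to the bit and no accumulation error enters.

Information-theoretic family: `I = Σp log p − Σs log s − Σt log t` (natural
logs, `0·log 0 := 0`), `split = I/H(S)`, `merge = I/H(T)`,
`F_α = I/((1−α)H(S) + αH(T))`.  Every score is a ratio of log-sums, so the
base cancels; invariance under base change is a tested property rather than a
promise.

Degenerate partitions (the corner cases the formulas leave open) follow these
conventions, reported via `degenerate_flags`:

* `H(S) = 0` (one predicted segment): `I := 0` and `split := 1` — a
  one-segment prediction asserts nothing false about splits.  Symmetrically
  for `H(T) = 0`.
* The F-score is always evaluated from its own formula, never from the two
  ratios, so it degrades gracefully: an all-merged prediction scores
  info-F = 0 at α = 0.5.  Only when the F denominator is exactly 0 is F set
  to 1.
* A one-to-one table (every predicted segment meets exactly one true segment
  and vice versa) is detected structurally and scores exactly 1.0 in all six
  numbers.  This keeps "perfect = 1.0" free of floating-point noise; the
  detection is exact, not a tolerance.

Mutual information is clamped at 0 from below (it can round to −1e-17);
ratios are clamped into [0, 1].

## Border thinning

Thinning removes border-width variation before scoring while provably never
merging objects.  Segments are grown back over the border one adjacency layer
per pass: each pass freezes the set of 0-pixels adjacent to foreground at the
start of the pass, scans them in row-major order, and flips a pixel iff all
its current foreground neighbours carry the same segment label, updating
labels immediately.  The immediate update guarantees no flip can join two
labels (the non-merge property, tested as a relabeled-identity contingency of
thinned vs input on the input's foreground); freezing each pass's candidates
makes opposite sides of a widened border advance symmetrically, so a border
dilated by `r` is restored to its exact position on straight and diagonal
borders (unit-tested).  The implementation bulk-flips all uncontested
candidates per pass and resolves only collisions between growth fronts
sequentially; this is equivalent to the pure sequential scan (verified
against a reference implementation on hundreds of random maps) and fast
enough for 512×512 slices.

At the fixpoint every remaining 0-pixel touches either no foreground or two
distinct segments.  "About one pixel wide" is realised as this fixpoint
property, not as a hard width bound: junction clusters can remain locally two
pixels wide.  Dead-end border spurs inside a single cell are absorbed.

Two consequences worth knowing:

* **Dilation is not exactly invertible on curved borders.**  At staircase
  corners the dilated band is asymmetric with respect to the growth metric,
  so a few pixels per corner either remain 0 (in-mask singletons) or attach
  to the neighbouring cell.  On Voronoi ground truths, `thin(dilate(gt, 1))`
  scores ≈ 0.98 rather than 1.0 against `gt`, while the partition itself
  (which cells exist, what touches what) is restored exactly.  No local rule
  that also guarantees non-merging can do better in general — the corner
  information is destroyed by the dilation.
* Thinning can legitimately change scores even for already-thin maps: spur
  pixels at the end of a spurious split line are absorbed, and if a boundary
  gap reconnects the two halves of a split cell the whole split line becomes
  absorbable.

`dilate_borders` is the converse primitive (Chebyshev-ball dilation of the
0-set, image border treated as foreground) used to manufacture border-width
perturbations.

## Aggregation and statistics

Stacks are scored per slice; reports give the arithmetic mean of per-slice
F-scores ± **standard error** (sample SD / √n).  The uncertainty convention
is stated in the output because "±" is ambiguous in the historical score
tables; standard error was chosen as the natural uncertainty of the mean at
10–30 slices.

Probabilistic maps are binarized at `pixel ≥ t → 1` over a threshold grid
(default 0.01…0.99, step 0.01) and the argmax-F point is reported, which is
how probabilistic submissions enter rankings.  Leaderboards sort by the raw
(un-thinned) Rand F-score — the historical official ranking — with
alphabetical tie-breaks, and report both families raw and thinned.

`spearman_rank` is the Pearson correlation of average ranks (delegated to
scipy); it refuses constant inputs.  `wilcoxon_signed_rank` drops zero
differences and, for n ≤ 12 remaining pairs, enumerates all 2ⁿ sign
assignments of the average-ranked |differences| exactly (ties are handled
naturally by the enumeration, which is why this is hand-written); above that
it uses the tie-corrected normal approximation without continuity
correction.  The two-sided p is `min(1, 2·min(P(W≤w), P(W≥w)))`.  scipy's
implementation serves as an independent cross-check in the tests.

## Synthetic data

`generate_ground_truth` draws `n_cells` seed points without replacement from
the pixel grid, labels each pixel by its nearest seed (squared Euclidean
distance, ties to the lowest seed index), marks a pixel as border when its
right or down neighbour belongs to a different cell, and thins the result so
the ground truth is itself a thinning fixpoint.  Voronoi cells stand in for
neurite cross-sections: convex, space-filling, with a realistic spread of
segment sizes.  The metrics are geometry-agnostic, so no attempt is made to
emulate EM texture, grayscale appearance, organelle boundaries, or 3D
continuity between slices — passing tests say nothing about boundary
*detection* difficulty on real images, only about score behaviour given a
segmentation.  Degenerate tessellations (a cell losing its interior) are
resampled with a logged warning; everything is deterministic per seed.

Perturbations (`perturb`) realise the three error types: `widen` dilates all
borders (width variation, no topology change), `gap` punches holes through
borders (merge errors), `spurious` cuts a straight chord across a cell (split
errors; chords are axis-aligned interior lines, which on convex cells always
cross the whole cell).

## The ranking-robustness experiment

`simulate_challenge` builds a synthetic "challenge": teams on the cross of
quality levels (gap + spurious counts per slice) with border widths, scored
with both families, raw and thinned, and compared via four Spearman
correlations (rand-vs-info raw; rand-vs-info thinned; rand raw-vs-thinned;
info raw-vs-thinned).  Design choices that matter:

* teams sharing a quality level share the same error realisation, and gaps
  are punched with a Chebyshev hole of radius (widening radius + 1) centred
  on thin-border pixels, so a team's split/merge error set is identical at
  every width — the width axis manipulates geometry only;
* spurious cuts are applied before widening (so split lines widen like real
  borders and thin back like them).

Defaults — 2 slices of 256×256 with 12 cells (cell diameter ≈ 70 px, 1-px
borders ≈ 2.5% of pixels), quality levels (1,1)/(2,2)/(4,4), widths 1–4 px,
12 teams — were chosen so the generator operates in the regime the metrics
were designed for, where borders are thin relative to cells: width effects on
the Rand F-score stay within ≈ 0.1 while the information-theoretic score
loses up to ≈ 0.25, and quality effects dominate Rand.  In this regime the
experiment reproduces the characteristic result: thinning raises the
agreement between the two families' rankings (median Spearman ρ ≈ 0.80 raw →
≈ 0.99 thinned over 20 seeds) and the Rand ranking is far more robust to
thinning than the information-theoretic one (ρ ≈ 0.91 vs ≈ 0.62).  If the
cells are made small relative to the border widths, both families become
width-dominated and the contrast disappears — the effect is a property of the
thin-border regime, not of the formulas alone.

An individual correlation whose inputs are constant (e.g. thinned scores all
exactly 1 in a width-only scenario) is reported as NaN with a warning; a
scenario with fewer than three distinct raw scores is rejected outright.

## Known limitations

* 2D only; anisotropic-z / supervoxel scoring is out of scope.
* Thinning is contractual on the non-merge guarantee, not on exact border
  placement at corners (see above).
* The Wilcoxon normal approximation is used above n = 12; at challenge scale
  (10–30 slices) this is the standard trade-off, but p-values near
  significance thresholds at n = 13–25 are approximate.
* The synthetic generator does not model spatially correlated errors or
  slice-to-slice correlation, so its standard errors are optimistic relative
  to real submissions.
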