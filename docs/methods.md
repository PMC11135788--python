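# Methods

This note documents the model implemented by `landmosaic`, the numerical
choices behind it, what the synthetic generators do and do not emulate,
and known limitations.

## The mosaic model

Each pixel with a valid (non-nodata) value receives the composition
(*a, n, d*) of agriculture / natural / developed land inside the centred
square window of odd side *w*, intersected with the map and excluding
nodata pixels. Composition order is fixed as (a, n, d) everywhere.
Proportions are ratios of integer counts; the counts come from integer
summed-area tables and are therefore exactly equal to literal per-pixel
counting (this equivalence is asserted against a brute-force oracle in
the test suite).

Two contracts follow from "proportions over observed land":

- **Edge handling.** Pixels outside the raster are treated as missing;
  the window shrinks rather than padding or reflecting. No data is
  fabricated, at the cost of smaller denominators along the map margin.
- **Centre-nodata.** A nodata pixel receives nodata output even when its
  neighbourhood is valid: the mosaic label describes a location's
  context, and an undefined location has no label.

A window is *pure* iff its class count equals its valid total — an exact
integer test, immune to 0.999… float artifacts. Only pure windows map to
the corner classes `AA`/`NN`/`DD`.

### 19-class labels

With presence *p* = 0.1 and dominance *q* = 0.6 (both configurable,
uniqueness fixed at 1): per component, uppercase iff proportion ∈ [q, 1),
lowercase iff ∈ [p, q), omitted below *p*; doubled letter on purity.
Threshold comparisons on count data are done with exact rational
arithmetic (count·denominator vs numerator·total), so boundary
compositions such as 3/5 are classified deterministically. Names list the
uppercase letter first and lowercase letters alphabetically (`Adn`,
`Nad`, `dn`, …). Canonical integer codes order the three dominance
blocks, then the two-letter mixtures, then `adn` (code 16 — its published
pixel value), then the corners.

### 103-class cells

Decile indices are floors of 10 × proportion, computed as
`(10·count) // total` on integer data (a 1e-9 guard is added before the
floor for float compositions, since deciles like 0.7 are not exactly
representable in binary). Indices sum to 9 (upward cell, 55 of them) or
8 (downward, 45); plus 3 corners = 103 cells partitioning the chart.

**Grid-intersection tie rule.** Compositions whose three indices sum
to 10 lie exactly on a decile grid intersection (all three proportions
are exact decile multiples) and must be assigned to one adjacent cell.
The package decrements the largest component whose index is *not* one of
the 19-region boundary deciles {1, 6}, breaking ties in the order
d > a > n. Such a component always exists — indices drawn from {0, 1, 6}
can sum to at most 8 — so the rule is total and deterministic, and it
has a property no "decrement the largest" rule can offer: the chosen cell
always lies in the same 19-class region as the composition itself
(boundary thresholds are inclusive-lower on both schemes), so the
19-class raster, the 103-class raster and the heatmap stay mutually
consistent pixel for pixel. This was verified exhaustively for every
count triple with total ≤ 60. The rule affects only a measure-zero set of
compositions but a non-negligible set of real windows (truncated windows
whose totals share factors with 10). One consequence, inherent to any
deterministic tie rule: exact-tie compositions such as (0.5, 0.5, 0)
cannot be assigned symmetrically, so permutation equivariance of the cell
assignment holds only off the grid intersections.

Canonical triangle codes run 1–100 in a documented order (descending
agriculture decile, then descending natural decile, upward before
downward); the corner codes 170/180/190 are fixed anchors. Users can
substitute a full code table (CSV `kind,la,ln,ld,code`) to match an
external legend; validation enforces a bijection over the 103 cells and
the corner anchors.

## Heatmap and deltas

The heatmap is the percent frequency of valid pixels per cell, kept at
full precision (integer rounding is display-only and never feeds
computation); nodata pixels are excluded from the denominator, consistent
with the windowing contract. Delta heatmaps are cellwise differences and
sum to 0 by construction. Group summaries over any covering partition
conserve total mass exactly, and aggregating heatmap mass through the
cell→19 mapping reproduces the 19-class histogram exactly (see the tie
rule above). CSV interchange uses `repr`-precision floats for lossless
round-trips; a matplotlib rendering of the triangular layout is optional
and makes no claim of matching any published graphic.

## Reporting schemes

All partitions are built from predicates evaluated at cell centroids —
corners map to unit vectors, an upward cell (i, j, k) to
((3i+1)/30, …), a downward one to ((3i+2)/30, …) — so groups align with
whole cells, and with decile-multiple thresholds the centroid's 19-label
holds for every interior point of its cell.

- **Background** (dominance 0.6): `Ax`/`Nx`/`Dx` = centroid component
  ≥ 0.6 → 17 cells each (10 upward, 6 downward, 1 corner); `mixed` = the
  remaining 52.
- **Diversity**: `uniform` = max component > 0.85 (9 cells: the three
  corners plus the two cells hugging each corner); `intermix` = all
  components in (0.25, 0.40) → the central upward cell (3,3,3) and its
  three downward neighbours, 4 cells. A minimum-only predicate (all
  ≥ 0.25) would also admit the six downward cells with one component at
  14/30 ≈ 0.47, which are visibly lopsided rather than near-equal; the
  symmetric band keeps `intermix` to the near-equal core. `triple` =
  remaining cells with all components ≥ 0.1 (45); `dual` = the rest (45).
  All four thresholds are parameters.
- **Refined mixed**: within the 52 mixed cells, `adn2` = all components
  ≥ 0.2 (16 cells); otherwise the interface class *opposite* the minimum
  component (scarce agriculture → `dn2`, etc.), giving 12 cells each —
  four groups of approximately equal extent. Minimum ties are broken in
  the order a, d, n; a test asserts the tie never actually triggers among
  mixed cells under the defaults.
- **Intensity categories**: cells binned by intensity into six
  equal-width bins over [0, 100] (edges configurable), the last bin
  closed.

### Anthropic intensity

`intensity = 100 · (w_d · d̄ + w_a · ā)` at the cell centroid, defaults
w_d = 1.0, w_a = 0.5. This is the unique linear centroid model that
reproduces all three anchors — 0 for `NN`, 100 for `DD`, and 85 for the
cell (0,1,8), third from the developed corner along the developed–natural
edge — while weighting development above agriculture. Pure agriculture
scores 50 under the defaults. A per-cell override table lets users encode
any bespoke weighting exactly; overrides are validated against the cell
set. Intensity is strictly increasing in the developed decile at fixed
agriculture decile, and (verified exhaustively for totals ≤ 60)
single-pixel natural→developed conversions never lower a window's
intensity.

## Change products

Intensity change is the per-pixel difference of two intensity rasters
from the same model, NaN-propagating. "No change" means exact equality:
default intensities are rational constants per cell, so identical cells
give exactly zero difference and a tolerance would only blur the
statistic (a tolerance parameter exists for continuous override models).
Change statistics report percent unchanged/changed over valid pixels and
an integer-resolution histogram of the changed pixels only; display
groupings of the histogram are user-supplied and must tile [−100, 100].

## Synthetic landscapes

The generators exist so every stage is testable without redistributing
land-cover products; they emulate the *statistical* structure the model
responds to, not real geography.

- `simulate_landscape`: three independent Gaussian fields smoothed to a
  configurable autocorrelation length (the patch scale, default 10 px on
  a 200×200 default grid — patches well below the largest default
  window) drive nodata placement, developed patches and agriculture
  patches; class membership is decided by *rank* thresholds, so realized
  proportions hit the targets to the pixel regardless of the noise law.
  Defaults (0.2, 0.6, 0.2) describe a natural-dominated landscape with
  substantial agriculture and development, the regime where mosaic
  interface zones are most informative.
- `simulate_change`: converts exactly `round(rate × n_natural)` natural
  pixels to developed, sampling without replacement with weight
  1 + 5·k where k is the pixel's count of developed 8-neighbours — a
  sprawl/infill analogue producing growth rings around existing
  development plus occasional new seeds.

What they do **not** emulate: legend noise and misclassification,
anisotropy, roads and other linear infrastructure, topographic
constraints, or agricultural abandonment. Passing tests therefore
demonstrate the correctness and invariances of the *method* (exact
counting, conservation, scale monotonicity on landscapes with sub-window
patch scale), not calibration against any real region.

## Problem sizes and numerical notes

The test suite runs the engine-vs-oracle comparison on ≤ 40×250 rasters
(all five default windows, with nodata), the scale-monotonicity check on
500×500 two-patch and autocorrelated landscapes across windows 7–243,
and exhaustive sweeps (0.01-step simplex; all count triples to total 60)
for the classification rules; the whole suite completes in a few seconds
on one CPU. Window sizes must be odd so windows are centred; a window
larger than both raster dimensions is rejected as degenerate (larger than
one dimension is fine — the window truncates). Heatmap/delta validation
tolerances are 1e-6 on sums of percentages; composition closure is
checked at 1e-9.

## Limitations

- The grid-intersection tie rule preserves 19/103 consistency for the
  default decile thresholds {0.1, 0.6}; with other decile thresholds the
  excluded boundary set {1, 6} would need to move accordingly (the
  19-classifier itself accepts any thresholds, and `cell_to_19` rejects
  non-decile ones).
- GeoTIFF support covers single-band integer rasters; georeferencing is
  passed through verbatim (model/key/GDAL tags) rather than interpreted.
  Reprojection, tiling and out-of-core processing are out of scope.
- Published figure colors and category edges that are not stated
  numerically are approximated by documented defaults; color tables are
  explicitly user-replaceable.
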