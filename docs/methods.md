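# Methods

This note documents the models, conventions and design choices behind
`glandscan`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under which assumptions, with which
defaults, and what the synthetic validation does and does not show.

## Coordinate and rasterization conventions

All geometry lives in pixel units with `x = column`, `y = row` (y pointing
down), 0-based, and pixel centers at integer coordinates. A pixel or voxel
belongs to a shape iff its **center** lies inside it: the even-odd
(crossing-number) rule for polygons, `Σ((v−c)/r)² ≤ 1` for axis-aligned
ellipsoids. The crossing test uses the half-open edge rule
`(y1 ≤ y) != (y2 ≤ y)` with strict `x < x_intersect`, which makes two
polygons sharing an edge partition on-edge points consistently — this is
what guarantees that the proximal and distal sub-ROIs tile the gland mask
exactly. Physical calibration (µm per pixel/voxel, stored in a JSON
sidecar, never in TIFF tags) is applied only when physical quantities are
produced; notably it is *not* applied before the attachment log-ratio (see
below).

## Axial profiling

The longitudinal axis is the Feret axis: the polygon vertex pair with
maximal Euclidean distance, found on the convex hull (which is exactly the
brute-force pairwise maximum), with the segment's angle mapped to
(−90°, 90°] measured from +x. Profiling rotates the image by the negative
Feret angle (bilinear interpolation; nearest-neighbor for the mask) and
takes the mean in-mask intensity of every 1-px column — equivalent to
sweeping rectangular line regions perpendicular to the axis, but easier to
verify. Two numerical details matter:

* the rotation maps the **pixel-center extent**, so a 0° rotation is the
  exact identity (no half-pixel resampling);
* the rotated mask is **eroded by 1 px** (`erode_margin`, configurable)
  before averaging, because bilinear interpolation blends boundary pixels
  with the image background and would otherwise bias slab means downward
  by a few percent. With erosion, binned profiles of the same gland at
  rotations 0–63° agree within ~0.5% of the dynamic range (the test suite
  enforces <2%).

Gland polarity cannot be inferred from the outline, so orientation is
fixed by an explicit **anchor point** at the proximal tip (the duct end);
without an anchor the profile is returned unoriented, and oriented and
unoriented profiles are never pooled.

Cross-gland aggregation maps positions to the relative axis coordinate
`position / Feret length`, bins into `n_bins` (default 256, a mid-range
choice for glands spanning a few hundred pixels; configurable), and
averages per bin. Under the default `per-gland-mean` normalization each
gland's profile is first divided by its own unweighted mean, so each gland
contributes shape rather than brightness and every normalized gland
profile averages to 1; a `none` option keeps raw intensities. Per-gland
reporter profiles can additionally be divided pointwise by a
driver-independent counterstain profile (`normalize_profile`, guard
ε = 10⁻⁶ of the reference maximum against empty reference slabs).

The smoother is a hand-written loess: for each grid point, a degree-2
polynomial (degree configurable) is fit to the `ceil(span·n)` nearest
neighbors under tricube weights `(1 − (d/d_max)³)³`, with no robustness
iterations; defaults span 0.05, degree 2, matching the common
`geom_smooth`-style presentation of such profiles. The smoother is applied
to the cross-gland mean only, never to raw per-gland data. It reproduces
polynomials up to its degree exactly; a window with fewer than degree+1
positively weighted points raises an error naming the grid point rather
than silently extrapolating.

## Nuclear morphometry

Segmentation is a global threshold of the DAPI channel — Otsu on a 256-bin
histogram by default (the field's plugin workflows rarely report their
threshold; a fixed-value override exists for reproducibility) — followed by
connected-component labeling at 26-connectivity (the convention of the
classic 3D object counters; 6-connectivity available). Volume is voxel
count × voxel volume; centroids are intensity-unweighted. Components below
`min_size_voxels` (default 64) are dropped as debris and counted in a QC
log, so voxel totals are conserved. Nuclei touching the stack border are
retained. Compartment assignment uses a 2D point-in-polygon test of the
(x, y) centroid against the PP/DP polygons — one hand-drawn 2D ROI is
shared by all slices of a stack, so z is deliberately ignored; overlapping
PP/DP polygons are rejected. Touching-nuclei splitting (watershed) is out
of scope: the synthetic generator places nuclei with a separation margin,
and the plugin workflows this mirrors do not split either.

Hypertrophy is summarized as `mean(per-gland means of group) /
mean(per-gland means of control)`; averaging per gland first keeps glands,
not nuclei, as the experimental unit.

## Hemocyte attachment

The statistic is `ln(hemocyte area) / ln(gland area)` with both areas in
**pixels**. Calibration is deliberately not applied before the logs: ln is
not scale-equivariant, so the statistic depends on the unit convention,
and the pixel-unit convention of the original macro workflows is kept and
recorded in output metadata. A hemocyte area ≤ 1 px maps to 0 ("no
attachment"); a gland area < 2 px is an error. The statistic is strictly
increasing in hemocyte area (above the 1-px floor) and invariant under the
power transform `(a, A) → (a^k, A^k)`. The segmentation threshold is an
explicit required parameter (unreported in the source workflows); an
optional 3×3 median filter suppresses single-pixel speckle. Effect sizes
divide both samples by the reference mean, anchoring the reference at
exactly 1.

## Per-nucleus correlation

"Accumulated" intensity is read literally as the **sum** of a channel over
a nucleus' voxels (a mean-intensity variant is a one-line change via the
per-nucleus voxel counts). Pearson r and an ordinary least-squares fit are
computed on log10-transformed sums, per compartment and pooled; nuclei
with a non-positive sum in either channel are excluded before the log
(count reported), and groups with n < 3 are flagged missing rather than
reported. No background subtraction is applied before accumulation.

## Statistics battery

* Shapiro–Wilk for normality (3 ≤ n ≤ 5000).
* A parametric bootstrap of normal goodness-of-fit: fit N(µ̂, σ̂) by MLE,
  compute the KS distance, and compare with B (default 1000) parametric
  resamples each refit to its own normal (the Lilliefors construction);
  p = fraction of resample distances exceeding the observed.
* Bartlett's K² for variance homogeneity.
* `t_test_auto`: Bartlett on the two groups gates between pooled-variance
  Student's t (gate p ≥ α_var) and Welch's t; α_var defaults to 0.05 (the
  gate level is a convention choice; the branch taken and the gate p-value
  are recorded in every result).
* Tie-corrected Kruskal–Wallis with Dunn's pairwise z-tests,
  `z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j))`;
  pairwise p-values unadjusted by default (Holm optional). An all-tied
  input yields H = 0, p = 1 rather than an error.
* All tests are two-sided; stars follow *** p<0.001, ** p<0.01, * p<0.05,
  n.s. p≥0.05 with half-open boundaries (p = 0.05 is n.s.).

The reporter assay scores, per replicate of 24 larvae, the fraction
showing no reporter signal, and compares genotypes with Kruskal–Wallis +
Dunn on those per-replicate fractions.

Calibration of the battery is verified by matched-null simulation (type-I
error within 0.05 ± 0.01–0.02 at 600–10⁴ replicates depending on the
test's cost) and by hand-computed worked examples (pooled t = −1.2247,
p = 0.2879 on {1,2,3} vs {2,3,4}; H = 7.2, p ≈ 0.0273 on
{1,2,3},{4,5,6},{7,8,9}).

## Synthetic data: what it emulates, and what it does not

The generator exists because the raw confocal images behind published
gland measurements are typically not deposited. It emulates the features
the measurements depend on — elongated, optionally rotated/bent capsule
glands; per-channel axial intensity functions (constant, linear,
proximal/distal step); disjoint hemocyte disks of known total area,
optionally compartment-restricted; two nuclear populations as digital
ellipsoids with per-compartment radius distributions; per-nucleus
two-channel totals drawn from a bivariate normal on log10 scale with set
correlation ρ; additive Gaussian and/or Poisson noise on intensities.

Key invariants: noise never touches geometry, so masks, pixel/voxel counts
and axial-position maps are exact; every generator is a pure function of
(spec, seed), with named sub-streams for geometry, placement and noise;
the relative axial position of a pixel is the normalized arc-length
coordinate of its nearest centerline point, stored so profiler error is
measurable; nuclei are placed with a 2-voxel halo so they remain separable
at 26-connectivity, matching the no-splitting segmentation; the marker
totals recorded as ground truth are the rendered sums, so accumulation can
be checked exactly.

What it does **not** emulate: point-spread-function blur, depth
attenuation, chromatic shifts, touching or disintegrating nuclei,
cell-membrane texture, or curved 3D gland surfaces. Passing the synthetic
battery therefore demonstrates correctness of the geometry, accounting and
statistics — not robustness to optical artifacts of real confocal data.
Bent glands are still profiled along the straight Feret axis (as in the
original macro); the bend amplitude parameter exists precisely to quantify
the resulting bias rather than to correct it.

## Problem sizes and determinism

The shipped demo study uses 5 glands per cohort, 140×200 px images
(gland 150×36 px), and 24×110×160 stacks with 24 nuclei per gland
(control radius 2.3 µm; the hypertrophic radius is the control radius ×
fold^(1/3), fold defaulting to 5.66 with a proportional ±10% radius
spread so the expected volume ratio equals the fold). Validation studies
use up to 500 nuclei per stack (correlation recovery) — sizes chosen so
the whole battery runs in minutes on a laptop core while keeping
Monte-Carlo tolerances meaningful. Every pipeline output carries the
master seed and a config hash, and re-running with identical config and
seed reproduces all CSV outputs byte-identically.

## Known limitations

* The straight-axis profile underestimates arc-length position for
  strongly bent glands (by design, see above).
* Otsu assumes a bimodal intensity histogram; dim or unstained stacks
  should use the fixed threshold.
* The attachment statistic's pixel-unit convention means values are
  comparable only across images with the same magnification.
* Dunn p-values are unadjusted by default; enable Holm when many pairwise
  comparisons are reported together.
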