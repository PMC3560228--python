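# Methods

This note documents the models, parameter choices and numerical
conventions behind `microcirc`, and what the synthetic validation does
and does not demonstrate.

## Imaging model and conventions

SDF-type devices render hemoglobin dark: capillaries are visible where
red cells are, on a bright tissue background. Frames are float64 in
[0, 1], normalized by the container's full-scale value (255/65535) so
thresholds are comparable across recordings; RGB input is reduced to
the green channel (the 550 nm contrast carrier), with a luma override.
Coordinates are (row, col), 0-based, row 0 at top. The default pixel
scale is 20/13 ≈ 1.538 µm/px, the scale at which the 13 px diameter cap
corresponds to a ~20 µm capillary.

## Stabilization

Translation-only, integer shifts. Control points are maxima of
|Laplacian| of the Gaussian-gradient magnitude (σ = 1.5 px, first-order
Gaussian derivatives; the Laplacian is the 4-connected 3×3 kernel, and
the absolute response is used since only saliency matters). The frame
is partitioned into a 3×3 grid; the 7 tiles with the strongest interior
peaks contribute one point each — spatial spread with exactly seven
areas. Matching is zero-mean NCC of a 25×25 reference patch against
placements inside a 40×40 window, offsets in [−7, 7]²; ties are broken
toward the smallest |dy|+|dx|, then dy, then dx, so results are
reproducible. The per-step frame shift is the component-wise median of
the 7 displacements, which tolerates up to 3 mismatched points. Points
are advected by the frame shift; any point reaching the 12 px border
margin (or a saturated ±7 step) triggers full re-seeding on the current
frame. Aligned frames use edge replication; all downstream density
measurements are restricted to the rectangle common to every aligned
frame, so padding never contributes vessels.

Limitations: no rotation, no subpixel motion. On scenes whose only
strong features are *moving* (e.g. phantoms with sparse cell trains and
no static texture) control points can lock onto flow; real mucosal
video carries static texture and stagnant vessels that anchor the
match. Exactness is therefore asserted on static-scene replays, where
camera motion is the only temporal change.

## Per-level preprocessing and threshold calibration

Each analyzed frame position uses the weighted mean of the 5
surrounding stabilized frames with weights (1,2,3,2,1)/9 — the middle
frame heaviest; a sliding window (clamped at the ends) yields one mean
frame per analyzed position, so 20 segmented frames support the
temporal flow analysis. Per level, the mean frame passes CLAHE
(scikit-image, clip limit 0.01) → median filter (edge-replicated) →
linear stretch of the 1st–99th percentiles to [0, 1]. CLAHE tiles are
(8, 8, 16, 16, 24, 24, 32, 32, 48, 64) px and median kernels
(7, 7, 7, 5, 5, 5, 5, 3, 3, 3): low levels suppress thin structure
(large kernels, local tiles) so only wide clear vessels survive the low
threshold, high levels preserve thin vessels and leave the pruning to
pixel verification.

Threshold calibration was the one genuinely open design area, and two
measurements drove it:

* **Per-level domains.** CLAHE reshapes the histogram differently at
  every tile size, so a single threshold value means different things
  at different levels (a fixed quantile of one pooled histogram was
  measured to binarize anywhere from 12% to 63% of a level's own
  image). Each level's threshold is therefore the level's quantile of
  the pooled histogram of *its own* preprocessed training frames (three
  representative mean frames of the recording). Raw threshold values
  are consequently not comparable across levels; the ordered object is
  the quantile grid.
* **Histogram-aware quantile grid.** Thresholds far beyond the
  dark-content fraction binarize large swaths of background; the
  verifier then sees background blobs with vessel-like local geometry,
  and every true vessel is thickened by the included background tail.
  The dark (vessel) coverage is estimated as the fraction of pixels
  below the Otsu split of the pooled adjusted histogram (clipped to
  [0.05, 0.45]), and the 10 quantiles span 0.3–1.5× that estimate:
  the lowest levels catch only the darkest vessel cores, the highest
  include all vessels plus a bounded margin of background for the
  verifier to prune.

`build_schedule` retains the simpler fixed-grid rule (quantiles
0.10–0.55 of one pooled adjusted histogram) for callers who want a
hand-specified schedule; the pipeline uses the adaptive calibration.
Both are overridable via the `quantiles` config field.

## Pixel verification

For candidate pixel *p* (foreground, ≥2 px from borders so the 5×5
neighborhood fits): *b_p* is the nearest background pixel from an exact
Euclidean distance transform; *b_j* are the nearest background pixels
of the 24 neighbors; *b_max* is the *b_j* farthest from *b_p*.

* `d = max_j ‖b_p − b_j‖` approximates the local structure width
  (measured between the background pixels flanking it);
* `θ` is the angle at *p* in the triangle (*b_p*, *p*, *b_max*) by
  the cosine rule with opposite side `d`, cosine clamped to [−1, 1] —
  near 180° when the two background anchors lie on opposite sides of a
  thin structure, small for blobs;
* `C = GL(b_max)/GL(p)` on the CLAHE-equalized, median-smoothed image
  — the intensity ratio *across* the structure. Two deliberate choices
  here: the ratio is taken at *b_max* (the across-the-vessel reading)
  rather than as a maximum over all 24 *b_j*, because candidates are by
  construction the dark tail of the histogram and a maximum over 24
  background samples is an order statistic that passes on pure noise;
  and the gray image is the smoothed enhanced image, because
  unsmoothed CLAHE amplifies i.i.d. sensor noise several-fold (measured
  0.0097 → 0.070 background σ at 8 px tiles) and would feed that
  amplification straight into the ratio. `GL(p) = 0` maps to `C = ∞`
  (the contrast test cannot fail on a perfectly dark pixel).

Verification: `d < P_d` ∧ `θ > P_θ` ∧ `C > P_C`, defaults
P_d = 13 px, P_θ = 130°, P_C = 1.17. The EDT uses exact distances;
nearest-pixel ties break toward smaller row then column so feature
values are reproducible across implementations. Note that an isolated
dark pixel genuinely passes all three tests (it is indistinguishable
from a 1 px vessel cross-section); the morphological opening after the
level union is what removes such speckles.

## Reconstruction, combination, refinement

Verified pixels are not only centerline pixels — they fill most of the
lumen — so stamping a disk of radius round(d/2) at each verified pixel
(the simple rule, kept as the `reconstruct` default) systematically
inflates a 3–9 px capillary by ~2 px per side. The pipeline instead
stamps a disk of lumen radius (d − 2)/2 (d spans the background pixels
one step outside the lumen on either side) centered at the *continuous*
midpoint of (b_p, b_max) — the vessel axis those two anchors imply —
rasterized against the float center so half-integer midpoints do not
smear the cross-section. The measured width bias drops from ~+2 px to
\<1 px per side.

The 10 level masks are unioned; interior holes (background not
4-connected to the border) are filled; the union is opened with a
radius-1 disk. A pixel of the combined mask is vessel when segmented in
≥2 of the 20 frames (`min_votes`, configurable; 1 gives a plain
union). Post-processing: bridge (set a background pixel whose 8
neighbors form ≥2 mutually disconnected foreground groups; implemented
as a 256-entry lookup table), fill, spur removal (3 iterations of
endpoint deletion — note a spur's base pixel has ≥2 neighbors and
survives by construction), then region growing: per 35×35 window, the
vessel orientation from second-order central moments (undefined below
10 vessel pixels or for isotropic moments), endpoints stepped along
both senses of the axis, accepting pixels whose gray value (on the
adjusted temporal-mean frame) lies within mean ± 0.5 σ of the window's
vessel pixels, up to 10 steps — growth is extensive and bounded.

## Flow classification and FCD

`transitions(p) = Σ_t |M_t(p) − M_{t+1}(p)|` over the 20 per-frame
masks (19 pairs). A pixel is active when vessel in the combined mask
and `transitions ≥ t_flow` (default 2 — one appearance/disappearance
cycle of a passing cell or gap). Pixel flags are speckly on real
video, so by default each 8-connected component of the refined mask is
kept wholly iff ≥ 50% of its pixels are active (`--no-component-vote`
restores the literal pixel rule). Area FCD = 100 × active pixels /
ROI pixels, ROI = stabilization-valid rectangle minus the 2 px
verification margin. Length FCD skeletonizes the active network and
sums 1 per 4-neighbor step and √2 per diagonal step, scaled by the
pixel size, per mm² of ROI; with the default 1.538 µm/px a healthy
phantom sits near 10–15 mm/mm². (Length densities are reported in
true units; per-subject tables from older tools may carry other
scalings and are compared via the statistics module, not rescaled.)

## Synthetic phantoms

The generator emulates what validates each stage, not photorealism:

* smooth curvature-limited centerlines (random-heading walk with ~4°/px
  turn limit, steered back near borders so curve length is stable
  across frame sizes), widths uniform in 3–9 px, placed by rejection
  sampling with a 3 px separation halo so per-vessel scoring is
  unambiguous;
* stagnant vessels: a static dark column (0.55 on a 0.8 background);
* perfused vessels: dark cells (0.35, radius ≤ half-width) advected
  along the centerline at 3 px/frame (~0.18 mm/s at the default pixel
  scale, a typical capillary red-cell speed) with 30 px spacing over a
  near-background plasma tube. This is the physical contrast
  mechanism: hemoglobin is visible only where cells are, so a perfused
  vessel's appearance changes frame to frame while a stagnant column
  does not — exactly the signal temporal differencing keys on. The
  kinematics are chosen so plasma gaps survive 5-frame averaging
  (smear 6 + 4·3 = 18 px < 30 px spacing) and every tube pixel is
  traversed within 20 frames, making the full tube the ground-truth
  perfused region;
* Gaussian sensor noise (σ 0.02), per-frame integer jitter (amplitude
  or explicit list), edge-replicated; ground truth (masks, shifts,
  per-vessel records) is taken before jitter. `render_static_jittered`
  replays one frozen frame under known shifts for exact stabilization
  oracles.

Defaults target the reference regime: 480×640, 24 frames, ~12%
perfused-area fraction (realized 9–13% depending on seed), 75% of
vessels perfused; `hemorrhage_spec` halves the perfused fraction over
the *same* network, giving matched pairs for monotonicity checks.
`scaled_spec` keeps the area fraction at reduced frame sizes by scaling
the vessel count with frame area / max dimension (vessel length scales
with the frame, width does not).

What phantom results do **not** show: robustness to illumination
drift, pressure artifacts, focus changes, capillary crossings/overlap
(the generator separates vessels), non-translational motion, or
realistic tissue texture. Passing the synthetic suite demonstrates the
algorithmic contracts, not clinical accuracy.

## Validation problem sizes

Pipeline-level checks run on 192×256 phantoms with 20 analyzed frames
(≈10 s per recording), 9 baseline/half-perfusion pairs for the
separation check; the distance transform is verified exactly against a
brute-force all-pairs oracle on fifty 20×20 masks; stabilization on
12-frame static replays with ±7 px steps. These sizes keep the full
validation in a few minutes while preserving the reference conditions
(widths, noise, perfused fraction, frame count).

## Statistics

`summary` is mean and n−1 standard deviation; `paired_t` computes
t = mean(d)/(sd(d)/√n) on baseline−condition differences with two-sided
p from the t distribution (df = n−1), erroring on zero-variance
differences; `bland_altman` returns bias, bias ± 1.96·sd limits and the
per-pair (mean, difference) points. The packaged nine-subject tables
give t(8) = 6.50 (automated analyzer, area) and t(8) = 4.19
(semi-automated reference, area); these and the column summaries are
frozen in the acceptance tests. The statistics path is cross-checked
against an independent implementation (`scipy.stats.ttest_rel`) and a
numerical t-tail integration.

## Known limitations

* Binary flow assessment only: no velocities, no flow grading.
* Translation-only stabilization; heavy rotation fails (re-seeding
  masks small failures, at the cost of a shrinking valid ROI).
* The contrast test assumes vessels darker than their surroundings;
  bright-field or reflectance modalities need inverted input.
* The threshold calibration assumes the recording contains some
  vessels; a featureless video yields zero FCD by construction.
* Component voting makes flow classification all-or-nothing per
  connected component; a partially stagnant vessel fused to a perfused
  network is classified with the majority.
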