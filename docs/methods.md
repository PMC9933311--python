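# Methods

This note documents the models, conventions and numerical choices behind
`lignoquant`, and what its synthetic validation does and does not show.

## Measurement procedure

One *section* is an ordered stack of 8-bit grey frames of the same field,
acquired at strictly increasing exposure times (default 100–3000 ms in
100 ms steps) with a single spatial calibration (default 0.8 µm/px). The
multi-exposure design exists because fluorescence intensity varies strongly
with pretreatment severity: somewhere in the series every sample has frames
below sensor saturation.

Both measurement branches operate on a single **enhanced grey-level average
image**: CLAHE is applied to every frame, then the frames are averaged
pixel-wise (rounded half-up to 8 bits). Enhancing *before* averaging
matters for weakly fluorescent sections: each dim frame is stretched to the
full 8-bit range first, so the average retains sub-grey-level precision
instead of collapsing onto a handful of quantized values. The reverse order
(project, then equalize once) is available via `wall_enhance="projection"`.

- **Wall branch.** The enhanced average is thresholded with the species'
  wall criterion (`huang` for spruce, `moments` for beechwood), keeping
  pixels *strictly above* the level (dark-background polarity). The mask is
  then applied to the **raw** frames; per exposure we report the mean grey
  over the mask, the mask size, and a saturation flag (≥ 1% of wall pixels
  at 255). CLAHE therefore shapes only the mask, never the measured
  intensities.
- **Lumen branch.** The same image is thresholded with the lumen criterion
  (`li` / `minimum`), keeping pixels *at or below* the level. The binary
  mask receives one 3×3 majority vote (below), holes inside particles are
  filled, 8-connected components are labelled in raster order, particles
  below the species bound (20 px spruce, 500 px beechwood) or touching the
  frame border are dropped, and the survivors are measured.

The lumen threshold can instead run on the CLAHE frame at the reference
exposure (`lumen_source="reference_frame"`); the default uses the shared
enhanced average, which pools the whole series and is markedly less
noise-ragged. Every parameter of a run is recorded in a JSON manifest;
re-running from the same inputs reproduces outputs bit-exactly (the
analysis path contains no randomness).

## Threshold criteria

All four methods consume a 256-bin histogram and return an integer level;
ties always break toward the **lowest** qualifying level, which makes
results platform-independent.

- **Huang** (fuzzy-membership entropy): for each candidate level t, pixels
  get membership u = 1/(1 + |g − µ_class|/C) to their side's mean, with C
  the occupied grey range; the level minimizing the summed Shannon entropy
  of u is returned. All candidates are scanned.
- **Li** (minimum cross-entropy): we return the exact integer minimizer of
  the cross-entropy objective, evaluated for all 255 splits with cumulative
  sums. The classic fixed-point iteration solves the same stationarity
  condition; the exhaustive scan costs the same O(256) work and cannot land
  in a secondary minimum. Grey levels are shifted by +1 inside the
  objective so histograms with mass at level 0 (dark lumens!) are
  well-defined. Two properties of this criterion are worth knowing: it is
  exactly *flat* across empty valley bins (any level in the flat stretch is
  optimal; we return its lowest level), and it is *not* mirror-symmetric in
  grey level (the objective weights levels by g·log g), so thresholds of an
  image and its negative do not sum to 255.
- **Moments** (Tsai): the dark-class fraction p₀ that preserves the first
  three grey-level moments is computed in closed form from the quadratic
  whose roots are the two representative levels; the returned level is the
  smallest at which the cumulative histogram fraction reaches p₀.
- **Minimum** (iterated-smoothing valley): the histogram is smoothed with a
  3-bin mean filter until exactly two local maxima remain (plateau-aware
  peak counting), and the minimum between them is returned. The filter's
  edge rule keeps the out-of-range third in the edge bin
  (h₀' = (2h₀ + h₁)/3), so total mass is conserved at every iteration. A
  histogram that is — or becomes — unimodal raises an explicit error, as
  does exceeding the iteration cap (default 10 000).

Degenerate single-level histograms return that level with a `degenerate`
flag instead of raising, so batch runs survive blank fields of view.

CLAHE is delegated to scikit-image (`equalize_adapthist`). The parameters
follow the plugin conventions of the ecosystem the procedure originated in:
tile `block_size` 127 px, 256 bins, `max_slope` 3.0, mapped onto the
backend's normalized clip limit as `max_slope / bins` (both clip the tile
histogram at `max_slope` times uniform occupancy). A constant image is
returned unchanged. Because the backend normalizes to the image's own
range, the whole wall-mask construction is exactly invariant to a global
brightness scaling that stays below clipping.

## Shape measurement

Area is the particle's pixel count times the calibration squared. Interior
holes are filled before measurement: the lumen is the void bounded by the
wall, and speckle noise inside it must not punch holes. Circularity is
4πA/P², clamped at 1.0 (tiny particles can exceed 1 under any discrete
perimeter convention).

**Perimeter** uses the crack boundary — the polyline of exposed pixel edges
— which is exact for axis-aligned rectangles but overestimates smooth
contours (by up to 4/π). We subtract a fixed penalty c per 90° direction
change of the crack polyline:

    P = L_crack − c · n_corners,
    c = (1 − (π/4 − √2/2)/(1 − √2/2)) / 2 ≈ 0.36635,

the unique value for which the estimator is unbiased for smooth boundaries
under a uniform orientation distribution (average the corrected length of a
staircase of slope tan θ over θ ∈ [0, π/4]). Corners are counted from 2×2
pixel configurations: one per lone-foreground/lone-background quarter, two
per checkerboard. Accuracy on reference shapes: 20×20 px square → 78.53
(−1.8%), digitized disk r = 50 → +0.14%, digitized ellipses ≥ 25 px
diameter → within ~1.6%. Worst case: small axis-aligned ellipses whose flat
top/bottom runs violate the isotropic-orientation assumption (~4% at minor
diameter 24 px); generic orientations behave.

**Majority smoothing.** Sensor noise at the segmentation boundary inflates
any discrete perimeter estimate (zero-mean boundary jitter lengthens the
crack polyline without changing area). One 3×3 majority vote on the lumen
mask removes this raggedness with sub-0.2 px systematic bias for particles
of ≥ 20 px diameter; on dim, severely pretreated sections it is the
difference between a ~6% and a ~1% perimeter error. It is a profile flag
(`smooth_mask`, default on, recorded in the manifest).

## Synthetic sections

The generator emulates the features of the real imaging problem that the
measurement procedure must survive:

- **Geometry.** Spruce: a rectangular lattice of rounded-rectangle tracheid
  lumens with jitter, lognormal size variation, small aspect/rotation
  jitter. Beechwood: vessels on a jittered hexagonal lattice (alternating
  row offsets; placements are non-overlapping by construction) plus small
  fibre lumens dart-thrown between them — deliberately below the 500 px
  vessel bound so the size filter is exercised. Every lumen is a polygon,
  deformed by low-frequency radial harmonics r(θ) ← r(θ)·(1 + Σ aₖ cos(kθ+φₖ)).
- **Severity** s ∈ [0, 1] applies, per cell, a radial shrink
  (1 − 0.30·s·(0.8 + 0.4·u)) and extra deformation harmonics (amplitude
  0.22·s), and reduces the wall gain by the factor (1 − 0.6·s). Severity is
  applied *after* each lumen is fitted to its lattice cell, so at fixed
  seed every cell's true area and circularity are strictly decreasing in
  s — the basis of the end-to-end ordering test.
- **Radiometry.** Wall intensity at exposure e is min(255, g·e) (g =
  `wall_gain`, grey/ms), lumens sit at a small floor (2 grey), edges are
  blurred with a σ = 0.7 px Gaussian (a stand-in for the optics' PSF), the
  frame is multiplied by a smooth illumination field 1 ± 0.2 (period ≳ the
  image, ≫ the CLAHE tile, so enhancement can plausibly remove it), and
  Gaussian noise (σ = 3 grey, an 8-bit camera at moderate gain) is added
  before rounding and clipping.
- **Ground truth** is defined on the pre-noise, pre-illumination geometry:
  per-lumen area from 8× supersampled rasterization (8× and 16× agree
  within 0.5%), perimeter as polygon arc length, and the wall intensity
  curve as the mean of the clean render over the wall mask eroded by 2 px
  (i.e. the intrinsic plateau, clear of partial-coverage edge pixels).
  Pipeline error is therefore attributable and bounded.

**Calibration.** `calibrate_to_target` matches the ground-truth *means* of
a species layout to target (area, circularity, wall grey at 2000 ms):
circularity by bisecting a single species shape knob (aspect plus
deformation-harmonic amplitude; monotone by construction), area by exact
uniform rescaling (circularity is scale-invariant), wall grey analytically
(g = target/2000). Means are matched within 2% for ≥ 300 cells; infeasible
targets (e.g. circularity 0.05) raise an explicit error. Only means are
targeted: the per-cell dispersions of the real data are not reproduced —
packing ~200 vessels of the published mean size into a 1024² frame caps
the feasible size spread (area CV ≈ 0.25–0.3), so the recovery benchmarks
validate mean recovery, not distribution recovery.

**Fixture sizes.** The benchmark fixtures use 1200 tracheids at 1280² px
(the published mean tracheid lumen of 647 px cannot pack 1200-fold into
1024² once walls are accounted for) and 200–230 vessels at 1024² px. Each
fixture generates and analyses in well under a minute on one CPU.

## Known limitations

- **Thin-wall partial-volume bias.** The detected wall mask includes
  boundary pixels of intermediate coverage; for spruce, whose walls are only
  ~4–6 px wide at this calibration, this biases measured wall grey ~5–8%
  below the intrinsic plateau. Beechwood's thick wall web keeps the bias
  within ~2%, which is why the fluorescence benchmark is a beechwood
  condition. A wall-mask erosion option would trade this bias for noise.
- The lumen masks of adjacent cells can merge if walls locally vanish
  (severe deformation + thin walls); no watershed splitting is attempted.
- The generator has no true optics (depth of field, PSF tails), no
  photobleaching, no spectral dimension, and its deformations are smooth
  radial harmonics — real collapsed cells can fold and self-contact.
  Passing the recovery benchmarks shows the *measurement chain* is unbiased
  under the stated imaging model, not that the model captures every
  property of real macrographs.
- Wall fluorescence is spatially uniform per section; real walls show
  compound-middle-lamella vs secondary-wall contrast at higher
  magnification.
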