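# Methods

## Problem and model

Fundus photographs have no intrinsic scale: the microns imaged per pixel
depend on camera optics, field of view, refraction and — for scanned
film — scanning resolution. Vessel-analysis practice recovers an
approximate scale from the optic disc (OD), assuming an average adult
disc diameter of 1800 μm. The resulting **image conversion factor**
(ICF, μm/px) exists in two flavours with different failure modes:

* **constant ICF** = 1800 / mean cohort OD diameter (px) — one factor for
  every image of a cohort;
* **individual ICF** = 1800 / this eye's OD diameter (px) — recomputed per
  image.

The ICF does double duty. It converts pixel calibers to μm
(`CRAE_μm = ICF × CRAE_px`) and it fixes the pixel radii of the
measurement annuli: zone B spans 0.5–1.0 and zone C 0.5–2.0 OD diameters
from the disc margin, i.e. radii of 1.0–1.5 and 1.0–2.5 reference
diameters (1800–2700 μm and 1800–4500 μm) from the disc center, divided
by the ICF. With an individual ICF the inner zone radius therefore
equals the eye's own disc diameter in pixels; with a constant ICF every
image gets the same pixel annuli regardless of its disc. The prose
description of the zone boundaries is ambiguous in parts of the
literature; this package follows the margin-referenced reading above,
which matches standard SIVA-style grids.

Twelve retinal vessel geometric characteristics (RVGC) summarise an
image: CRAE/CRVE/AVR (Knudtson "big six" central equivalents of the six
widest arterioles/venules plus their ratio) in zone B, the same over
zone C (CRAEoC/CRVEoC/AVRoC), box-counting fractal dimension of the
zone C skeleton (Df, and Dfa/Dfv per vessel type), and mean simple
tortuosity (arc length / chord) of zone C segments (STt/STa/STv).

The Knudtson equivalent iteratively pairs the sorted widths largest-
with-smallest as `ŵ = c·sqrt(w_max² + w_min²)` (c = 0.88 arteries, 0.95
veins), carrying any middle value, until one value remains. It is
permutation-invariant and homogeneous of degree one, so the ICF factors
straight through to the μm result — which is exactly why AVR, tortuosity
and fractal dimension are ICF-independent while the μm equivalents are
not.

## Measurement pipeline

Input is a labeled raster (0 background, 1 artery, 2 vein, 3 disc) with
a JSON sidecar giving the disc center and axis diameters as rendered;
the disc is the only scale reference used. Steps:

1. Vessels are connected label components per type (8-connectivity),
   analysed within the zone C bounding box.
2. Centerlines by topological thinning (scikit-image `skeletonize`).
3. Caliber at each centerline pixel = 2 × Euclidean distance to the
   nearest background pixel. For speed this distance is evaluated only
   at skeleton pixels with a KD-tree over the mask's background
   boundary, which is exactly the distance-transform value there. A
   vessel's width per zone is the mean over its centerline pixels inside
   the annulus. On rendered test bands of known width this estimator is
   accurate to about half a pixel.
4. Tortuosity: centerline pixels are ordered by radial distance from the
   disc center (vessels radiate outward; strongly re-entrant paths are
   outside the model), smoothed with an 11-point moving average, and
   resampled every 10 px before the arc/chord ratio is taken. The
   smoothing removes the ±0.5 px lattice jitter of thinning, whose
   zig-zag would otherwise inflate arc length by ~10⁻²; residual error
   on straight vessels is below 10⁻³, while vessel-scale undulations
   (wavelengths of hundreds of px) are attenuated by well under 1%.
5. Fractal dimension: occupied-box counts of the zone C skeleton on a
   dyadic ladder of box sizes (2 px up to a quarter of the zone C
   bounding box, at least five sizes), least-squares slope of log N
   versus log(1/size). On calibration rasters this yields 1.00 (line),
   2.00 (filled square) and 1.585 (Sierpinski triangle) within 0.05.
6. Big-six selection takes the six largest widths per type and zone,
   ties broken by vessel id. If fewer than six vessels exist, the list
   is padded by repeating the smallest measured width and a shortfall
   flag is raised (the manual-marking remedy used on real images has no
   batch analogue). Skeleton branches shorter than 10 px are ignored as
   noise.
7. Left eyes (sidecar `laterality: "OS"`) are flipped to a canonical
   right-eye orientation, together with the zone centers, before
   measurement. Topological thinning is not reflection-equivariant, so
   without this step mirrored copies of the same eye would differ at the
   0.01 px level for purely algorithmic reasons.

Zone B clipped by the frame is a hard error; zone C clipping is reported
as an annulus-area fraction and used by the pipelines as an exclusion
rule (default threshold 2%).

## Synthetic cohort

The generator emulates 60° fundus photography of a screening cohort and
provides exact ground truth:

* disc diameter ~ N(1800, 135) μm (CV 7.5%), truncated at ±3 SD, with up
  to 3% ellipticity split between the axes; at the native scale of
  2.4 μm/px this reproduces a cohort individual-ICF spread of about
  2.4 ± 0.18, and the constant factor of such cohorts is ≈2.4;
* 7 arterioles and 7 venules alternating in disjoint angular sectors;
  root calibers ~ N(92, 10) μm (arteries) and N(100, 12) μm (veins),
  floored at 55 μm, giving AVR ≈ 0.75–0.8 and cohort mean equivalents of
  roughly 160 μm (CRAE) and 210–220 μm (CRVE);
* centerlines are radial rays with a sinusoidal perpendicular offset:
  wavelength U(250, 450) px, amplitude 5–10% of the wavelength (capped
  so sectors never overlap), giving mean simple tortuosity around
  1.05–1.08; amplitude 0 gives exactly straight vessels;
* vessels run from 0.45 to 2.75 OD diameters (at least 2.75 reference
  diameters) from the disc center, covering zone C for both calibration
  flavours; width is constant along the vessel unless a linear taper
  (`taper_per_od`) is enabled;
* rendering is purely geometric (binary labels, no photometric model),
  with the macula placed 2.5 OD diameters temporal to the disc on the
  horizontal meridian; the default frame is the minimal one containing
  zone C, clamped to the field of view (the disc is taken to subtend
  5.5°, so a 60° frame is ~11 OD diameters wide); resolution changes are
  nearest-neighbour resampling of the native render, mimicking a rescan
  at a different pitch.

What the generator does **not** model: vessel branching and crossings
(components map 1:1 to vessels, so the synthetic fractal dimension sits
near 1 rather than the ~1.25 of real branching trees), caliber pulsation
and the central light reflex, photometric noise, film grain or scanner
artifacts, and ocular magnification differences. Passing tests therefore
validate the calibration algebra, geometry and statistics — not
segmentation robustness on photographic material.

The fellow-eye ("laterality") null is modeled as the same generative eye
with independent Gaussian caliber noise (default SD 2 μm), rendered and
mirrored. With the noise at zero the pair is measurement-identical by
construction and paired p-values equal 1 by the all-zero convention.

## Statistics

Bland-Altman agreement uses d = x − y per image, the sample (n−1) SD,
limits of agreement md ± 1.96 SD, a one-sample t test of d against zero
(systematic bias), and OLS of d on the pairwise mean (x+y)/2 with a
slope test (proportional bias). Location comparisons branch between the
paired t test and the Wilcoxon signed-rank test on a Shapiro–Wilk
normality check of the differences at α = 0.05 (the branch rule is
configurable; the diagnostic used in the original SPSS analyses is not
recorded anywhere, so Shapiro–Wilk is this package's choice). The
multiple-comparison threshold over the twelve RVGC is plain Bonferroni,
0.05/12 ≈ 0.0042. Correlation tables are pairwise-complete Pearson.
All-zero differences and zero-variance denominators are reported as
degenerate rather than raised.

## Design choices and problem sizes

* Width estimator 2×EDT at skeleton pixels: the half-pixel conventions
  of polygon rasterization and thinning roughly cancel, placing rendered
  60 px bands within ±1 px.
* STt is the unweighted mean over all zone C segments of both types;
  zone B equivalents use widths sampled inside zone B only (the
  alternative B∪C sampling can be obtained by passing the zone C
  annulus).
* The default simulation sizes in the test suite and acceptance script
  (cohorts of 10–30 eyes, scale factors 1.0/1.5) keep a full run in the
  minutes range on one core while leaving the Monte-Carlo means well
  inside their tolerance bands; per-eye rasters are ~4000² px at native
  scale, matching disc diameters of ~750 px.
* The iICF-vs-cICF mean-difference direction (individually calibrated
  calibers averaging above constant-factor ones) is driven by Jensen's
  inequality, E[1/OD] > 1/E[OD], and is about CV² ≈ 0.6% of the caliber
  (~1.3 μm) at the default 7.5% disc-size spread — an order of magnitude
  smaller than the per-eye spread of the difference, so it is asserted
  on a large simulated disc cohort at the calibration layer rather than
  through rendered images.

## Known limitations

* Centerline ordering by radial distance assumes vessels do not curve
  back toward the disc inside the measurement annuli.
* The box-counting slope on sparse radial skeletons is a finite-size
  estimate; absolute synthetic Df values are not comparable to
  photographic cohorts, only differences between views/calibrations of
  the same eye are.
* User-supplied maps must already be segmented and artery/vein-labeled;
  no photograph processing is included.
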