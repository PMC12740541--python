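# Methods

## Phantom model

The simulator emulates a hollow artificial coronary artery in a water bath:
a straight cylinder of lumen radius 2.5 mm along +z carrying five concentric
annular calcifications (inner diameter 5 mm, outer diameter 11 mm, length
5 mm, analytic volume 377 mm³ each) of calcium hydroxyapatite (CaHA) at 75,
100, 200, 400 and 800 mg/cc. Default ring centers are 13 mm apart on an
80 mm artery, leaving a >= 10 mm calcium-free lumen stretch that is scored
as a control region. The lumen is blood-equivalent (40 HU) and can carry 0,
50, 100 or 150% of a clinical iodine contrast dose. The surrounding thorax,
extension ring and lungs are not rasterized: they influence dose and noise,
which the noise model absorbs, but not scoring geometry, so the background
is homogeneous water at 0 HU.

### Material calibration

Conventional HU are piecewise-linear through the insert's calibration
points, anchored at water = 0:

- CaHA: (75, 96), (100, 129), (200, 259), (400, 521), (800, 1044) HU.
  Monoenergetic 70 keV HU are used interchangeably with 120 kVp
  conventional HU, the standard surrogate for calcium scoring.
- Lumen mixture: (0%, 40), (50%, 185), (100%, 390), (150%, 590) HU.

Each material also has a (photoelectric, Compton) base-image direction per
conventional HU: CaHA (2.0, 25.0), iodine (3.38, 2.0), blood (0.0, 1.5),
water (0, 0). The vendor's base-image scaling is proprietary, so these are
*calibrated, not physical*: they are chosen once so that the shipped
boundary (slope 3.69, intercept -3361) classifies pure CaHA down to ~37 HU
as calcium while the lumen stays non-calcium at every contrast dose (margin
~960 base units even at 150%). Only separability matters to the algorithm;
absolute base-image units carry no meaning. One behavioural consequence
worth knowing: at 100% contrast, inner-edge voxels mixing ring calcium with
lumen iodine classify as calcium for calcium fractions above ~0.25 while
their conventional HU can reach ~300; this is the mechanism by which the
96/129 HU rings (below the 130 HU threshold in pure form) become detectable
on contrast-enhanced scans, mirroring scanner behaviour.

### Rasterization, jitter, noise, slices

Volumes are rasterized analytically on the reconstruction grid (default
220 mm field of view / 512 matrix = 0.4297 mm pixels; native z sampling
0.335 mm) with sub-voxel supersampling (default 3x3x3 offsets averaged), so
edge voxels carry exact partial-volume mixtures. Per repetition, a seeded
rigid jitter emulates manual repositioning: rotation uniform in +-2 degrees
about a random transverse axis and translation uniform in +-2 mm per
component (both configurable; magnitudes are stated as approximate, so a
uniform draw within the stated bound is used). Independent zero-mean
Gaussian noise is added per channel on the native grid, with
sigma = sigma_ref * sqrt(202 mAs / mAs) * sqrt(3.0 mm / thickness)
(defaults 20 / 40 / 60 HU-like units for conventional / PE / Compton at the
202 mAs, 3.0 mm reference). Slices are then resampled into overlapping
slabs: each output slice is the mean of native slices whose centers fall in
a window of the slice thickness, stepped by the increment (3.0/1.5 mm
thick, 0.67/0.335 mm thin; only increment <= thickness is supported).
Because averaging follows the noise, the effective noise of a 3 mm slab is
lower than the native sigma by roughly the square root of the slab's sample
count; sigmas are configurable where a specific reconstructed-slice noise
is wanted.

## Classification and the VNC baseline

The calcium mask is the raw voxel-wise inequality pe <= compton * slope +
intercept (boundary inclusive), with no smoothing, applied independently to
each reconstruction; the masked conventional image feeds the standard
scoring. The 130 HU threshold belongs to scoring, not classification.

The comparison baseline emulates calcium-agnostic VNC: the iodine-attributed
HU of each voxel is estimated from a water/iodine two-base decomposition of
the base images, with water as a pure-Compton direction (equivalently,
iodine HU = pe / 3.38), and subtracted, scaled by `suppression_fraction`
(default 1.0). Iodine-filled lumen returns exactly to the blood baseline,
while calcium loses the fraction 2.0/3.38 = 0.59 of its signal: 259 HU
(200 mg/cc) drops to ~106 HU and disappears below the scoring threshold,
521 HU keeps ~213 HU and survives — the documented failure mode of such
reconstructions. A full 2x2 decomposition using the *blood* direction as the
water basis would assign calcium a negative iodine component under this
calibration (calcium is Compton-heavy here) and enhance it instead; the
pure-Compton water basis is therefore part of the baseline's definition.

## Scoring conventions

- 2D lesions: per-slice 8-connected components of voxels >= 130 HU with
  area >= 0.5 mm² (non-strict); grouped into 3D lesions by 26-connectivity.
- Weight from the 2D component's maximum HU (the original per-slice
  definition), bins 130/200/300/400 inclusive at the lower edge.
- 3 mm-equivalent score: the per-slice-summed raw score times
  (increment / 3.0). Overlapping reconstructions visit each 3 mm of anatomy
  3/increment times; this removes the multiple counting and is the identity
  at 3.0/3.0.
- Volume score: accepted-lesion voxel count times (pixel area x increment),
  so overlapping slabs are not double counted. Sub-area specks are excluded.
- Reports round to one decimal; comparisons against integer theoretical
  values round to the nearest integer.
- With a phantom manifest, 3D lesions are assigned to the nearest listed
  region by z centroid within 6.5 mm (half the default ring spacing).

The analytic ideal path (`ideal_agatston_score`) scores a uniform lesion as
area x weight x ceil(length / 3 mm) with no partial volume; for the ring
insert it gives 0, 0, 302, 603, 603 points. Voxelized slab-averaged scores
are systematically lower for mid densities (the partial slabs of a 5 mm
lesion under a 3 mm window drop weight bins): the noiseless 3.0/1.5 mm
phantom scores ~0/0/222/528/701, which is what the tests validate against a
closed-form slab-coverage oracle (edge effects modeled by an
orientation-averaged linear pixel-edge profile; agreement within 5%).
Likewise the volume score of the 400 mg/cc ring on thin slices
overestimates 377 mm³ by ~17%: at 521 HU the threshold keeps voxels down to
~25% calcium fraction, dilating the ring by ~0.25 pixel per edge — the
familiar overestimation of high-density calcifications.

## Boundary optimization

`fit_boundary` wraps scipy's differential evolution over slope in [0, 10]
and intercept in [-10000, 0] (bounds bracket the shipped optimum), with 30
population members, dithered mutation 0.5-1.0, recombination 0.7, and a
seeded generator. The objective is the sum over scans and calcifications of
|Agatston(masked image) - reference|. Termination: 1000 generations, or
relative best-objective improvement below 0.1% over a sliding 20-generation
window (the improvement rule is underspecified at single-generation
granularity; the window avoids premature stops on flat steps). The
per-generation best-objective trace is returned and is non-increasing.
Recovery is assessed in classification space, not parameter space: the
objective is piecewise constant with a broad zero plateau, so many (slope,
intercept) pairs induce identical masks on the scored voxels.

## Statistics

`mean_ci` returns mean +- crit * sd / sqrt(n) with the normal critical
value (1.96 at 95%) by default; Student-t is available and recorded in the
result, as the choice is material at n = 5. Significance between two cells
is the non-overlapping-CI rule with touching endpoints counted as
overlapping (conservative). Volume accuracy is 100 * (VS - 377) / 377 per
ring; calcium-free regions report absolute volume.

## What the synthetic data does and does not show

The generator reproduces geometry-driven effects: partial volume in-plane
and through-plane, slab phase sensitivity, threshold dilation/erosion,
contrast-dependent classification margins, repositioning variability, and
first-order noise/dose scaling. It does not model projection physics, beam
hardening, calcium blooming, detector spectral response, iterative
reconstruction texture, or the vendor's actual base-image scaling. Passing
tests therefore demonstrate correctness of the algorithms and their
interaction with sampling geometry — not quantitative agreement with any
scanner. In particular, scanner-measured scores of low-density rings are
noise-assisted (noise lifts some voxels over threshold and weight edges),
so noiseless synthetic scores for the 75/100 mg/cc rings are lower than
measured ones, while the relative ordering of methods (calcium-preserving
vs iodine-suppressing vs non-contrast reference) is reproduced.

## Problem sizes used in tests and examples

Tests and examples run at the clinical pixel pitch but with the water bath
cropped (27.5 mm field of view, 64 matrix — exactly 220/512 mm pixels) and
3-31 mm of z margin; the background is homogeneous water, so cropping
changes nothing but run time. The boundary-recovery experiment uses a
32 matrix and the three rings >= 200 mg/cc, for which any zero-objective
boundary must reproduce essentially all pure-material classifications.
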