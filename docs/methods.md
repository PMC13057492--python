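# Methods

This note documents the models, conventions and numerical choices behind
`bvbquant`, and what validation on synthetic data does and does not show.

## Coordinate and image conventions

Volumes are scalar HU grids indexed `(z, y, x)` with per-axis spacing in mm
(default 0.62 mm isotropic, a typical thin-slice chest reconstruction) and
an axis-aligned affine `world = origin + index·spacing`; world points are
`(x, y, z)` mm. No rotation matrix is carried: phantoms are generated
axis-aligned and oblique geometry is expressed through sampling planes, so
every geometric test has an analytic expectation. All interpolation is
trilinear (exact for affine HU fields — that identity is the resampling
oracle used in tests). Samples outside the grid default to −1024 HU (air),
a conservative choice for wall and cuff detection. The display lung window
defaults to center −600 / width 1500 HU and is a presentation convention
only; no measurement depends on it.

## Reformation

Hand-drawn centerlines are interpolated with a cubic spline, re-parameterised
by arc length on a densely sampled polyline and resampled at uniform steps;
the reported `arc_length` is the position along the continuous curve, and the
maximum deviation from the raw polyline is attached to the result. CPR
builds one cross-section per arc step (default: the in-plane voxel size)
perpendicular to the central-difference tangent, with in-plane frames by the
double-reflection rotation-minimizing construction — this avoids
torsion-induced twisting of the section stack on curved paths (frame rotation
< 10° per 0.5 mm step on smooth paths is a tested property). Default
section extent is 20 mm (13 mm in the measurement pipeline), covering a
~4 mm segmental lumen plus wall, the 2 mm fractal annulus and a ≥2 mm cuff.
CPR refuses paths closer than half the section width to the volume boundary.

## Airway wall morphometry (WT/D)

Rays (default 72) are cast outward from the lumen centroid (the air-density
connected component at the seed). Edges are localised by the
full-width-half-maximum convention with subpixel linear interpolation: the
inner wall edge is the crossing of the half-way level between the lumen
plateau and the wall plateau, the outer edge the crossing between the wall
plateau and the parenchyma level behind it. The wall plateau is estimated
globally as the 95th percentile of per-ray peaks rather than per ray: a
~1 mm wall never reaches its plateau on every ray at 0.62 mm voxels, and
half-maximum thresholds derived from the attenuated per-ray peak shift both
edges outward (on the noise-free stage-design phantom this bias moves WT/D
from 0.26 to 0.30; the global-plateau variant recovers 0.262). D is twice
the mean inner-edge radius, WT the mean outer-minus-inner distance;
measurement fails when more than 25% of rays find no closed wall. D from the
mean radius (not the minimum chord) is a documented convention. The
narrowest-section search minimises D over a CPR stack, ties to the smallest
arc position.

## Bifurcation angle and AVI

Branch directions are the dominant eigenvector of the centerline points
within 10 mm of the bifurcation vertex, oriented away from it; the 3D angle
is the arccos of the clamped dot product. AVI is the absolute deviation from
a 110° healthy reference (the population ±15° is between-subject spread, not
part of the statistic). Absolute — not signed — deviation is used, so
101.73° and 118.27° both give AVI 8.27.

## Peribronchial fractal dimension

The ROI is the annulus from the outer wall edge outward by 2 mm; the
foreground is its supra-threshold (>30 HU) pixels — the same soft-tissue
cut the cuffing rule uses, exposed as a parameter. Box counting uses a
geometric ladder of box sizes preferring exact divisors of the grid size
(falling back to a dyadic ladder on irregular sizes) and takes, at each
scale, the minimum count over four grid offsets — the covering-number
estimator. Partial border boxes otherwise inflate counts at coarse scales
and flatten the slope: with naive dyadic ceil-padded counting a filled
81×81 square measures 1.88 and a depth-4 Sierpinski carpet 1.72; with
divisor-aligned scales both are exact (2.000 and 1.8928). FD is minus the
slope of the least-squares log-count vs log-size fit over ≥4 scales, with
the fit R² reported.

## Cuffing sign

Per section, 360 one-degree rays sweep outward from the outer wall edge; a
ray qualifies when the contiguous run of >30 HU samples starting at the edge
extends ≥2 mm, and a section qualifies when more than 50% of rays do. The
sign is positive when strictly more than 3 consecutive sections qualify
(">3 slices" read literally as a run of ≥4). All inequalities are strict as
printed. Because a cuff is soft tissue contiguous with the wall, a
single-section FWHM measurement cannot separate the two; the pipeline
therefore sweeps from the stack-median wall, which a cuff confined to a few
sections does not move. The detector is monotone in each criterion:
tightening the HU cut, coverage, thickness or run length can only turn
positives negative (a tested property).

## Staging

Continuous features are z-scored with the sample-SD (n−1) convention
(population-SD is available via `ddof=0`). Selection follows the
minimum-cross-validated-binomial-deviance rule on an L1-penalised logistic
path (40 log-spaced penalties from the data-derived maximum, 10 stratified
folds); the surviving features are refit by unpenalised maximum likelihood
on the raw scale, which is the form with interpretable coefficients,
standard errors and p-values. Known behaviour of the minimum-deviance rule:
it retains essentially every real signal but also over-selects pure-noise
features (~40–50% per feature in our n=400, log-OR-2 simulations); this is
a property of the selection rule itself, not of the implementation, and the
tests encode it as such.

The published combined score is on the raw feature scale. The mapping from
the continuous score to ordinal stages is not part of the published model;
`call_stage` applies two ordered cut-points, either user-supplied or fitted
by exhaustive scan of score midpoints maximising staging accuracy
(deterministic, ties to the lowest cuts).

## Evaluation statistics

AUC uses the Mann–Whitney formulation with ties counted ½ (exact against an
exhaustive pairwise oracle for small n), the 95% CI the DeLong
placement-value variance, and the operating point the Youden-maximising
observed score (ties to the lower cutoff). ICC is ICC(2,1) — two-way
random effects, absolute agreement, single measures — computed through
pingouin, with the F-method CI. Weighted kappa supports identity, linear
and quadratic weights with the standard large-sample SE; the linear weight
is the default for ordinal stages. Concordance tables report rows-true
confusion counts and per-class diagonal percentages to two decimals.

## Synthetic data: what it emulates and what it does not

Airway and bifurcation phantoms are rasterised with 3× (2× for
bifurcations) subvoxel supersampling so edge voxels carry true
partial-volume fractions — without this, subpixel FWHM localisation would
be meaningless. The HU palette (lumen −1000, wall +40, parenchyma −850,
vessel +60, cuff +50) is physically plausible and consistent with the
30 HU soft-tissue bound; Gaussian noise (default SD 12.4 HU, a realistic
thin-slice level) is i.i.d. and seeded. Partial cuffs are angular sectors,
so ground-truth coverage is exact.

Fractal textures: the filled square and Sierpinski carpet have analytic
dimensions; the `fbm` pattern is the median-level contour of a spectral-
synthesis fractional Brownian surface. The asymptotic level-set law
FD = 2 − H under-shoots by 0.07–0.14 at a 256-px grid, so the generator
inverts a measured calibration table (Hurst 0.1–0.8, 30 fields per knot,
anchored at the default 256 px size) — the generator's contract is the
expected *measured* dimension, and recovery tests confirm ±0.01 at the
three stage design points.

Cohorts draw WT/D, AVI and FD independently within stage from the stage-wise
normal distributions, the cuffing sign from per-stage Bernoulli rates, and
auxiliary clinical variables (vascular calcification score, lung volume,
pulmonary artery diameter) through a Gaussian copula hitting their target
correlations with the anchor feature. Within-stage independence of the
three morphometrics is an assumption — no within-stage covariance is
available to calibrate against — and it makes the synthetic cohorts *more*
separable than real patients: transitional stage-II heterogeneity,
measurement artifacts and reader variability are not modelled. Passing the
simulation targets therefore demonstrates correctness of the scoring and
evaluation machinery under the stated distributions, not real-world
diagnostic accuracy; replicate-cohort AUCs (~0.99) sit above real-cohort
performance for exactly this reason, and per-stage concordance of fitted
cuts on synthetic cohorts (~94–100%) exceeds what transitional stage-II
cases allow clinically.

## Problem sizes and determinism

Default phantoms are ~25–60 voxels per axis at 0.62 mm spacing — large
enough for every measurement window, small enough that the full validation
suite (including 60 noise-seeded wall recoveries, 60 fbm textures and 200
replicate cohorts) runs in about a minute. Every stochastic component
(phantom noise, cohort draws, simulated readers) takes an explicit integer
seed and is bit-reproducible; deterministic pipeline stages are
byte-reproducible, which the manifest's output checksums make checkable.

## Known limitations

* No airway segmentation or automatic centerline extraction: centerlines
  are inputs (files or phantom ground truth).
* Axis-aligned affines only; no DICOM series handling, gantry tilt or
  scanner PSF modelling.
* FWHM morphometry assumes a closed, roughly convex wall ring; plates,
  open walls or touching vessels fail rays and, past 25%, the measurement.
* The fbm-texture calibration is anchored at 256 px; other sizes are
  approximate.
* Stage cut-points are a fitted convention, not part of the published
  model; ordinal/multinomial alternatives are out of scope.
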