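# Methods

## Representations

Each eye is described by three expert-reviewed boundary surfaces on the
lateral (A-scan × B-scan) grid: ILM, RPE border, BM, with axial depth in
voxels increasing downward and the invariant ILM ≤ RPE ≤ BM everywhere.
Depths are floats: subtraction is exact on integer voxel indices and
remains well defined for sub-voxel boundaries.  The axis convention is
(x = A-scan, z = axial, y = B-scan) throughout; a full-rate acquisition
is 1000 × 512 × 100 voxels over a 6.7 mm × 6.7 mm field, so the lateral
pixel is strongly anisotropic (≈ 6.7 µm × 67 µm).

Thickness maps are computed by direct subtraction — NSR = RPE − ILM,
RPEDC = BM − RPE, and TR as their sum so that TR = NSR + RPEDC holds
bit-exactly (equal to BM − ILM up to one rounding).  Maps stay on the
native anisotropic grid; no resampling to a square raster is performed,
because interpolation would inject synthetic data into the texture the
descriptors measure.  Thickness stays in voxel units; a micrometre
conversion is display-only.

The en-face projection samples mean reflectance over the axial window
[round(b_rpe) − d, round(b_rpe) + d] per lateral position.  Boundary
depths are rounded half-to-even (the projection indexes voxels; it does
not interpolate).  Windows clipped by the volume edge shrink to the
in-range voxels so the map stays dense; a strict flag masks clipped
pixels instead.  `d` has no default: it is a required choice whenever
ENFACE arrangements are requested.

### Region of interest

The analysis region is a disc of physical radius r (mm) around the
manually marked fovea, which becomes an ellipse in pixel indices under
anisotropic spacing.  The radius is a required, explicit parameter: for
the standard 6.7 mm field the half-width is 3.35 mm, so this package's
own examples and the acceptance script use r = 3.0 mm, which keeps the
disc fully inside the field while covering ~63% of the scanned area.
Masking only shrinks the validity mask; values are untouched, and the
operation is idempotent.

## Directional variography

For a masked 2-D map, unordered pixel pairs are selected per
(direction θ, lag h) cell by three tests on the separation vector v:

* distance: max(1, h − Δh) ≤ |v| ≤ h + Δh (closed interval, Euclidean;
  the lower clamp excludes the zero-offset self pair);
* angle: the acute angle between v and the direction axis, modulo 180°,
  is at most the angular tolerance, read as a **half-angle** (the
  geostatistics convention; with 45° direction spacing and the default
  10° tolerance the sectors do not overlap);
* bandwidth: the perpendicular distance of v from the direction axis is
  at most 3 px.

Defaults: lags 1..15, Δh = 3, directions 0/45/90/135°, tolerance 10°,
bandwidth 3 px.  With unit lag spacing and Δh = 3 the distance annuli of
adjacent lags overlap, so neighboring-lag features are correlated — this
is part of the estimator's definition and is kept as stated.  Distances
and angles are evaluated in pixel units on the native anisotropic grid
by default; a PHYSICAL mode evaluates them on (dx·sx, dy·sy) in mm for
users who want geometry-true sectors.

The semivariogram accumulates squared differences, the semimadogram
absolute differences, each divided by 2N.  Pairs are generated once per
cell from a precomputed set of canonical half-plane integer offsets and
accumulated by shifted-grid differences under the joint mask —
mathematically identical to pair enumeration, and verified exactly
(values and counts) against an independent O(P²) per-pair oracle
(`brute_force_curve`) in the test suite.  Numerical details: geometric
comparisons carry a 1e-9 slack so offsets landing exactly on a closed
bound are admitted regardless of floating-point noise; a (direction,
lag) cell with no admissible pairs contributes feature value 0 and is
flagged with a warning (strict mode raises instead), so fixed-length
feature vectors survive aggressive ROIs.

Feature vectors concatenate curve values direction-major (0°, 45°, 90°,
135°), lag-ascending within direction: 60 features by default.
Concatenation rather than direction pooling preserves anisotropy
information.  No per-vector normalization is applied at extraction time;
standardization belongs to the classifier fold (see below) to avoid
test-set leakage.

## Classification protocol

Eight arrangements pair the four representations (TR, NSR, RPEDC,
ENFACE) with the two functions.  For one arrangement's feature table the
protocol is: for each repetition, draw a fresh stratified k-fold split
(k = 5 ⇒ 80/20 train/test); per fold, fit a z-score standardizer on the
training split only, train an SVM, and score the held-out split with the
decision function.  Each repetition's out-of-fold predictions are pooled
into one confusion matrix, one AUROC (rank-based, ties ½) and one κ;
aggregates over repetitions are mean, sample standard deviation
(ddof = 1), and the maximum-accuracy and maximum-κ repetitions.

Choices made where the protocol was open: RBF kernel with C = 1 and
gamma = "scale" (exposed in configuration and recorded in the report for
provenance); stratified folds because AMD cohorts are typically
unbalanced and plain folds can drop a class from a training split;
per-repetition pooling of fold predictions rather than averaging
per-fold metrics, because fold-level AUROC on ~20 cases is noisy and
pooling keeps every metric well defined.  Metrics signal
`UndefinedMetricError` on degenerate confusion tables (e.g. no positive
cases) instead of silently returning 0.  A fixed master seed derives all
per-repetition split seeds, making reports bit-identical across runs.

## Synthetic cohorts

The generator emulates what the method assumes about retinal morphology,
not optics:

* ILM = base plane (30 voxels) + Gaussian foveal pit (depth 15 voxels,
  σ = 0.35 mm) + smooth noise; the NSR thickness field subtracts the pit
  again, so the retina thins toward the fovea while the RPE stays flat —
  the anatomically correct configuration.
* Thickness fields: NSR 40 ± 1.5 voxels, RPEDC 8 ± 1 voxels.  Smooth
  variation is white noise blurred with a Gaussian kernel (correlation
  length 0.2 mm) and rescaled to the target pointwise sd, giving maps
  genuine spatial correlation — the regime variogram descriptors exist
  for.
* Drusen (AMD eyes only): K ~ Poisson(8), K ≥ 1 enforced, Gaussian
  bumps with amplitude U(5, 20) voxels and width U(0.08, 0.25) mm at
  uniform integer pixel centers, **subtracted** from the RPE border
  depth (the border lifts toward the ILM) with BM fixed.  The RPEDC map
  thus thickens focally while TR = BM − ILM carries no disease signal at
  all — so the total-retina arrangement behaves as a built-in negative
  control, mirroring its weak discriminative power on real data.
  Amplitudes are clipped where a bump would cross the ILM; clips are
  counted and logged.
* Volumes: piecewise-constant compartment intensities (vitreous 20,
  NSR 90, RPEDC 160, below-BM 50 — RPEDC brightest), multiplied by
  gamma speckle of unit mean and cv 0.2.  cv = 0 reproduces the means
  exactly, which anchors the en-face cross-checks.

The default grid is 200 × 50 × 128 voxels over the 6.7 mm × 6.7 mm
field — a scaled-down acquisition that preserves the anisotropic pitch
ratio; full-size generation is a parameter change.  Per-case RNG streams
are spawned from the cohort seed, so cohorts are reproducible and
individual cases independent.

What the generator does **not** emulate: realistic speckle physics,
vessel shadows, motion artifacts between B-scans, segmentation error,
geographic atrophy or choroidal neovascularization, and the reflectance
changes real drusen cause.  Consequently a passing synthetic benchmark
shows the pipeline recovers a known morphological group difference under
its own assumptions; it does not certify performance on clinical data.
In particular the synthetic en-face arrangements carry almost no class
signal by design (drusen displace the sampling surface but compartment
intensities are class-independent), which is consistent with the weak
en-face results reported on real data.

## Problem sizes

The packaged benchmark (`scripts/acceptance.py`) uses 60 AMD + 60
control eyes on the default 200 × 50 grid with ROI r = 3 mm, evaluating
TR-SV, NSR-SV, RPEDC-SV and RPEDC-SM under 5-fold × 10 repetitions;
estimator limit checks run on 128 × 128 i.i.d. grids.  These sizes give
stable estimates (AUROC standard errors well below 0.01 for the
discriminative arrangements) while completing in well under a minute on
a laptop-class CPU.

## Known limitations

* The empirical curves are raw descriptors; no variogram model fitting
  (sill/range/nugget) is provided or used as a feature.
* Lag geometry is closed-interval Euclidean; other conventions
  (axis-aligned Chebyshev annuli, open intervals) would shift pair
  counts at annulus boundaries.
* The CSV dialect does not carry reflectance volumes; use NPZ or MAT.
* Classifier hyperparameters are not tuned; the package deliberately
  reports the fixed-protocol result rather than a model-selection
  optimum.
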