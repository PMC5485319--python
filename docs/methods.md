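# Methods

This note records the models implemented in `kmotion`, the numerical
choices behind them, and what the synthetic phantoms do and do not
establish about real data.

## Acquisition model

All simulation is 2D, on the central axial slice of a 3D volume.  The
forward model evaluates the slice's spectrum at the trajectory's sample
positions,

    s(k) = Σ_x f(x) · exp(−2πi k·x),

with pixel positions x indexed relative to the image center and k in
cycles per pixel, each component in [−0.5, 0.5].  Three trajectories
are provided, each an ordered list of readouts (readout index =
acquisition time):

* **Cartesian** — horizontal lines at ky = (i − ⌊n/2⌋)/n, acquired top
  to bottom, so the central line is acquired halfway through the scan.
  For full sampling the forward map is exactly the centered 2D FFT and
  the reconstruction the inverse FFT (round-trip error ~1e−16).
* **Radial** — diameter spokes at angles jπ/n_spokes, signed radius
  sweeping (t − ⌊m/2⌋)/m.  Every spoke crosses k = 0.
* **Spiral** — Archimedean interleaves k(t) = 0.5·t·(cos φ, sin φ),
  φ = 2π·turns·t + interleave phase, from the center to |k| = 0.5.

### Gridding NUFFT

Non-Cartesian transforms use Kaiser–Bessel gridding on a 2× oversampled
grid (kernel width 12, Beatty shape parameter, deapodization by the
DFT of the sampled kernel).  Forward and adjoint share the same real
interpolation weights, so the adjoint is the exact matrix adjoint of
the forward operator (inner-product identity holds to ~1e−16).  The
accuracy contract — every sample within 1e−6 (measured: ~2e−11) of a
direct O(N²M) non-uniform DFT sum — is enforced by tests; the kernel
itself is an implementation detail behind that contract.

### Density compensation and reconstruction scale

Radial and spiral sampling oversample the k-space center; the adjoint
is therefore weighted by the ramp w ∝ |k| (samples at exactly k = 0 get
half the smallest non-zero radius; weights normalized to sum to the
sample count).  Voronoi or iterative compensation was deliberately not
used — the ramp is cheap and visibly faithful.  The reconstruction is
scaled by a per-trajectory calibration (cached) such that a
forward/adjoint round trip on a constant image preserves its mean.

One property worth knowing: with spoke samples spaced 1/N apart the
ramp-compensated point-spread function has a long-range halo that wraps
around the field of view, adding ~25% relative L2 error against the
original slice (402 spokes × 256 samples on a 256 grid).  Sampling each
spoke more densely — readout oversampling, which every real scanner
does — enlarges the alias-free FOV and removes the wrap: 402 × 1024 on
the same grid measures ~0.054, spiral (16 interleaves × 4096 samples,
8 turns) ~0.097.  These measured values are frozen as regression
bounds.  Artefact-energy comparisons are unaffected since corrupted and
clean images pass through the identical reconstruction.

## Motion models

**Bulk motion** follows a five-step strategy: rigidly transform the
volume (rotation about the volume center, then translation; linear
interpolation, zero fill), extract the central slice of both volumes,
forward-transform both, exchange a contiguous block of readouts —
`[round(offset·n), round(offset·n) + round(exchange·n))`, rounding
half-away-from-zero so that 2/256 at offset 0.5 hits exactly the two
central lines — and reconstruct the joint k-space.  Random transforms
draw each translation component uniformly with the vector rescaled to a
3.64 mm norm cap, and each rotation angle uniformly within ±5° (the
rotation bound is a configurable default; only the translation cap is a
fixed model constant).  Exchange granularity is always whole readouts:
lines, spokes, or interleaves.

**Respiratory motion** translates only the heart (not the torso)
superiorly by d(t) = max·(1 − cos(2π·cycles·t/n))/2, peaking at 7 mm by
default — the upper end of reported craniocaudal heart excursions over
a breathing cycle.  The displacement is quantized to 8 equispaced
levels (quantization error ≤ max/14, tested), so 8 shifted volumes
stand in for 256; each readout takes its k-space from the level the
breathing curve occupies at that moment.  The heart is moved by
resampling inside a dilated mask (radius = ceil(displacement) + 2
voxels) with a linear distance-transform feather across the dilation
band; how the vacated region is filled is underdetermined by the
physical setup, and the feathered warp is this package's choice.
Voxels outside the dilated mask are bit-identical to the input.

## Features

Every image is min–max normalized to [0, 1] over the ROI before
extraction, so no feature can key on global intensity scale introduced
by reconstruction weights.  Four families, all parameterized by one
frozen random specification set applied identically to every image:

* box: population mean and variance in a random patch;
* line: population std and max−min range of a bilinear profile sampled
  at unit steps along a random start/angle/length;
* histogram: mean, variance, skewness, excess kurtosis, entropy (bits)
  and energy, computed *from the histogram* (bin centers × normalized
  counts) so the random bin count genuinely matters; over the whole ROI
  (rotation invariant) or in a random patch (not);
* texture: the 13 classical Haralick GLCM statistics (64 gray levels,
  distance 1, symmetric, the four 2D directions averaged — exactly
  invariant under quarter-turn rotations).

Degenerate conventions keep every vector finite: zero-variance
skewness/kurtosis/correlation and the information measures of
correlation at zero entropy are all defined as 0; a constant input puts
all histogram mass in one bin.  The classical sum-variance statistic is
centered on the sum average (the well-known erratum in the original
formulation is not reproduced).  For cardiac images the ROI is the
maximal per-subject central-slice mask bounding box enlarged by 10%
total and centered on the pooled centroid; for brain images it is the
full image.  Default spec counts (200 box, 100 line, 25 + 25 histogram,
1 texture block; bins 8–64) are package choices, exposed in config.

## Detection protocol

One image per subject (clean or corrupted, chosen by a seeded
permutation under exact ⌊n/2⌋/⌈n/2⌉ balance) prevents the forest from
recognizing anatomy instead of artefacts.  Outer 5-fold stratified CV
estimates accuracy; inner 3-fold grid search (100 trees; max depth
unlimited/8/16 × min leaf 1/5; ties resolved in declared grid order)
selects hyperparameters on the outer-training split only.  Accuracy is
pooled over outer-test predictions.  Every random consumer receives an
independent child seed spawned from one master seed (`SeedSequence`
spawning, first word, reduced below 2³¹).  The experiment driver
computes each subject's per-state k-spaces once and re-merges them per
grid cell, so sweeping fractions/offsets costs only merges and inverse
transforms.

## Synthetic phantoms: what they emulate, and what they do not

Both generators are pure functions of (seed, shape), built from
analytic ellipsoids plus smoothed random fields — no data files.  The
brain phantom is a bright head (jittered position/size/orientation per
seed) containing a cortical shell, two bright ventricle-like lobes, a
mid-intensity deep structure and a small dark blob, over near-zero
background (≥ 30% of voxels below 5% of max); the cardiac phantom is a
textured torso with lung-like hypointensities and a two-ring heart
(bright blood pools in darker myocardium, 3–4% of the volume) with its
binary mask.  Critically, the *noise and texture amplitudes are drawn
per subject*: a cohort in which every scan has an identical noise floor
is unrealistic and makes even a single exchanged fringe line trivially
separable, because background features then have essentially zero
between-subject variance.  With between-scan SNR variation, detection
difficulty scales with artefact strength, which is the phenomenon under
study.

The phantoms do **not** emulate realistic MR contrast (T1/T2/PD), coil
sensitivities, bias fields, Rician noise correlations, anatomical
variability beyond affine jitter, or acquisition noise in k-space (none
is added; artefacts are the only corruption).  Passing tests therefore
demonstrate correctness of the simulation/detection machinery and the
*relative* structure of detectability (center sensitivity of Cartesian
sampling, offset robustness of radial/spiral, monotonicity in exchanged
fraction) — not absolute accuracy levels transferable to clinical
scans.

## Problem sizes

Default experiment scale is 60 subjects at 256×256×32 voxels (256
phase-encoding steps, matching the schedule arithmetic above); the
statistical checks use 10 phantom seeds for energy structure, 200
subjects for the permuted-label null, and 3 dataset seeds × 4 fractions
for the monotone-trend estimate.  These sizes are the package's chosen
desk-scale defaults; all are configurable.

## Known limitations

* Through-plane and intra-readout motion, cardiac contraction, and
  motion *correction* are out of scope.
* 2D simulation only; 3D trajectories and multi-coil data are not
  modelled.
* The ramp density compensation is adequate for artefact synthesis but
  not competitive with iterative reconstruction for image quality.
* Classification accuracies on phantoms should be read as
  pipeline-level sanity structure, not clinical performance estimates.
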