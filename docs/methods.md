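# Methods

`ringmrsi` implements the reconstruction chain for spatial-spectral MR
spectroscopic imaging (MRSI) acquired on concentric-ring k-space
trajectories, accelerated by hybrid through-time/through-k-space (tt/tk)
GRAPPA, with coil combination from an interleaved water-reference
acquisition.  Because no public raw data exist for this acquisition type,
the package also contains a first-class synthetic study generator; every
quantitative claim in the test suite is computed on that generator's output.

## Trajectory and gridding

k-space is sampled on `n_rings` equidistant circles with radii
`(i + 0.5) / fov` (first ring at half the Nyquist ring spacing) and the same
uniform angular grid of `points_per_ring` samples on every ring.  With
`n_rings = matrix_size / 2` the disc out to the Nyquist radius
`kmax = matrix_size / (2 fov)` is fully covered; the full-scale geometry is
32 rings x 540 points for a 64 x 64 matrix over a 220 mm FOV.  Units are
cycles/mm in k-space; image coordinates are 0-based voxel indices with the
object center at `matrix_size // 2` (FFT convention).

Reconstruction to Cartesian images uses convolution gridding: density
compensation, Kaiser-Bessel spreading (kernel width 3, oversampling factor
2, beta from Beatty's formula), inverse FFT, numerical deapodization, and a
center crop.  An exact adjoint non-uniform DFT (`adjoint_nudft`) and the
exact forward NUDFT (`image_to_rings`, also the simulator's forward model)
serve as references; gridding agrees with the direct sum to well under 5%.

**Density compensation.** Pipe-Menon fixed-point iteration
`w <- w / (w * C)` with the width-3 Kaiser-Bessel kernel measured in
*Nyquist* grid units (1/fov), so adjacent rings couple radially; for this
ring family the iteration collapses to an `n_rings x n_rings` ring-coupling
matrix and converges in a handful of iterations (defaults `n_iter=30`,
`tol=1e-2`).  Interior weights land on the annulus-area rule
`2 pi r dk / points_per_ring` to within a few percent; the rule breaks at
both radial boundaries (the unsampled center disc, and the outermost ring
whose kernel coupling is one-sided), which is why the area property is
stated for interior rings only.

**Normalization.** The trajectory acquires no sample at k = 0; the DC mode
is reconstructed entirely from Dirichlet tails picked up on the innermost
ring and its gain cannot be pinned to the passband gain by any diagonal
weighting.  We normalize the weights so that a quarter-band spatial
frequency round-trips with unit amplitude (unit passband gain); a perfectly
flat object then reconstructs roughly 1.5x too bright, and content within
about a ring spacing of the FOV edge aliases.  Both effects are properties
of the sampling, cancel in any comparison between two reconstructions of
the same data, and are avoided in practice by keeping the object inside
~75% of the FOV — which the evaluation masks do.

## Synthetic study generator

`make_phantom` builds a deterministic (seeded) 2-D head: elliptical brain
with a cortical gray-matter band, inner white matter, two CSF ventricles,
and a 2-voxel subcutaneous lipid rim separated from the brain by one voxel.
Per-compartment amplitudes define ground-truth maps for tNAA (2.01 ppm),
tCr (3.02 ppm), tCho (3.2 ppm), lipids (1.3 / 0.9 ppm), and water (4.7 ppm
carrier, ~40x the metabolite level).  Each voxel emits a sum of Lorentzian
FIDs, `A exp(2 pi i f t) exp(-t/T2*)`, with ppm-to-Hz conversion at 7 T
(297.2 MHz); metabolite T2* of 24 ms gives ~13 Hz linewidths, matching the
linewidths reported for this sequence in vivo.  Receive coils are smooth
complex Gaussian-blob profiles on a circle around the FOV (8 by default);
Biot-Savart realism is unnecessary for validating reconstruction algebra.
Acquisition evaluates the coil-weighted forward NUDFT on the ring
trajectory per spectral time point and adds i.i.d. complex Gaussian noise.

The **noise level** (per-component k-space sd 8.0 in the desk preset) was
calibrated once so that the combined in-brain spectral SNR — tCr-band
maximum over pseudo-replica noise, the same definition used for the in vivo
data — sits near the reported in vivo value of ~21.

**Calibration modes.** Water references use 27 spectral points and a
reduced flip scale: `sin(5)/sin(42)` for the interleaved reference
(`imusical`), `sin(13)/sin(42)` for the standalone prescans.  The
interleaved mode shares the head position of the MRSI scan exactly.  The
`static` prescan is given a small repositioning drift (3 deg rotation by
default): acquired minutes away from the MRSI scan, a prescan never sees an
identical head position, and this drift is precisely the mechanism to which
the interleaved reference owes its in vivo advantage — without it the two
modes are statistically identical in simulation.  The `moved` prescan
rotates the head by 15 deg (instructed rotation).  Rotations are bilinear
and applied to the object, with masks re-derived by thresholding.

**What the generator does not emulate:** macromolecular baselines, eddy
currents and gradient delays, B0 inhomogeneity (the off-resonance map
defaults to zero and no off-resonance correction is implemented),
T1-saturation differences between TRs, intra-scan motion, and realistic
coil noise covariance (identity by default, prewhitening hook provided).
Passing tests therefore demonstrate the correctness of the reconstruction
algebra and the direction of calibration-quality effects, not in vivo
performance levels.

## Undersampling

Acceleration is counted per ring (one ring costs one TR per temporal
interleaf).  `make_pattern(n_rings, R, core)` keeps the innermost `core`
rings (5 at full scale) and every `R`-th outer ring after skipping `R - 1`.
This phase convention reproduces the printed effective factors — 18/32
measured rings (R_eff 1.78) for two-fold and 11/32 (R_eff 2.91) for
four-fold variable density — and makes the patterns of successive powers of
two nest, which the recursive reconstruction ladder
(R=8 -> R=4 -> R=2 -> full) requires.  Decimation is a pure restriction of
retrospectively fully sampled data.

## tt/tk-GRAPPA

Each missing sample is reconstructed independently as a linear combination
of six sources: the nearest measured ring below and above the target, at
three angular indices centered on the target's (circular along the ring).
Translational invariance holds only locally on a non-Cartesian trajectory,
so weight calibration harvests kernel repetitions from a segment of 15
points x 4 rings around the target (13 x 3 = 39 spatial positions, the
constellation mirrored ring-for-ring and index-for-index in the fully
sampled calibration data) and from the first 21 calibration FID points
(earliest points have the highest SNR), 819 repetitions in total.  Weights
are accepted only if repetitions >= source points x coils (192 at 32
coils; `force=True` overrides).  The per-target least-squares problem is
solved via batched normal equations (Cholesky), falling back to
`lstsq`/pseudoinverse on rank deficiency, with optional Tikhonov
regularization scaled relative to the mean diagonal of the normal matrix
(`lam`, default 0 — plain least squares).  Residual norms and a condition
estimate are stored per ring.

Boundary handling: a target with no measured ring on one side (possible for
constant-density patterns and the outermost rings) falls back to the two
nearest measured rings on the available side and records a warning; the
segment's ring shifts are truncated, never wrapped across the k-space
center.

Application multiplies the same weights onto every spectral time point of
the undersampled FID — filled data at time t depend only on measured data
at t.  Recursion re-solves weights per stage against the same calibration
set with the same geometry.  3-D stacks are handled by looping the 2-D
engine over partitions.

The core correctness oracle is a planted linear model: data whose missing
rings are exact fixed linear combinations of their sources are recovered to
machine precision, for any coil count and kernel width, when the segment
has no ring extent beyond the kernel.  (A planted per-ring model cannot be
made ring-shift invariant in general, so ring sliding is validated on the
phantom regressions instead.)

## Coil combination

The first spectral point of the water reference is gridded per coil into
U_c; weights `w_c = conj(U_c) / sum |U_c|^2` (switchable to
`/ sqrt(sum |U_c|^2)`, `norm_mode="rss"`).  The default gives a
sensitivity-corrected image in object units and scales inversely with a
global calibration scale; the rss mode is scale invariant.  Both cancel the
common phase at t = 0 exactly — the intrinsic 0th-order prephasing — and
reach the matched-filter SNR for identity noise covariance when the
reference is clean.  Voxels below a relative calibration-power floor
(1e-3 of the maximum) are zeroed and masked.  Combination runs in image
space after GRAPPA (performed in k-space) and gridding, matching the
pipeline order of the acquisition this models.

## Evaluation

*Pseudo-replica*: synthetic complex Gaussian noise is added to the measured
k-space, the full deterministic reconstruction (GRAPPA weights pre-solved
from calibration, hence replica-independent) is run per replica, and the
per-voxel std of the output (per noise component, so an identity
reconstruction returns the injected sd) is the noise map; SNR =
|mean| / std.  The default SNR functional is the combined t = 0 image,
the highest-SNR point of the FID.

*g-factor*: `g = SNR_full / (SNR_PI sqrt(R_total))` with R_total the
pattern's effective (ring-count) acceleration.  At desk scale the
unaccelerated control gives g = 1 within Monte-Carlo tolerance and matched
calibration beats the rotated prescan (1.03 vs 1.29 at R_eff 1.78,
seed 1, 50 replicas).  One known deviation from the in vivo behavior:
weights solved from the smooth, high-SNR water phantom have small norms and
act as mild apodizers, so synthesized rings carry *suppressed* noise and
mean g does not grow with R the way it does in vivo; for constant-density
patterns (which lose an innermost ring under the parity convention) the
apparent g can drop to ~0.8.  The g >= 1 property is therefore asserted
for variable-density patterns, the ones this acquisition design favors.

*Maps*: LCModel-style spectral fitting is out of scope; metabolite maps
integrate the magnitude spectrum over bands (tNAA 1.9-2.1, tCr 2.9-3.1,
tCho 3.1-3.3 ppm, half-open to avoid overlap) and residual lipid
contamination integrates 0.2-2.3 ppm normalized to the median tCr of the
fully sampled reference.  Magnitude-mode Lorentzian tails decay only as
1/offset, so adjacent bands exchange ~10% even for narrow lines — a
limitation of band integration relative to fitting, shared by all
reconstructions being compared.  %RMSE is `100 ||map - ref||_2 /
||ref||_2` over the brain mask with a global norm; references are the
fully sampled reconstruction combined with the matching calibration (the
static-prescan reference also serves the moved prescan).

## Problem sizes and determinism

The `desk` preset (32 x 32 matrix, 16 rings, 128 points/ring, 8 coils, 64
spectral points, 27-point calibrations) is the package's standard study
size: a full simulate-reconstruct-evaluate sweep over all patterns and
calibration modes runs in about a minute on one core, which is what the
test suite uses (fixed seed 1).  The `full` preset carries the full
acquisition geometry (64 x 64, 32 rings, 540 points, 882 spectral points,
32 coils) for users who want to run at scale.  All randomness flows through
explicit seeds; every container embeds the configuration and seed that
produced it, and re-running any stage with identical inputs reproduces its
output bit for bit.

## Known limitations

- Off-resonance correction during gridding is not implemented (the
  simulator's B0 map defaults to zero).
- Constant-density patterns can leave the innermost or outermost rings with
  one-sided GRAPPA sources; the fallback is logged but accuracy there is
  structurally worse.
- Band-integration maps are a coarse substitute for spectral fitting; the
  tNAA band in particular inherits simulated lipid-tail contamination, as
  tNAA does in vivo.
- Prospective undersampling of the interleaved calibration is not modeled
  (retrospective decimation only).
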