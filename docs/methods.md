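# Methods

## The distortion model

All geometry lives on a fixed axis convention: axis 0 readout, axis 1
phase-encode (PE), axis 2 partition.  Off-resonance `f(x)` (Hz) displaces
signal along PE by `d = f · T_ro` voxels, where `T_ro` is the total readout
time; blip-up (+1) shifts toward +PE, blip-down (−1) the opposite way.  The
simulator's forward model is the pull-back

```
I±(y) = I0(y ∓ d(y)) · (1 ∓ ∂d/∂y)
```

with linear interpolation and zeros outside the FOV.  The Jacobian factor
`1 ∓ ∂d/∂y` conserves the integral of each PE line (verified to < 0.5% for
smooth fields); compressed regions brighten, stretched regions dim.  k-space
is stored centered (DC at index `N//2`); a pseudo-centric acquisition places
the Fourier transform of the blip-up image on PE lines ≥ center and of the
blip-down image on the acquired lines below, with partial Fourier truncating
the −PE edge (`round(pf·N)` lines kept; default pf = 0.75, so the blip-down
half spans a quarter of the full extent).  The center line — the first
acquired, blip-free line — belongs to the blip-up transform.

## Splitting conventions

Two center-line rules exist because estimation and correction need different
things.  For **field estimation** the center line is included in *both*
halves, balancing the gross signal level of the two surrogate images.  For
**correction** it is included only in the blip-up half, so that the two
zero-filled halves partition the data exactly: their complex sum equals the
plain zero-filled reconstruction, which keeps the zero-field case exact.

## POCS completion

Each partial k-space is completed by alternating a phase projection with a
data-consistency projection.  Choices that matter (all measured on the
synthetic suite):

* **Initialization** is the Hermitian-completed k-space — unacquired samples
  whose conjugate partner was acquired start from the reflected conjugate.
  For a real-valued object this is already exact (recovery RMSE < 1e−3 is a
  tested invariant); zero-fill starts converge to visibly worse fixed points.
* **The phase reference** is recomputed every iteration from the central
  Hann-windowed band of the *current* estimate (self-consistent), with the
  band half-width capped at 4 lines: a wide band lets reconstruction
  artifacts leak into the reference.  By default the reference is further
  regularized by a magnitude-weighted 2nd-order polynomial fit per in-plane
  slice (`phase_model="poly"`); the raw band estimate remains available
  (`"band"`).  The fit assumes wrap-free phase — exactly the regime in which
  partial-Fourier acquisition is sensible.
* 30 iterations, relative-change tolerance 1e−6; the final step is always
  data consistency, so acquired samples are preserved to float round-off
  (tested at 1e−10).

## Masking and uniformity correction

The blip-up surrogate is masked by Otsu's 256-bin threshold (largest
connected component kept, holes filled).  The blip-down mask is obtained by
dilation with a triangular structuring element (radius 2, in-plane) on the
first pass — before any field information exists — and on later passes by
warping the blip-up mask along PE by `−2·d` (nearest neighbour), since the
two images are displaced by +d and −d.

Uniformity correction divides the magnitude image by a lowpass copy in which
the background was first replaced by the image maximum (so background noise
is not amplified).  The smoothing width is either constant σ = 8 voxels, or
location-dependent: σ = 0.5 at the mask's in-plane center of mass, 8 at the
boundary, linear in the relative radial distance along each ray (implemented
by polar sampling of the boundary at 720 angles).  Spatially varying
smoothing interpolates between a bank of constant-σ filtered images
(σ ∈ {0.5, 1, 2, 4, 8}), which makes the constant-σ case *exactly* a single
Gaussian convolution (tested against that oracle).  The correction is used
only to prepare the registration inputs; corrected EPI images never pass
through it.

## Reversed-polarity registration

The field is the minimizer of

```
Σ w² · (W₊(I_up, d) − W₋(I_down, d))² + λ ‖∇² d‖²
```

where `W±` warp by ±d toward undistorted space (with Jacobian modulation),
`λ = 2` weights a bending-energy penalty (inputs are normalized by their
joint 99th percentile, so λ is scale-free), and `w` is a signal-confidence
weight `(smoothed max(I_up, I_down))^0.5` that keeps low-signal voxels —
which carry reconstruction ringing rather than anatomy — from driving the
estimate.  Optimization is Gauss–Newton with a diagonal data term, sparse
biharmonic regularizer, Levenberg damping (1e−3), and backtracking line
search, over a coarse-to-fine pyramid (σ/subsampling 4/4, 2/2, 1/1); the
objective is non-increasing across accepted steps at every level (tested).
Everything is deterministic: d₀ = 0, no randomness anywhere.  3-D volumes are
estimated slice-wise along the partition axis.  λ was calibrated on
parameter-recovery simulations; the null case is a fixed point for any λ
because identical inputs give a zero residual at d = 0.

The full single-k-space procedure runs three masking/uniformity/registration
passes: pass 1 uses the dilation mask and constant σ, later passes use the
warped mask, and the final pass switches to the location-dependent σ.  The
ablation switches (`IterativeOptions.from_variant`) disable these steps one
by one, from `pocs_only` up to `lsr`.

## Correction and least-squares restoration

`correct_cenepi` zero-fills the two correction-split halves (no POCS at this
stage), inverse transforms, scales each complex half-image by 2 (each half
carries roughly half the signal; a uniform factor preserves the partition
identity, so a zero field reproduces the partial-Fourier reconstruction
exactly), and either complex-averages the two oppositely corrected images or
solves, per PE column, the joint linear system

```
min ‖A₊ o − i_up‖² + ‖A₋ o − i_down‖² + ε ‖o − o̅‖²
```

whose operators `A±` are the same linear-interpolation + Jacobian matrices
the simulator applies.  The Tikhonov term (ε = 1e−3 of the mean normal-matrix
diagonal) shrinks toward the complex average of the two singly corrected
columns `o̅`, which regularizes rows fed from outside the FOV while keeping
the zero-field closed form `(i_up + i_down)/2` exact.  Complex data reuse the
real operators on real and imaginary parts.

## The synthetic study conditions

The simulator defines the conditions under which the pipeline is validated:

* phantom: overlapping ellipses (outer "skull", internal structures, a
  ventricle-like dark region), ~12% smooth texture, a ±25% receive-coil-like
  bias, edges softened with a σ = 1 Gaussian toward a band-limited object,
  background exactly zero over ≥ 30% of the FOV;
* object phase: a smooth 2nd-order polynomial of ±~0.12 rad.  This amplitude
  keeps the acquisition inside the approximate-Hermitian-symmetry regime that
  partial Fourier presupposes.  The pipeline's sensitivity to this choice is
  known and deliberate: at ±0.45 rad the phase-dependent difference between
  the two partial-Fourier reconstructions already biases the null-field
  estimate to ~0.23 voxels, and localized multi-radian phase (air-tissue
  interfaces, fat) breaks the desk-scale estimator altogether — see
  *Limitations*;
* field: 3–4 Gaussian bumps, default 80 Hz amplitude and ≥ 10-voxel width,
  giving PE shifts up to 2.4 voxels at `T_ro` = 30 ms (gradient bounded by
  amplitude/smoothness per voxel by construction);
* noise: optional complex Gaussian in k-space, off by default;
* perfusion: 34 label/control pairs and 15 M₀ volumes, ΔM/M₀ = 0.6% in gray
  matter (≈ 53 ml/100 g/min under the standard constants: blood T1 1.65 s,
  labeling efficiency 0.68, partition coefficient 0.9 ml/g, PLD 1.5 s,
  labeling duration 1.8 s).

Everything is bitwise reproducible per seed.

## What passing tests do and do not show

On these conditions the pipeline recovers smooth fields with median in-mask
r ≈ 0.92 and RMSE ≈ 0.28 voxels over ten seeded phantoms, keeps the
zero-field estimate below 0.1 voxel, strictly improves Dice on every case,
and LSR beats complex averaging by orders of magnitude on noiseless pairs.

One expected ordering is *not* reproduced, and its test is intentionally left
failing rather than weakened: enabling the masking/uniformity-correction
safeguards should not worsen the field error relative to POCS alone, yet here
it does (median RMSE 0.07 voxels for `pocs_only` vs 0.23–0.46 for the UC
variants).  The reason is structural: those safeguards target in-vivo signal
suppression that survives POCS — driven by large phase errors, fat, and
relaxation, none of which these clean synthetic conditions contain — so on
this phantom family they can only add boundary and interpolation cost.  In
probes with multi-radian localized phase the expected tendency reappears
(dilation-mask UC beats `pocs_only`), but under such conditions the overall
recovery quality collapses below any useful threshold for this simplified
engine.  The simulation therefore validates the mechanics and contracts of
every step, not the in-vivo benefit of the robustness steps.

## Limitations

* Object phase beyond a few tenths of a radian degrades the partial-Fourier
  surrogates; no phase unwrapping is attempted anywhere (the GRE reference
  aliases at |f| ≥ 1/(2ΔTE)).
* Relaxation, coil sensitivities, ghosting, fat, motion, and jump-blip eddy
  currents are not simulated; input k-space is assumed phase-corrected.
* Field estimation is slice-wise 2-D; a 3-D-coupled estimate and FSL-style
  spline parametrizations are out of scope, as is bit-compatibility with
  FSL's topup/applytopup.
* Partial Fourier is modeled on the PE axis only.
* The discrete boundary Hausdorff distance saturates at one voxel on 64×64
  masks, so geometric improvement below that scale shows up in Dice but only
  in the suite-mean Hausdorff.
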