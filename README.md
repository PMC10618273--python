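# blipmap

**B₀ field mapping and susceptibility-distortion correction from a single
centric-ordered EPI k-space.**

Echo-planar imaging (EPI) has a low bandwidth along the phase-encode (PE)
axis, so B₀ inhomogeneity displaces signal by `d = f · T_ro` voxels (`f` the
off-resonance in Hz, `T_ro` the total readout time).  The classic remedy —
reversed-polarity ("topup") field mapping — needs **two** scans with opposite
PE blip polarity.  A pseudo-centric single-shot EPI trajectory, however, fills
the upper and lower k-space halves with *opposite* blip polarities within one
shot: a single k-space already contains two oppositely distorted views of the
object.  `blipmap` exploits that:

1. **split** the centric k-space at the center line (shared by both halves to
   balance signal for estimation; blip-up-only for correction),
2. **complete** each partial k-space by POCS (projection onto convex sets)
   with a smooth-phase constraint,
3. **equalize** the two surrogate images by iterative automatic brain masking
   (Otsu → triangular dilation → field-based warping) and uniformity
   correction (division by a max-filled, Gaussian-lowpassed copy; constant
   σ = 8 or a location-dependent σ rising from 0.5 at the mask's center of
   mass to 8 at its boundary),
4. **register** them with a reversed-polarity displacement estimator
   (multi-resolution Gauss–Newton on
   `‖W₊(I_up, d) − W₋(I_down, d)‖² + λ‖∇²d‖²`) to obtain the field map, and
5. **unwarp** the two complex half-images in opposite directions, combining
   them by complex averaging or per-column least-squares restoration (LSR).

A synthetic simulator (brain-like phantom, smooth Gaussian-bump fields,
polarity-dependent distortion with Jacobian intensity modulation, partial
Fourier, double-echo GRE pair, toy pCASL series) makes every stage testable
without scanner data, and an evaluation suite provides Dice, Hausdorff,
perfusion SNR/tSNR, field-map correlation, and CBF quantification
(`CBF = (ΔM/M₀) · 6000·λ·e^{PLD/T1b} / (2·α·T1b·(1−e^{−τ/T1b}))`).

## Worked example

```python
import numpy as np, blipmap as bm

params  = bm.AcquisitionParams(matrix_shape=(64, 64), partial_fourier=0.75,
                               total_readout_time=0.03)
phantom = bm.make_phantom((64, 64), seed=1)
truth   = bm.make_field_map((64, 64), amplitude_hz=80.0, smoothness=10.0, seed=7)
k       = bm.simulate_cenepi_kspace(phantom, truth, params)

fmap, mask_up, mask_dn = bm.estimate_field_single_kspace(k)   # 3 passes
corrected = bm.correct_cenepi(k, fmap, use_lsr=True)
```

Running `python examples/02_field_from_single_kspace.py` and
`03_distortion_correction.py` prints:

```
in-object agreement : Pearson r = 0.948, RMSE = 0.21 voxels
uncorrected     : Dice vs truth = 0.9961, in-object RMSE = 0.0620
complex average : Dice vs truth = 0.9980, in-object RMSE = 0.0263
LSR             : Dice vs truth = 0.9980, in-object RMSE = 0.0111
```

i.e. the field recovered from the *single* k-space matches the simulated
truth to ~0.2 voxels, correction restores the object geometry (Dice up), and
LSR halves the residual intensity error relative to complex averaging.  The
other examples demonstrate the simulator (`01`) and the double-echo GRE
reference plus perfusion/CBF metrics (`04`).

A thin CLI mirrors the library:

```bash
blipmap simulate --shape 64,64,8 --out-dir sim/
blipmap estimate --kspace sim/kspace --out sim/field
blipmap correct  --kspace sim/kspace --field sim/field --out sim/corrected.nii.gz
blipmap evaluate --corrected sim/corrected.nii.gz --truth sim/phantom_mag.nii.gz
blipmap ablate   --seed 0            # step-by-step ablation sweep
blipmap demo     --seed 0            # end-to-end run with a JSON report
```

Volumes are NIfTI-1; k-space travels as NPZ plus a YAML sidecar with the
acquisition parameters; field maps are written in Hz and in voxel
displacement with a plain-text PE-direction/readout-time sidecar.

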