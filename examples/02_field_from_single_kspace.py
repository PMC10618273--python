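"""Estimate the B0 field map from one centric k-space — no extra scan.

The k-space is split at the center line, both halves are completed by POCS,
and the two oppositely distorted surrogate images are registered through
three passes of automatic masking + uniformity correction.  The recovered
field is compared voxelwise with the simulated truth.
"""

import numpy as np

import blipmap as bm

params = bm.AcquisitionParams(matrix_shape=(64, 64))
phantom = bm.make_phantom((64, 64), seed=1)
truth = bm.make_field_map((64, 64), amplitude_hz=80.0, smoothness=10.0, seed=7)
k = bm.simulate_cenepi_kspace(phantom, truth, params)

passes = []
fmap, mask_up, mask_dn = bm.estimate_field_single_kspace(
    k, callback=lambda it, f: passes.append(it))
print(f"registration passes : {len(passes)} "
      "(dilation mask first, warped masks after; location-dependent "
      "uniformity correction on the last pass)")

obj = np.abs(phantom) > 0.1 * np.abs(phantom).max()
d_hat = fmap.displacement_voxels(params)
d_true = truth.displacement_voxels(params)
r = np.corrcoef(d_hat[obj], d_true[obj])[0, 1]
rmse = np.sqrt(np.mean((d_hat - d_true)[obj] ** 2))
print(f"in-object agreement : Pearson r = {r:.3f}, RMSE = {rmse:.2f} voxels")
print("a correlation near 1 and sub-voxel RMSE mean the field recovered from "
      "the single k-space can drive the distortion correction")
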