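"""Correct the EPI distortion with the estimated field map.

The two k-space halves are corrected separately in opposite directions and
combined either by complex averaging or by least-squares restoration (LSR),
which solves the joint resampling system per PE column.  Geometric quality is
scored by the Dice overlap with the undistorted object mask.
"""

import numpy as np

import blipmap as bm
from blipmap.core import ifft_centered

params = bm.AcquisitionParams(matrix_shape=(64, 64))
phantom = bm.make_phantom((64, 64), seed=1)
truth = bm.make_field_map((64, 64), amplitude_hz=80.0, smoothness=10.0, seed=7)
k = bm.simulate_cenepi_kspace(phantom, truth, params)

fmap, _, _ = bm.estimate_field_single_kspace(k)

distorted = ifft_centered(k.data)
avg = bm.correct_cenepi(k, fmap, use_lsr=False)
lsr = bm.correct_cenepi(k, fmap, use_lsr=True)

truth_mask = bm.otsu_mask(np.abs(phantom))
for name, img in (("uncorrected", distorted), ("complex average", avg),
                  ("LSR", lsr)):
    d = bm.dice(bm.otsu_mask(np.abs(img)), truth_mask)
    obj = np.abs(phantom) > 0.1 * np.abs(phantom).max()
    rmse = np.sqrt(np.mean((np.abs(img) - np.abs(phantom))[obj] ** 2))
    print(f"{name:16s}: Dice vs truth = {d:.4f}, in-object RMSE = {rmse:.4f}")
print("Dice should rise after correction; LSR sharpens fine structure beyond "
      "plain averaging of the two corrected halves")
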