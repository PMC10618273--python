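"""Cross-check against the double-echo GRE reference and quantify perfusion.

A double-echo gradient-echo pair gives the reference field map (phase
difference over 2*pi*dTE, exact when no wrap occurs).  The single-k-space
estimate is correlated against it, and a toy pCASL label/control series is
evaluated with perfusion SNR, temporal SNR, and the standard CBF
quantification.
"""

import numpy as np

import blipmap as bm

params = bm.AcquisitionParams(matrix_shape=(64, 64))
phantom = bm.make_phantom((64, 64), seed=3)
truth = bm.make_field_map((64, 64), amplitude_hz=60.0, smoothness=10.0, seed=33)

te1, te2 = 0.00492, 0.00738
e1, e2 = bm.simulate_gre_pair(phantom, truth, te1, te2)
gre = bm.gre_fieldmap(e1, e2, te1, te2)
obj = np.abs(phantom) > 0
print(f"GRE reference error : {np.abs(gre.values - truth.values)[obj].max():.2e} Hz "
      "(machine precision in the wrap-free regime)")

k = bm.simulate_cenepi_kspace(phantom, truth, params)
fmap, mask_up, _ = bm.estimate_field_single_kspace(k)
r = bm.fieldmap_correlation(fmap, gre, mask_up)
print(f"single-k-space vs GRE reference: r = {r:.3f} over {mask_up.sum()} voxels")

gm = bm.otsu_mask(np.abs(phantom))
series = bm.simulate_perfusion_series(phantom, gm, noise_sd=0.01, seed=0)
perf = series.delta_m()
snr = bm.perfusion_snr(perf, series.gm_mask, series.bg_mask)
tsnr = bm.perfusion_tsnr(series, series.gm_mask)
cbf = bm.cbf_map(perf, series.m0_mean(), bm.CBFParams())
print(f"perfusion SNR = {snr:.2f}, temporal SNR = {tsnr:.3f} "
      f"({series.n_pairs} label/control pairs)")
print(f"gray-matter CBF = {cbf[gm].mean():.1f} ml/100 g/min "
      "(labeling efficiency 0.68, blood T1 1.65 s, PLD 1.5 s, tau 1.8 s)")
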