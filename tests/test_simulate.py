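"""Simulator contracts: phantom structure, field smoothness, the distortion
model and its conservation/round-trip properties, centric k-space assembly,
GRE pair and perfusion series."""

import numpy as np
import pytest

import blipmap as bm
from blipmap.core import fft_centered, ifft_centered
from blipmap.simulate import _pe_sample


class TestMakePhantom:
    def test_deterministic_and_seed_sensitive(self):
        a = bm.make_phantom((64, 64), seed=1)
        b = bm.make_phantom((64, 64), seed=1)
        c = bm.make_phantom((64, 64), seed=2)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_background_corners_are_zero(self, seed):
        ph = bm.make_phantom((64, 64), seed=seed)
        for ix in (0, -1):
            for iy in (0, -1):
                assert abs(ph[ix, iy]) == 0.0

    def test_background_covers_fov_edge(self):
        ph = bm.make_phantom((64, 64, 8), seed=0)
        assert np.mean(np.abs(ph) == 0) >= 0.3

    @pytest.mark.parametrize("shape", [(4, 64), (64, 4), (64, 64, 4, 2), (16, 16)])
    def test_degenerate_shapes_rejected(self, shape):
        with pytest.raises(ValueError):
            bm.make_phantom(shape, seed=0)


class TestMakeFieldMap:
    def test_zero_amplitude_gives_zero_field(self):
        f = bm.make_field_map((64, 64), amplitude_hz=0.0, seed=3)
        assert np.all(f.values == 0)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_amplitude_and_gradient_bounds(self, seed):
        amp, smooth = 50.0, 8.0
        f = bm.make_field_map((64, 64), amp, smooth, seed=seed)
        assert np.abs(f.values).max() <= amp + 1e-9
        for ax in range(2):
            assert np.abs(np.diff(f.values, axis=ax)).max() <= amp / smooth + 1e-9

    def test_distinct_seeds(self):
        f1 = bm.make_field_map((64, 64), 50.0, seed=1)
        f2 = bm.make_field_map((64, 64), 50.0, seed=2)
        assert not np.array_equal(f1.values, f2.values)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            bm.make_field_map((64, 64), amplitude_hz=-1.0)


class TestDistortImage:
    def test_zero_field_is_identity(self, phantom2d, params2d):
        out = bm.distort_image(phantom2d, np.zeros((64, 64)), +1, params2d)
        assert np.allclose(out, phantom2d, atol=1e-12)

    def test_uniform_integer_shift(self, phantom2d, params2d):
        f = np.full((64, 64), 2.0 / params2d.total_readout_time)
        out = bm.distort_image(phantom2d, f, +1, params2d)
        assert np.allclose(out[:, 2:], phantom2d[:, :-2], atol=1e-12)
        assert np.allclose(out[:, :2], 0.0)

    def test_matches_dense_bruteforce_resampler(self, phantom2d, params2d, field2d):
        out = bm.distort_image(phantom2d, field2d, +1, params2d,
                               modulate_jacobian=False)
        d = field2d.displacement_voxels(params2d)
        expect = np.zeros_like(phantom2d)
        for ix in range(64):
            for iy in range(64):
                t = iy - d[ix, iy]
                j0 = int(np.floor(t))
                fr = t - j0
                v = 0.0
                if 0 <= j0 < 64:
                    v += (1 - fr) * phantom2d[ix, j0]
                if 0 <= j0 + 1 < 64:
                    v += fr * phantom2d[ix, j0 + 1]
                expect[ix, iy] = v
        assert np.abs(out - expect).max() < 1e-10

    def test_jacobian_conserves_line_sums(self, phantom2d, params2d, field2d):
        out = bm.distort_image(phantom2d, field2d, +1, params2d,
                               modulate_jacobian=True)
        sums_in = np.abs(phantom2d).sum(axis=1)
        sums_out = np.abs(out).sum(axis=1)
        sel = sums_in > 0.1 * sums_in.max()
        rel = np.abs(sums_out - sums_in)[sel].max() / sums_in[sel].max()
        assert rel < 0.005

    def test_round_trip_with_resampled_field(self, phantom2d, params2d, field2d):
        distorted = bm.distort_image(phantom2d, field2d, +1, params2d)
        d = field2d.displacement_voxels(params2d)
        # field expressed in distorted coordinates (one fixed-point sweep)
        d_res = _pe_sample(d, d, 1, order=1)
        f_res = d_res / params2d.total_readout_time
        back = bm.distort_image(distorted, f_res, -1, params2d)
        obj = np.abs(phantom2d) > 0
        rel = np.linalg.norm((back - phantom2d)[obj]) / np.linalg.norm(phantom2d[obj])
        assert rel < 0.02

    def test_excessive_displacement_rejected(self, phantom2d, params2d):
        f = np.full((64, 64), 100.0 / params2d.total_readout_time)
        with pytest.raises(ValueError):
            bm.distort_image(phantom2d, f, +1, params2d)


class TestCenepiKspace:
    def test_zero_field_equals_masked_transform(self, phantom2d, params2d):
        k = bm.simulate_cenepi_kspace(phantom2d, np.zeros((64, 64)), params2d)
        ref = fft_centered(phantom2d)
        mask = params2d.acquired_lines()
        assert np.allclose(k.data[:, mask], ref[:, mask], rtol=1e-9, atol=1e-9)
        assert np.all(k.data[:, ~mask] == 0)

    def test_partial_fourier_row_mask(self, phantom2d, params2d):
        k = bm.simulate_cenepi_kspace(phantom2d, np.zeros((64, 64)), params2d)
        assert k.acquired_mask.sum() == 48          # 0.75 * 64
        assert not k.acquired_mask[:16].any()
        assert k.acquired_mask[16:].all()

    def test_halves_carry_their_polarity(self, phantom2d, params2d, field2d):
        k = bm.simulate_cenepi_kspace(phantom2d, field2d, params2d)
        pair = bm.split_for_estimation(k)
        up_img = 2 * ifft_centered(pair.k_up.data)
        tru_up = bm.distort_image(phantom2d, field2d, +1, params2d)
        tru_dn = bm.distort_image(phantom2d, field2d, -1, params2d)

        def nerr(a, b):
            return (np.linalg.norm(np.abs(a) - np.abs(b))
                    / np.linalg.norm(np.abs(b)))

        assert nerr(up_img, tru_up) < nerr(up_img, tru_dn)

    def test_linear_trajectory_rejected(self, phantom2d):
        p = bm.AcquisitionParams(matrix_shape=(64, 64), trajectory="linear_up")
        with pytest.raises(ValueError):
            bm.simulate_cenepi_kspace(phantom2d, np.zeros((64, 64)), p)

    def test_noise_reproducible_for_seed(self, phantom2d, params2d):
        k1 = bm.simulate_cenepi_kspace(phantom2d, np.zeros((64, 64)), params2d,
                                       noise_sd=1.0, seed=5)
        k2 = bm.simulate_cenepi_kspace(phantom2d, np.zeros((64, 64)), params2d,
                                       noise_sd=1.0, seed=5)
        assert np.array_equal(k1.data, k2.data)


class TestGrePair:
    def test_phase_difference_closed_form(self, phantom2d):
        f = np.full((64, 64), 30.0)
        e1, e2 = bm.simulate_gre_pair(phantom2d, f, 0.00492, 0.00738)
        obj = np.abs(phantom2d) > 0
        dphi = np.angle(e2 * np.conj(e1))[obj]
        assert np.allclose(dphi, 2 * np.pi * 30.0 * 0.00246, atol=1e-9)
        assert np.allclose(np.abs(e1), np.abs(e2))

    def test_zero_field_zero_phase_difference(self, phantom2d):
        e1, e2 = bm.simulate_gre_pair(phantom2d, np.zeros((64, 64)), 0.005, 0.007)
        assert np.allclose(np.angle(e2 * np.conj(e1)), 0.0, atol=1e-12)

    def test_echo_order_validated(self, phantom2d):
        with pytest.raises(ValueError):
            bm.simulate_gre_pair(phantom2d, np.zeros((64, 64)), 0.007, 0.005)


class TestPerfusionSeries:
    def test_noiseless_fraction_recovered(self, phantom2d):
        gm = np.abs(phantom2d) > 0.5
        s = bm.simulate_perfusion_series(phantom2d, gm, perfusion_fraction=0.02,
                                         noise_sd=0.0, n_pairs=4, seed=0)
        ratio = s.delta_m()[gm] / s.m0_mean()[gm]
        assert np.allclose(ratio, 0.02, atol=1e-12)
        assert s.n_pairs == 4

    def test_default_pair_count_is_34(self, phantom2d):
        gm = np.abs(phantom2d) > 0.5
        s = bm.simulate_perfusion_series(phantom2d, gm, seed=0)
        assert s.n_pairs == 34 and s.m0.shape[0] == 15

    def test_zero_fraction_means_no_signal(self, phantom2d):
        gm = np.abs(phantom2d) > 0.5
        s = bm.simulate_perfusion_series(phantom2d, gm, perfusion_fraction=0.0,
                                         noise_sd=0.01, n_pairs=40, seed=1)
        assert abs(s.delta_m()[gm].mean()) < 0.005

    def test_empty_gm_rejected(self, phantom2d):
        with pytest.raises(ValueError):
            bm.simulate_perfusion_series(phantom2d, np.zeros((64, 64), bool))
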