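"""Evaluation metrics: CBF quantification, Dice, Hausdorff, perfusion SNR and
temporal SNR, field-map correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import blipmap as bm
from blipmap.metrics import CBFParams, center_slices


class TestCbf:
    def test_zero_delta_m(self):
        out = bm.cbf_map(np.zeros((8, 8)), np.ones((8, 8)))
        assert np.all(out == 0)

    def test_default_constants(self):
        p = CBFParams()
        assert (p.t1_blood, p.alpha, p.lam, p.pld, p.tau) == (1.65, 0.68, 0.9, 1.5, 1.8)

    def test_matches_term_by_term_arithmetic(self):
        p = CBFParams()
        out = bm.cbf_map(np.full((2, 2), 0.01), np.ones((2, 2)), p)
        # independent high-precision evaluation of the quantification formula
        num = 6000.0 * 0.9 * np.exp(1.5 / 1.65)
        den = 2.0 * 0.68 * 1.65 * (1.0 - np.exp(-1.8 / 1.65))
        expect = 0.01 * num / den
        assert np.allclose(out, expect, rtol=1e-12)

    def test_linear_in_delta_m_and_inverse_in_m0(self):
        rng = np.random.default_rng(0)
        dm = rng.random((6, 6))
        m0 = 1.0 + rng.random((6, 6))
        base = bm.cbf_map(dm, m0)
        assert np.allclose(bm.cbf_map(3 * dm, m0), 3 * base, rtol=1e-12)
        assert np.allclose(bm.cbf_map(dm, 2 * m0), base / 2, rtol=1e-12)

    def test_nonpositive_m0_flagged_zero(self):
        dm = np.ones((2, 2))
        m0 = np.array([[1.0, 0.0], [-1.0, 2.0]])
        out = bm.cbf_map(dm, m0)
        assert out[0, 1] == 0 and out[1, 0] == 0 and out[0, 0] > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CBFParams(alpha=1.5)
        with pytest.raises(ValueError):
            CBFParams(t1_blood=-1)


class TestDice:
    def test_self_and_disjoint(self):
        a = np.zeros((8, 8), bool)
        a[2:5, 2:5] = True
        b = np.zeros((8, 8), bool)
        b[6:8, 6:8] = True
        assert bm.dice(a, a) == 1.0
        assert bm.dice(a, b) == 0.0

    def test_arithmetic_example(self):
        a = np.zeros(16, bool)
        b = np.zeros(16, bool)
        a[:6] = True          # |A| = 6
        b[3:7] = True         # |B| = 4, overlap = 3
        assert bm.dice(a, b) == pytest.approx(0.6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((10, 10)) > 0.5
        b = rng.random((10, 10)) > 0.5
        if not (a.any() or b.any()):
            return
        d = bm.dice(a, b)
        assert d == bm.dice(b, a)
        assert 0.0 <= d <= 1.0

    def test_both_empty_rejected(self):
        e = np.zeros((4, 4), bool)
        with pytest.raises(ValueError):
            bm.dice(e, e)


def brute_force_hausdorff(a, b):
    from blipmap.metrics import _boundary_points
    pa, pb = _boundary_points(a), _boundary_points(b)
    d_ab = max(min(np.linalg.norm(p - q) for q in pb) for p in pa)
    d_ba = max(min(np.linalg.norm(p - q) for q in pa) for p in pb)
    return max(d_ab, d_ba)


class TestHausdorff:
    def test_identical_masks(self):
        a = np.zeros((8, 8), bool)
        a[2:6, 2:6] = True
        assert bm.hausdorff(a, a) == 0.0

    def test_two_voxels_three_apart(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[2, 2] = True
        b[2, 5] = True
        assert bm.hausdorff(a, b) == pytest.approx(3.0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_matches_quadratic_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((12, 12)) > 0.6
        b = rng.random((12, 12)) > 0.6
        if not (a.any() and b.any()):
            return
        assert bm.hausdorff(a, b) == pytest.approx(brute_force_hausdorff(a, b))

    def test_translation_consistency(self):
        a = np.zeros((16, 16), bool)
        a[4:8, 4:8] = True
        b = np.roll(a, 3, axis=0)
        assert bm.hausdorff(a, b) == pytest.approx(3.0)

    def test_empty_mask_rejected(self):
        a = np.zeros((4, 4), bool)
        a[1, 1] = True
        with pytest.raises(ValueError):
            bm.hausdorff(a, np.zeros((4, 4), bool))


class TestPerfusionSnr:
    def test_linearity_in_perfusion_signal(self):
        """Doubling the gray-matter perfusion signal (background noise
        unchanged) doubles the SNR."""
        rng = np.random.default_rng(0)
        perf = rng.random((16, 16))
        gm = np.zeros((16, 16), bool)
        gm[4:8, 4:8] = True
        bg = np.zeros((16, 16), bool)
        bg[12:, 12:] = True
        snr = bm.perfusion_snr(perf, gm, bg)
        boosted = perf * (1 + gm)  # doubles GM only
        assert bm.perfusion_snr(boosted, gm, bg) == pytest.approx(2 * snr)

    def test_zero_variance_background_rejected(self):
        perf = np.ones((8, 8))
        gm = np.zeros((8, 8), bool)
        gm[1, 1] = True
        bg = np.zeros((8, 8), bool)
        bg[6:, 6:] = True
        with pytest.raises(ValueError):
            bm.perfusion_snr(perf, gm, bg)

    def test_matches_closed_form_expectation(self, phantom2d):
        gm = np.abs(phantom2d) > 0.5
        frac, sd, n = 0.02, 0.01, 34
        snrs = []
        for seed in range(8):
            s = bm.simulate_perfusion_series(phantom2d, gm, frac, sd, n, seed=seed)
            perf = s.delta_m()
            snrs.append(bm.perfusion_snr(perf, s.gm_mask, s.bg_mask))
        expect = (frac * np.abs(phantom2d)[gm].mean()) / (sd * np.sqrt(2.0 / n))
        assert np.mean(snrs) == pytest.approx(expect, rel=0.1)


class TestPerfusionTsnr:
    def test_identical_frames_rejected(self):
        series = np.ones((5, 8, 8))
        gm = np.zeros((8, 8), bool)
        gm[2, 2] = True
        with pytest.raises(ValueError):
            bm.perfusion_tsnr(series, gm)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            bm.perfusion_tsnr(np.random.default_rng(0).random((2, 4, 4)),
                              np.ones((4, 4), bool))

    def test_single_voxel_equals_scalar_ratio(self):
        rng = np.random.default_rng(1)
        series = rng.random((20, 4, 4))
        gm = np.zeros((4, 4), bool)
        gm[1, 2] = True
        ts = series[:, 1, 2]
        expect = ts.mean() / ts.std(ddof=1)
        assert bm.perfusion_tsnr(series, gm) == pytest.approx(expect)

    def test_doubling_noise_roughly_halves_tsnr(self, phantom2d):
        gm = np.abs(phantom2d) > 0.5
        vals = []
        for sd in (0.01, 0.02):
            per_seed = [
                bm.perfusion_tsnr(
                    bm.simulate_perfusion_series(phantom2d, gm, 0.02, sd,
                                                 n_pairs=30, seed=s), gm)
                for s in range(4)]
            vals.append(np.mean(per_seed))
        assert vals[0] / vals[1] == pytest.approx(2.0, rel=0.15)


class TestFieldmapCorrelation:
    def test_perfect_and_inverted(self, field2d):
        roi = np.abs(field2d.values) > 1.0
        assert bm.fieldmap_correlation(field2d, field2d, roi) == pytest.approx(1.0)
        neg = bm.FieldMap(-field2d.values)
        assert bm.fieldmap_correlation(field2d, neg, roi) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((16, 16)), rng.random((16, 16))
        roi = np.ones((16, 16), bool)
        x, y = a[roi], b[roi]
        expect = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert bm.fieldmap_correlation(a, b, roi) == pytest.approx(expect)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        roi = np.ones((8, 8), bool)
        r = bm.fieldmap_correlation(a, b, roi)
        assert bm.fieldmap_correlation(3 * a + 5, b, roi) == pytest.approx(r)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            bm.fieldmap_correlation(np.ones((4, 4)), np.ones((4, 4)),
                                    np.zeros((4, 4), bool))


def test_center_slices_selection():
    assert center_slices(8, 5) == slice(1, 6)
    assert center_slices(3, 5) == slice(0, 3)
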