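import numpy as np
import pytest

import blipmap as bm


@pytest.fixture(scope="session")
def params2d():
    return bm.AcquisitionParams(matrix_shape=(64, 64))


@pytest.fixture(scope="session")
def phantom2d():
    return bm.make_phantom((64, 64), seed=1)


@pytest.fixture(scope="session")
def field2d():
    return bm.make_field_map((64, 64), amplitude_hz=80.0, smoothness=10.0, seed=7)


def in_object(phantom):
    """Evaluation mask: voxels with appreciable signal."""
    mag = np.abs(phantom)
    return mag > 0.1 * mag.max()


@pytest.fixture(scope="session")
def recovery_suite(params2d):
    """Ten seeded phantom/field cases pushed through the full single-k-space
    pipeline; shared across the acceptance-style checks."""
    from blipmap.core import ifft_centered

    cases = []
    for seed in range(10):
        phantom = bm.make_phantom((64, 64), seed=seed)
        truth = bm.make_field_map((64, 64), 80.0, 10.0, seed=seed + 1000)
        k = bm.simulate_cenepi_kspace(phantom, truth, params2d)
        fmap, mask_up, mask_dn = bm.estimate_field_single_kspace(k)
        corrected = bm.correct_cenepi(k, fmap, use_lsr=True)
        distorted = ifft_centered(k.data)
        cases.append(dict(seed=seed, phantom=phantom, truth=truth, k=k,
                          fmap=fmap, corrected=corrected, distorted=distorted))
    return cases
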