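"""Synthetic phantoms, B0 fields and distorted EPI / GRE / ASL data.

The generators emulate the structure the estimation pipeline relies on: a
compact bright brain-like object on a zero background, a smooth off-resonance
field of a few tens of Hz, blip-polarity-dependent geometric displacement
along the PE axis, centric k-space assembly with partial Fourier, a
double-echo gradient-echo pair, and a toy label/control perfusion series.
Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import (
    AcquisitionParams,
    FieldMap,
    KSpace,
    PerfusionSeries,
    as_field_values,
    fft_centered,
)

__all__ = [
    "make_phantom",
    "make_field_map",
    "distort_image",
    "simulate_cenepi_kspace",
    "simulate_gre_pair",
    "simulate_perfusion_series",
]


def _inplane_grids(shape):
    """Normalized [-1, 1] coordinates for the two in-plane axes."""
    nx, ny = shape[0], shape[1]
    x = np.linspace(-1, 1, nx)
    y = np.linspace(-1, 1, ny)
    return np.meshgrid(x, y, indexing="ij")


def make_phantom(shape: Tuple[int, ...], seed: int = 0) -> np.ndarray:
    """Brain-like complex phantom: overlapping ellipses with internal texture,
    a smooth receive-bias-like intensity modulation and smooth low-order
    phase, on an exactly zero background.

    ``shape`` is (readout, PE) or (readout, PE, partition); in-plane axes must
    be >= 32 voxels.  The object stays inside ~70% of the in-plane FOV so the
    background (signal exactly zero) covers the FOV edge.
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) not in (2, 3):
        raise ValueError("phantom shape must be 2-D or 3-D")
    if any(n < 8 for n in shape):
        raise ValueError(f"degenerate shape {shape}: every axis needs >= 8 voxels")
    if shape[0] < 32 or shape[1] < 32:
        raise ValueError("in-plane axes must be >= 32 voxels")

    rng = np.random.default_rng(seed)
    X, Y = _inplane_grids(shape)
    nz = shape[2] if len(shape) == 3 else 1

    # outer "skull" ellipse, slightly randomized, always inside |r| < 0.72
    a0 = 0.58 + 0.06 * rng.uniform(-1, 1)
    b0 = 0.66 + 0.05 * rng.uniform(-1, 1)
    tilt = 0.15 * rng.uniform(-1, 1)
    Xr = X * np.cos(tilt) + Y * np.sin(tilt)
    Yr = -X * np.sin(tilt) + Y * np.cos(tilt)

    # internal structures: a few overlapping ellipses with distinct levels
    n_sub = 4
    subs = []
    for _ in range(n_sub):
        cx, cy = rng.uniform(-0.3, 0.3, size=2)
        sa, sb = rng.uniform(0.12, 0.35, size=2)
        th = rng.uniform(0, np.pi)
        level = rng.uniform(-0.35, 0.45)
        subs.append((cx, cy, sa, sb, th, level))
    # ventricle-like dark ellipse near the middle
    vent = (rng.uniform(-0.08, 0.08), rng.uniform(-0.08, 0.08),
            rng.uniform(0.08, 0.14), rng.uniform(0.16, 0.24), rng.uniform(0, np.pi))

    # fine texture shared across slices, smoothly varying
    texture = ndimage.gaussian_filter(rng.standard_normal(shape[:2]), 1.5)
    texture /= max(np.abs(texture).max(), 1e-12)
    # smooth multiplicative bias (receive-coil-like)
    bx, by = rng.uniform(-1, 1, size=2)
    bias = 1.0 + 0.25 * (bx * X + by * Y) + 0.15 * (X * Y) * rng.uniform(-1, 1)

    # smooth low-order phase (rad)
    p = rng.uniform(-1, 1, size=5)
    phase = 0.04 * (p[0] + p[1] * X + p[2] * Y + 0.5 * (p[3] * X**2 + p[4] * Y**2))

    vol = np.zeros(shape, dtype=complex)
    zc = (nz - 1) / 2.0
    for iz in range(nz):
        # ellipsoid-like shrink of the outer boundary toward edge slices
        if nz > 1:
            frac = 1.0 - ((iz - zc) / (0.75 * nz)) ** 2
            frac = max(frac, 0.35)
        else:
            frac = 1.0
        outer = (Xr / (a0 * frac)) ** 2 + (Yr / (b0 * frac)) ** 2 <= 1.0
        mag = np.where(outer, 1.0, 0.0)
        for cx, cy, sa, sb, th, level in subs:
            Xs = (X - cx) * np.cos(th) + (Y - cy) * np.sin(th)
            Ys = -(X - cx) * np.sin(th) + (Y - cy) * np.cos(th)
            inside = (Xs / sa) ** 2 + (Ys / sb) ** 2 <= 1.0
            mag = np.where(inside & outer, mag + level, mag)
        cx, cy, sa, sb, th = vent
        Xs = (X - cx) * np.cos(th) + (Y - cy) * np.sin(th)
        Ys = -(X - cx) * np.sin(th) + (Y - cy) * np.cos(th)
        inside = (Xs / sa) ** 2 + (Ys / sb) ** 2 <= 1.0
        mag = np.where(inside & outer, 0.25, mag)
        mag = np.clip(mag, 0.0, None)
        mag = mag * (1.0 + 0.12 * texture) * bias
        mag = np.clip(mag, 0.0, None) * outer
        # soften edges toward a band-limited object; background stays exactly 0
        mag = ndimage.gaussian_filter(mag, 1.0)
        mag *= ndimage.gaussian_filter(outer.astype(float), 1.0) > 0.02
        sl = mag * np.exp(1j * phase)
        if nz > 1:
            vol[:, :, iz] = sl
        else:
            vol = sl
    return vol


def make_field_map(
    shape: Tuple[int, ...],
    amplitude_hz: float = 50.0,
    smoothness: float = 8.0,
    seed: int = 0,
    n_bumps: int = 4,
) -> FieldMap:
    """Smooth synthetic off-resonance field: a sum of random Gaussian bumps.

    ``max |f| <= amplitude_hz`` by construction and the per-voxel finite
    difference gradient is bounded by ``amplitude_hz / smoothness``
    (``smoothness`` is the minimum bump width in voxels).
    """
    shape = tuple(int(n) for n in shape)
    if amplitude_hz < 0:
        raise ValueError("amplitude_hz must be >= 0")
    if amplitude_hz == 0:
        return FieldMap(np.zeros(shape), provenance="truth")
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    f = np.zeros(shape)
    for _ in range(n_bumps):
        center = [rng.uniform(0.2 * n, 0.8 * n) for n in shape]
        widths = [rng.uniform(smoothness, 2.5 * smoothness) for _ in shape]
        amp = rng.uniform(0.4, 1.0) * rng.choice([-1.0, 1.0])
        r2 = sum(((g - c) / w) ** 2 for g, c, w in zip(grids, center, widths))
        f += amp * np.exp(-0.5 * r2)
    peak = np.abs(f).max()
    if peak > 0:
        f *= amplitude_hz / peak
    # enforce the gradient bound (the width floor nearly guarantees it)
    bound = amplitude_hz / smoothness
    for _ in range(20):
        grad = max(np.abs(np.diff(f, axis=ax)).max() for ax in range(f.ndim))
        if grad <= bound:
            break
        f = ndimage.gaussian_filter(f, 1.0)
        peak = np.abs(f).max()
        if peak > 0:
            f *= amplitude_hz / peak
    return FieldMap(f, provenance="truth")


def _pe_sample(img: np.ndarray, shift: np.ndarray, pe_axis: int, order: int,
               cval: float = 0.0) -> np.ndarray:
    """Resample ``img`` along the PE axis at positions ``y + shift`` (voxels)."""
    coords = list(np.meshgrid(*[np.arange(n, dtype=float) for n in img.shape], indexing="ij"))
    coords[pe_axis] = coords[pe_axis] + shift
    coords = np.stack(coords)
    if np.iscomplexobj(img):
        re = ndimage.map_coordinates(img.real, coords, order=order, cval=cval, mode="constant")
        im = ndimage.map_coordinates(img.imag, coords, order=order, cval=cval, mode="constant")
        return re + 1j * im
    return ndimage.map_coordinates(img, coords, order=order, cval=cval, mode="constant")


def distort_image(
    img: np.ndarray,
    field,
    polarity: int,
    params: AcquisitionParams,
    modulate_jacobian: bool = True,
) -> np.ndarray:
    """Geometrically distort an image along the PE axis.

    The off-resonance displacement is ``d = field * total_readout_time``
    voxels; the distorted image is the pull-back
    ``out(y) = img(y - polarity * d(y))`` with linear interpolation and zeros
    outside the FOV.  With ``modulate_jacobian`` the result is multiplied by
    ``1 - polarity * dd/dy`` so the integrated signal along each PE line is
    conserved (compression brightens, stretching dims).
    """
    if polarity not in (+1, -1):
        raise ValueError("polarity must be +1 or -1")
    values = as_field_values(field)
    if values.shape != img.shape:
        raise ValueError("field and image grids differ")
    d = values * params.total_readout_time
    if np.abs(d).max() >= params.n_pe:
        raise ValueError("displacement exceeds the PE matrix extent; "
                         "field / total_readout_time inconsistent")
    out = _pe_sample(img, -polarity * d, params.pe_axis, order=1)
    if modulate_jacobian:
        ddy = np.gradient(d, axis=params.pe_axis)
        out = out * (1.0 - polarity * ddy)
    return out


def simulate_cenepi_kspace(
    img: np.ndarray,
    field,
    params: AcquisitionParams,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> KSpace:
    """Assemble a centric-ordered EPI k-space from an undistorted object.

    The PE lines at and above the center line come from the Fourier transform
    of the blip-up (+1) distorted image, the acquired lines below the center
    from the blip-down (-1) transform; lines outside the partial-Fourier
    extent are zero and flagged unacquired.  Optional complex Gaussian noise
    is added to the acquired samples.
    """
    if not params.is_centric:
        raise ValueError("simulate_cenepi_kspace requires a centric trajectory")
    if img.shape != params.matrix_shape:
        raise ValueError("image shape does not match matrix_shape")
    k_up = fft_centered(distort_image(img, field, +1, params))
    k_dn = fft_centered(distort_image(img, field, -1, params))
    c = params.center_line
    mask = params.acquired_lines()
    lines = np.arange(params.n_pe)
    data = np.zeros(params.matrix_shape, dtype=complex)
    sel_up = lines >= c
    sel_dn = mask & (lines < c)
    idx = [slice(None)] * img.ndim
    idx[params.pe_axis] = sel_up
    data[tuple(idx)] = k_up[tuple(idx)]
    idx[params.pe_axis] = sel_dn
    data[tuple(idx)] = k_dn[tuple(idx)]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = noise_sd * (rng.standard_normal(data.shape)
                            + 1j * rng.standard_normal(data.shape))
        idx[params.pe_axis] = mask
        data[tuple(idx)] += noise[tuple(idx)]
    return KSpace(data=data, acquired_mask=mask, params=params)


def simulate_gre_pair(
    img: np.ndarray, field, te1_s: float, te2_s: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Double-echo gradient-echo pair: identical magnitude, no geometric
    distortion, per-voxel phase difference ``2*pi*f*(te2 - te1)``."""
    if te2_s <= te1_s:
        raise ValueError("te2 must exceed te1")
    values = as_field_values(field)
    mag = np.abs(img)
    phase0 = np.angle(img) if np.iscomplexobj(img) else np.zeros_like(mag)
    e1 = mag * np.exp(1j * (phase0 + 2 * np.pi * values * te1_s))
    e2 = mag * np.exp(1j * (phase0 + 2 * np.pi * values * te2_s))
    return e1, e2


def simulate_perfusion_series(
    img: np.ndarray,
    gm_mask: np.ndarray,
    perfusion_fraction: float = 0.006,
    noise_sd: float = 0.01,
    n_pairs: int = 34,
    n_m0: int = 15,
    seed: int = 0,
) -> PerfusionSeries:
    """Toy pCASL label/control series.

    Control volumes are the magnitude image plus Gaussian noise; label volumes
    lose ``perfusion_fraction`` of the signal inside the gray-matter mask.
    Defaults mirror a typical perfusion protocol: 34 label/control pairs and
    15 magnetization-transfer-free M0 measurements.
    """
    if not 0 <= perfusion_fraction < 1:
        raise ValueError("perfusion_fraction must lie in [0, 1)")
    gm_mask = np.asarray(gm_mask, dtype=bool)
    if not gm_mask.any():
        raise ValueError("gray-matter mask is empty")
    rng = np.random.default_rng(seed)
    mag = np.abs(img)
    control = mag[None] + noise_sd * rng.standard_normal((n_pairs,) + mag.shape)
    label = (mag - perfusion_fraction * mag * gm_mask)[None] \
        + noise_sd * rng.standard_normal((n_pairs,) + mag.shape)
    m0 = mag[None] + noise_sd * rng.standard_normal((n_m0,) + mag.shape)
    brain = mag > 0
    bg_mask = ~ndimage.binary_dilation(brain, iterations=3)
    return PerfusionSeries(control=control, label=label, m0=m0,
                           gm_mask=gm_mask, bg_mask=bg_mask)
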