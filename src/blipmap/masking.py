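"""Automatic brain masking and intensity-uniformity correction.

The blip-up surrogate image is masked by Otsu thresholding; the blip-down
mask is derived from it either by dilation with a triangular structuring
element (first pass, no field information yet) or by warping the blip-up mask
twice along the PE axis with the current field estimate (later passes, since
the two images are displaced in opposite directions).  Uniformity correction
divides an image by its lowpass-filtered version, where the background is
replaced by the image maximum before smoothing so background noise is not
amplified; the Gaussian width is either a constant sigma = 8 or a
location-dependent map rising linearly from 0.5 at the mask's center of mass
to 8 at the boundary.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import AcquisitionParams, as_field_values

__all__ = [
    "otsu_threshold",
    "otsu_mask",
    "triangular_footprint",
    "dilate_mask",
    "warp_mask",
    "sigma_field",
    "lowpass_image",
    "uniformity_correct",
    "SIGMA_BANK",
    "SIGMA_MIN",
    "SIGMA_MAX",
]

SIGMA_MIN = 0.5
SIGMA_MAX = 8.0
#: constant-sigma bank used to realize spatially varying Gaussian smoothing
SIGMA_BANK = (0.5, 1.0, 2.0, 4.0, 8.0)


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: maximizes between-class variance over a histogram.

    Returns the bin boundary (upper edge of the last background bin); voxels
    strictly above it are foreground.  Raises on a constant image.
    """
    values = np.asarray(values, dtype=float).ravel()
    lo, hi = values.min(), values.max()
    if not np.isfinite(lo) or not np.isfinite(hi) or lo == hi:
        raise ValueError("degenerate histogram: image has no intensity contrast")
    hist, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(hist).astype(float)
    w1 = w0[-1] - w0
    s0 = np.cumsum(hist * centers)
    mu0 = np.where(w0 > 0, s0 / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (s0[-1] - s0) / np.maximum(w1, 1), 0.0)
    var_between = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(var_between[:-1]))  # last split leaves class 1 empty
    return float(edges[k + 1])


def otsu_mask(img: np.ndarray) -> np.ndarray:
    """Brain mask: Otsu threshold on the magnitude image, then keep the
    largest connected component and fill holes."""
    mag = np.abs(img)
    t = otsu_threshold(mag)
    mask = mag > t
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("Otsu mask is empty")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def triangular_footprint(radius: int, ndim: int = 2) -> np.ndarray:
    """In-plane triangular structuring element of the given radius.

    Rows ``-radius..0`` along the PE axis, widening away from the apex at the
    origin; radius 1 gives the origin plus 3 offsets.  For 3-D inputs the
    element occupies a single partition plane (dilation acts in-plane).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    size = 2 * radius + 1
    foot = np.zeros((size, size), dtype=bool)
    for j in range(-radius, 1):          # PE offsets, apex at 0
        half = -j
        foot[radius - half:radius + half + 1, radius + j] = True
    if ndim == 3:
        foot3 = np.zeros((size, size, 1), dtype=bool)
        foot3[:, :, 0] = foot
        return foot3
    return foot


def dilate_mask(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Morphological dilation with the triangular structuring element."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot dilate an empty mask")
    if radius == 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=triangular_footprint(radius, mask.ndim))


def warp_mask(mask: np.ndarray, field, factor: float, params: AcquisitionParams) -> np.ndarray:
    """Resample a mask along PE by displacement ``-factor * field * trt``
    (nearest neighbour, re-binarized).  ``factor = 2`` maps a blip-up mask
    onto blip-down geometry, since the two are displaced by +d and -d."""
    mask = np.asarray(mask, dtype=bool)
    d = as_field_values(field) * params.total_readout_time
    if d.shape != mask.shape:
        raise ValueError("field and mask grids differ")
    coords = list(np.meshgrid(*[np.arange(n, dtype=float) for n in mask.shape], indexing="ij"))
    coords[params.pe_axis] = coords[params.pe_axis] + factor * d
    out = ndimage.map_coordinates(mask.astype(np.float32), np.stack(coords),
                                  order=0, cval=0.0, mode="constant")
    return out > 0.5


def _sigma_slice(mask2d: np.ndarray, n_angles: int = 720, radial_step: float = 0.25) -> np.ndarray:
    """Location-dependent sigma for one in-plane mask slice."""
    out = np.full(mask2d.shape, SIGMA_MAX, dtype=float)
    if not mask2d.any():
        return out
    com = ndimage.center_of_mass(mask2d)
    angles = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    r_max = float(np.hypot(*mask2d.shape))
    radii = np.arange(0.0, r_max, radial_step)
    iy = np.rint(com[0] + radii[None, :] * np.cos(angles)[:, None]).astype(int)
    ix = np.rint(com[1] + radii[None, :] * np.sin(angles)[:, None]).astype(int)
    inb = (iy >= 0) & (iy < mask2d.shape[0]) & (ix >= 0) & (ix < mask2d.shape[1])
    inside = np.zeros(iy.shape, dtype=bool)
    inside[inb] = mask2d[iy[inb], ix[inb]]
    first_out = np.argmin(inside, axis=1)          # first False along each ray
    all_in = inside.all(axis=1)
    boundary_r = np.where(all_in, radii[-1], radii[np.maximum(first_out - 1, 0)])
    boundary_r = np.maximum(boundary_r, radial_step)

    ys, xs = np.nonzero(mask2d)
    dy, dx = ys - com[0], xs - com[1]
    r = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dx, dy), 2 * np.pi)
    ang_idx = np.rint(theta / (2 * np.pi / n_angles)).astype(int) % n_angles
    t = np.clip(r / boundary_r[ang_idx], 0.0, 1.0)
    out[ys, xs] = SIGMA_MIN + (SIGMA_MAX - SIGMA_MIN) * t
    return out


def sigma_field(mask: np.ndarray, mode: str = "location_dependent") -> np.ndarray:
    """Per-voxel Gaussian smoothing width for uniformity correction.

    ``constant`` mode returns sigma = 8 everywhere.  ``location_dependent``
    mode assigns 0.5 at the in-plane center of mass of the mask and 8 at the
    mask boundary, linearly increasing with relative radial distance along
    the ray from the center of mass; outside the mask sigma = 8.  3-D masks
    are processed slice-by-slice along the partition axis.
    """
    mask = np.asarray(mask, dtype=bool)
    if mode == "constant":
        return np.full(mask.shape, SIGMA_MAX, dtype=float)
    if mode != "location_dependent":
        raise ValueError(f"unknown sigma mode {mode!r}")
    if not mask.any():
        raise ValueError("sigma_field needs a nonempty mask")
    if mask.ndim == 2:
        return _sigma_slice(mask)
    out = np.empty(mask.shape, dtype=float)
    for iz in range(mask.shape[2]):
        out[:, :, iz] = _sigma_slice(mask[:, :, iz])
    return out


def _gauss_inplane(img: np.ndarray, sigma: float) -> np.ndarray:
    s = [sigma, sigma] + [0.0] * (img.ndim - 2)
    return ndimage.gaussian_filter(img, sigma=s, mode="nearest")


def lowpass_image(img: np.ndarray, mask: np.ndarray, sigma) -> np.ndarray:
    """Lowpass (bias) image: the magnitude image with its background replaced
    by the image maximum, smoothed with a per-voxel Gaussian width.

    Spatially varying smoothing is realized by linear interpolation between a
    bank of constant-sigma filtered images (sigma in ``SIGMA_BANK``); a
    constant sigma map reduces exactly to a single Gaussian convolution.
    """
    mag = np.abs(img)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("lowpass_image needs a nonempty mask")
    peak = mag.max()
    if peak <= 0:
        raise ValueError("image has no signal")
    target = np.where(mask, mag, peak)
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim == 0 or np.all(sigma == sigma.flat[0]):
        return _gauss_inplane(target, float(np.clip(sigma.flat[0] if sigma.ndim else sigma, SIGMA_MIN, SIGMA_MAX)))
    if sigma.shape != mag.shape:
        raise ValueError("sigma map and image grids differ")
    s = np.clip(sigma, SIGMA_MIN, SIGMA_MAX)
    bank = np.array(SIGMA_BANK)
    filtered = np.stack([_gauss_inplane(target, b) for b in bank])
    hi = np.searchsorted(bank, s, side="left")
    hi = np.clip(hi, 1, len(bank) - 1)
    lo = hi - 1
    w = (s - bank[lo]) / (bank[hi] - bank[lo])
    flat_idx = np.arange(s.size)
    f_lo = filtered.reshape(len(bank), -1)[lo.ravel(), flat_idx].reshape(s.shape)
    f_hi = filtered.reshape(len(bank), -1)[hi.ravel(), flat_idx].reshape(s.shape)
    return (1 - w) * f_lo + w * f_hi


def uniformity_correct(img: np.ndarray, mask: np.ndarray, sigma) -> np.ndarray:
    """Divide the magnitude image by its lowpass-filtered version.

    Used only to equalize the two surrogate inputs of the field estimation;
    corrected EPI images never pass through this operation.
    """
    mag = np.abs(img)
    lp = lowpass_image(img, mask, sigma)
    floor = 1e-6 * lp.max()
    if floor <= 0:
        raise ValueError("lowpass image vanished; division guard triggered")
    return mag / np.maximum(lp, floor)
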