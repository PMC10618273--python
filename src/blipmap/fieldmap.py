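"""B0 field estimation.

Three estimators live here:

* :func:`estimate_field_topup` — a self-contained reversed-polarity
  registration engine in the spirit of FSL's ``topup``: find the smooth PE
  displacement field whose opposite warps bring the blip-up and blip-down
  images into agreement, by multi-resolution Gauss-Newton with a
  bending-energy penalty.
* :func:`estimate_field_single_kspace` — the single-k-space procedure: split
  the centric k-space, complete both halves with POCS, then iterate
  automatic brain masking and uniformity correction around the registration
  engine (three passes by default; constant smoothing width except for a
  location-dependent width on the final pass).
* :func:`gre_fieldmap` — the double-echo gradient-echo reference: phase
  difference divided by ``2*pi*dTE``, exact in the wrap-free regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .core import AcquisitionParams, FieldMap, KSpace
from .kspace import pocs_reconstruct, split_for_estimation
from .masking import dilate_mask, otsu_mask, sigma_field, uniformity_correct, warp_mask

__all__ = [
    "TopupOptions",
    "IterativeOptions",
    "estimate_field_topup",
    "estimate_field_single_kspace",
    "gre_fieldmap",
]


@dataclass(frozen=True)
class TopupOptions:
    """Settings of the reversed-polarity registration engine.

    ``levels`` is the coarse-to-fine pyramid as (Gaussian sigma in voxels,
    subsampling factor) pairs.  ``lam`` weights the bending energy
    ``||laplacian(d)||^2`` of the displacement field against the (intensity-
    normalized) image mismatch; it is scale-free because the inputs are
    normalized internally.  Estimation is fully deterministic (d0 = 0).
    """

    levels: Tuple[Tuple[float, int], ...] = ((4.0, 4), (2.0, 2), (1.0, 1))
    lam: float = 2.0
    max_iter: int = 10
    tol: float = 1e-4
    jacobian_modulation: bool = True
    damping: float = 1e-3
    #: exponent of the signal-confidence weight on the residuals; 0 disables.
    #: low-signal voxels carry reconstruction ringing rather than anatomy, so
    #: their mismatch should not drive the displacement estimate.
    weight_gamma: float = 0.5


@dataclass(frozen=True)
class IterativeOptions:
    """Schedule of the single-k-space iterative procedure, with the ablation
    switches of the step-by-step study.

    The full procedure runs ``n_iterations`` masking/uniformity/registration
    passes: pass 1 derives the blip-down mask by triangular dilation of the
    blip-up Otsu mask, later passes warp the blip-up mask twice with the
    current field; the smoothing width is constant (sigma = 8) on all but the
    last pass, which uses the location-dependent width map.
    """

    n_iterations: int = 3
    uniformity_correction: bool = True
    iterative_masking: bool = True
    location_dependent_final: bool = True
    use_lsr: bool = True
    dilation_radius: int = 2
    pocs_iterations: int = 30

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    @classmethod
    def from_variant(cls, name: str) -> "IterativeOptions":
        """Ablation variants, each adding one proposed step."""
        variants = {
            "pocs_only": cls(uniformity_correction=False, iterative_masking=False,
                             location_dependent_final=False, use_lsr=False),
            "uc_by_dilation_masking": cls(iterative_masking=False,
                                          location_dependent_final=False, use_lsr=False),
            "uc_by_iterative_masking": cls(location_dependent_final=False, use_lsr=False),
            "location_dependent_uc": cls(use_lsr=False),
            "lsr": cls(),
        }
        if name not in variants:
            raise ValueError(f"unknown variant {name!r}; choose from {sorted(variants)}")
        return variants[name]

    @property
    def effective_iterations(self) -> int:
        return self.n_iterations if self.iterative_masking else 1


# ---------------------------------------------------------------------------
# registration engine
# ---------------------------------------------------------------------------

_LTL_CACHE: dict = {}


def _bending_operator(shape: Tuple[int, int]) -> sparse.csr_matrix:
    """Squared 2-D Laplacian (bending energy) on a C-ordered grid."""
    if shape in _LTL_CACHE:
        return _LTL_CACHE[shape]
    nx, ny = shape

    def lap1d(n):
        d = sparse.diags([1.0, -2.0, 1.0], [-1, 0, 1], shape=(n, n), format="lil")
        d[0, 0] = d[-1, -1] = -1.0  # Neumann boundary
        return d.tocsr()

    L = sparse.kron(lap1d(nx), sparse.eye(ny)) + sparse.kron(sparse.eye(nx), lap1d(ny))
    ltl = (L.T @ L).tocsc()
    _LTL_CACHE[shape] = ltl
    return ltl


def _warp_pe_2d(img: np.ndarray, e: np.ndarray, sign: float) -> np.ndarray:
    """Sample ``img`` at (x, y + sign * e(x, y)), linear, zeros outside."""
    nx, ny = img.shape
    gx, gy = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float),
                         indexing="ij")
    return ndimage.map_coordinates(img, np.stack([gx, gy + sign * e]),
                                   order=1, cval=0.0, mode="constant")


def _level_objective(u, v, e, lam, ltl, jac_mod, w):
    ey = np.gradient(e, axis=1)
    wu = _warp_pe_2d(u, e, +1.0)
    wv = _warp_pe_2d(v, e, -1.0)
    if jac_mod:
        wu = wu * (1.0 + ey)
        wv = wv * (1.0 - ey)
    r = w * (wu - wv)
    le = ltl @ e.ravel()
    return r, float(np.vdot(r, r).real + lam * float(e.ravel() @ le))


def _solve_level(u, v, e, opts: TopupOptions, lam: float):
    """Gauss-Newton at one pyramid level.  Returns (e, objective history)."""
    ltl = _bending_operator(u.shape)
    du = np.gradient(u, axis=1)
    dv = np.gradient(v, axis=1)
    if opts.weight_gamma > 0:
        w = ndimage.gaussian_filter(np.maximum(u, v), 2.0, mode="nearest")
        w = np.clip(w / max(w.max(), 1e-12), 0.02, 1.0) ** opts.weight_gamma
    else:
        w = np.ones_like(u)
    r, obj = _level_objective(u, v, e, lam, ltl, opts.jacobian_modulation, w)
    history = [obj]
    for _ in range(opts.max_iter):
        ey = np.gradient(e, axis=1)
        gu = _warp_pe_2d(du, e, +1.0)
        gv = _warp_pe_2d(dv, e, -1.0)
        if opts.jacobian_modulation:
            gu = gu * (1.0 + ey)
            gv = gv * (1.0 - ey)
        J = (w * (gu + gv)).ravel()
        diag = J * J
        mu = opts.damping * max(diag.max(), 1e-12)
        A = sparse.diags(diag + mu) + lam * ltl
        b = -(J * r.ravel() + lam * (ltl @ e.ravel()))
        delta = spsolve(A.tocsc(), b).reshape(e.shape)
        accepted = False
        for alpha in (1.0, 0.5, 0.25, 0.125, 0.0625):
            e_try = e + alpha * delta
            r_try, obj_try = _level_objective(u, v, e_try, lam, ltl,
                                              opts.jacobian_modulation, w)
            if obj_try < obj:
                e, r, prev, obj = e_try, r_try, obj, obj_try
                history.append(obj)
                accepted = True
                break
        if not accepted:
            break
        if (prev - obj) <= opts.tol * max(history[0], 1e-30):
            break
    return e, history


def _upsample_to(e_coarse: np.ndarray, shape: Tuple[int, int], sub: int) -> np.ndarray:
    if e_coarse.shape == shape and sub == 1:
        return e_coarse
    gx, gy = np.meshgrid(np.arange(shape[0], dtype=float) / sub,
                         np.arange(shape[1], dtype=float) / sub, indexing="ij")
    return ndimage.map_coordinates(e_coarse, np.stack([gx, gy]),
                                   order=1, mode="nearest")


def _estimate_slice(u: np.ndarray, v: np.ndarray, opts: TopupOptions):
    """Displacement field (voxels, full resolution) for one 2-D slice pair."""
    e_full = np.zeros(u.shape)
    histories = []
    for sig, sub in opts.levels:
        us = ndimage.gaussian_filter(u, sig, mode="nearest")[::sub, ::sub]
        vs = ndimage.gaussian_filter(v, sig, mode="nearest")[::sub, ::sub]
        e = (ndimage.gaussian_filter(e_full, sig, mode="nearest") if sig > 0 else e_full)
        e = e[::sub, ::sub] / sub
        e, hist = _solve_level(us, vs, e, opts, opts.lam)
        histories.append(hist)
        e_full = _upsample_to(e, u.shape, sub) * sub
    return e_full, histories


def estimate_field_topup(
    img_up: np.ndarray,
    img_down: np.ndarray,
    params: AcquisitionParams,
    opts: Optional[TopupOptions] = None,
    return_info: bool = False,
):
    """Estimate the off-resonance field from two oppositely distorted
    magnitude images.

    Minimizes ``||W+(img_up, d) - W-(img_down, d)||^2 + lam * ||lap d||^2``
    over the PE displacement field d (voxels), where ``W+``/``W-`` warp by
    +d/-d (with optional Jacobian modulation), mapping both images toward
    undistorted space.  3-D volumes are processed slice-wise along the
    partition axis.  Returns the field in Hz (``d / total_readout_time``).
    """
    opts = opts or TopupOptions()
    up = np.asarray(img_up, dtype=float)
    dn = np.asarray(img_down, dtype=float)
    if up.shape != dn.shape:
        raise ValueError("image grids differ")
    if not (np.all(np.isfinite(up)) and np.all(np.isfinite(dn))):
        raise ValueError("non-finite input image")
    if params.pe_axis != 1:
        raise NotImplementedError("estimation assumes PE on axis 1")

    scale = max(np.percentile(up, 99), np.percentile(dn, 99), 1e-12)
    u, v = up / scale, dn / scale

    if u.ndim == 2:
        d, info = _estimate_slice(u, v, opts)
        infos = [info]
    elif u.ndim == 3:
        d = np.empty(u.shape)
        infos = []
        for iz in range(u.shape[2]):
            d[:, :, iz], info = _estimate_slice(u[:, :, iz], v[:, :, iz], opts)
            infos.append(info)
    else:
        raise ValueError("expected 2-D or 3-D images")

    fmap = FieldMap(d / params.total_readout_time, provenance="topup")
    if return_info:
        return fmap, {"objectives": infos}
    return fmap


# ---------------------------------------------------------------------------
# single-k-space iterative procedure
# ---------------------------------------------------------------------------

def estimate_field_single_kspace(
    k: KSpace,
    topup_opts: Optional[TopupOptions] = None,
    opts: Optional[IterativeOptions] = None,
    callback=None,
) -> Tuple[FieldMap, np.ndarray, np.ndarray]:
    """Estimate the B0 field from a single centric k-space.

    Pipeline: split with the center line shared -> POCS completion of both
    halves -> magnitude surrogate images -> iterative masking + uniformity
    correction wrapped around the reversed-polarity registration engine.
    Returns ``(field, mask_up, mask_down)``; ``callback(iteration, field)``
    if given is invoked after every registration pass.
    """
    opts = opts or IterativeOptions()
    params = k.params
    pair = split_for_estimation(k)
    up = np.abs(pocs_reconstruct(pair.k_up, n_iter=opts.pocs_iterations))
    dn = np.abs(pocs_reconstruct(pair.k_down, n_iter=opts.pocs_iterations))

    if not opts.uniformity_correction:
        fmap = estimate_field_topup(up, dn, params, topup_opts)
        fmap.provenance = "single_kspace"
        if callback is not None:
            callback(1, fmap)
        mask_up = otsu_mask(up)
        return fmap, mask_up, mask_up.copy()

    mask_up = otsu_mask(up)
    n_passes = opts.effective_iterations
    fmap: Optional[FieldMap] = None
    mask_dn = None
    for it in range(1, n_passes + 1):
        if it == 1 or fmap is None:
            mask_dn = dilate_mask(mask_up, radius=opts.dilation_radius)
        else:
            mask_dn = warp_mask(mask_up, fmap, 2.0, params)
            if not mask_dn.any():
                raise RuntimeError("blip-down mask collapsed to empty during iteration "
                                   f"{it}; field estimate is unusable")
        mode = ("location_dependent"
                if (opts.location_dependent_final and it == n_passes and n_passes > 1)
                else "constant")
        up_c = uniformity_correct(up, mask_up, sigma_field(mask_up, mode))
        dn_c = uniformity_correct(dn, mask_dn, sigma_field(mask_dn, mode))
        fmap = estimate_field_topup(up_c, dn_c, params, topup_opts)
        if callback is not None:
            callback(it, fmap)
    fmap.provenance = "single_kspace"
    return fmap, mask_up, mask_dn


# ---------------------------------------------------------------------------
# double-echo GRE reference
# ---------------------------------------------------------------------------

def gre_fieldmap(
    echo1: np.ndarray, echo2: np.ndarray, te1_s: float, te2_s: float
) -> FieldMap:
    """Reference field map from a double-echo gradient-echo pair.

    ``f = angle(echo2 * conj(echo1)) / (2 * pi * (te2 - te1))`` Hz.  Exact in
    the wrap-free regime ``|f| < 1 / (2 * dTE)``; no unwrapping is attempted,
    so faster off-resonance aliases.  Voxels with zero magnitude in either
    echo are flagged invalid (``valid`` mask) and set to 0 Hz.
    """
    if te2_s <= te1_s:
        raise ValueError("te2 must exceed te1")
    if echo1.shape != echo2.shape:
        raise ValueError("echo grids differ")
    dte = te2_s - te1_s
    valid = (np.abs(echo1) > 0) & (np.abs(echo2) > 0)
    f = np.angle(echo2 * np.conj(echo1)) / (2 * np.pi * dte)
    f = np.where(valid, f, 0.0)
    return FieldMap(f, provenance="gre", valid=valid)
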