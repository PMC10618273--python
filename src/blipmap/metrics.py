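"""Evaluation metrics: mask overlap (Dice, Hausdorff), perfusion SNR and
temporal SNR, field-map correlation, and CBF quantification for pCASL."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff
from scipy.stats import pearsonr

from .core import PerfusionSeries, as_field_values

__all__ = [
    "CBFParams",
    "cbf_map",
    "dice",
    "hausdorff",
    "perfusion_snr",
    "perfusion_tsnr",
    "fieldmap_correlation",
    "center_slices",
]


@dataclass(frozen=True)
class CBFParams:
    """pCASL quantification constants.

    Defaults: blood T1 1.65 s, labeling efficiency 0.68, brain-blood
    partition coefficient 0.9 ml/g, post-labeling delay 1.5 s, labeling
    duration 1.8 s.
    """

    t1_blood: float = 1.65
    alpha: float = 0.68
    lam: float = 0.9
    pld: float = 1.5
    tau: float = 1.8

    def __post_init__(self):
        if min(self.t1_blood, self.alpha, self.lam, self.pld, self.tau) <= 0:
            raise ValueError("all CBF parameters must be positive")
        if self.alpha > 1:
            raise ValueError("labeling efficiency cannot exceed 1")


def cbf_map(delta_m: np.ndarray, m0: np.ndarray, p: CBFParams = CBFParams()) -> np.ndarray:
    """Cerebral blood flow in ml/100 g/min.

    ``CBF = (dM / M0) * 6000 * lam * exp(PLD / T1b)
            / (2 * alpha * T1b * (1 - exp(-tau / T1b)))``

    Voxels with nonpositive M0 are invalid and set to 0.
    """
    delta_m = np.asarray(delta_m, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    valid = m0 > 0
    scale = (6000.0 * p.lam * np.exp(p.pld / p.t1_blood)
             / (2.0 * p.alpha * p.t1_blood * (1.0 - np.exp(-p.tau / p.t1_blood))))
    out = np.zeros_like(delta_m)
    out[valid] = delta_m[valid] / m0[valid] * scale
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|A ∩ B| / (|A| + |B|)``."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    total = a.sum() + b.sum()
    if total == 0:
        raise ValueError("both masks are empty")
    return float(2.0 * np.logical_and(a, b).sum() / total)


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels (erosion difference, face connectivity)."""
    interior = ndimage.binary_erosion(mask)
    return np.argwhere(mask & ~interior)


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance (voxels) between mask boundaries."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if not (a.any() and b.any()):
        raise ValueError("masks must be nonempty")
    pa = _boundary_points(a).astype(float)
    pb = _boundary_points(b).astype(float)
    return float(max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0]))


def perfusion_snr(perf: np.ndarray, gm: np.ndarray, bg: np.ndarray) -> float:
    """Mean gray-matter perfusion signal over background standard deviation."""
    gm = np.asarray(gm, dtype=bool)
    bg = np.asarray(bg, dtype=bool)
    if not (gm.any() and bg.any()):
        raise ValueError("masks must be nonempty")
    if np.any(gm & bg):
        raise ValueError("gray-matter and background masks overlap")
    sd = float(np.std(perf[bg]))
    if sd == 0:
        raise ValueError("background has zero variance; SNR undefined")
    return float(np.mean(perf[gm]) / sd)


def perfusion_tsnr(series, gm: np.ndarray) -> float:
    """Temporal SNR of the perfusion-weighted series, averaged over gray
    matter: mean over GM voxels of (temporal mean / temporal sd) of the
    per-pair control - label images."""
    if isinstance(series, PerfusionSeries):
        pw = series.perfusion_weighted()
    else:
        pw = np.asarray(series, dtype=float)
    if pw.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    gm = np.asarray(gm, dtype=bool)
    if not gm.any():
        raise ValueError("gray-matter mask is empty")
    tm = pw.mean(axis=0)[gm]
    ts = pw.std(axis=0, ddof=1)[gm]
    if np.any(ts == 0):
        raise ValueError("zero temporal standard deviation in gray matter")
    return float(np.mean(tm / ts))


def fieldmap_correlation(f1, f2, roi: np.ndarray) -> float:
    """Pearson correlation between two field maps over an ROI."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    x = as_field_values(f1)[roi]
    y = as_field_values(f2)[roi]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance inside the ROI")
    return float(pearsonr(x, y)[0])


def center_slices(n_slices: int, count: int = 5) -> slice:
    """Slice object selecting the centered ``count`` partitions (the
    evaluation region for Dice/Hausdorff/correlation)."""
    count = min(count, n_slices)
    lo = (n_slices - count) // 2
    return slice(lo, lo + count)
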