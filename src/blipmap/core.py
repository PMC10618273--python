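"""Core containers and k-space conventions.

Axis convention used throughout the package: axis 0 is the frequency-encode
(readout) axis, axis 1 is the phase-encode (PE) axis, axis 2 (when present) is
the partition/slice axis.  A positive off-resonance shifts blip-up images
toward +PE.  k-space arrays are stored *centered*: the DC sample sits at index
``N // 2`` along every axis, and the FFT helpers below apply the matching
shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "AcquisitionParams",
    "FieldMap",
    "KSpace",
    "SplitPair",
    "PerfusionSeries",
    "CENTRIC_TRAJECTORIES",
    "TRAJECTORIES",
    "fft_centered",
    "ifft_centered",
    "hermitian_reflect",
]

CENTRIC_TRAJECTORIES = ("centric_1shot", "centric_2shot")
TRAJECTORIES = CENTRIC_TRAJECTORIES + ("linear_up", "linear_down")


def fft_centered(x: np.ndarray, axes: Optional[Tuple[int, ...]] = None) -> np.ndarray:
    """Forward FFT with the DC sample at index ``N // 2`` on every axis."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes), axes=axes)


def ifft_centered(x: np.ndarray, axes: Optional[Tuple[int, ...]] = None) -> np.ndarray:
    """Inverse of :func:`fft_centered`."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(x, axes=axes), axes=axes), axes=axes)


def hermitian_reflect(k: np.ndarray) -> np.ndarray:
    """Conjugate reflection of a centered k-space through the DC sample.

    Returns R with ``R[i] = conj(K[(2c - i) mod N])`` per axis (c = N//2),
    i.e. the k-space of the complex conjugate image.  For the k-space of a
    real-valued image, ``R == K``.
    """
    out = np.conj(k)
    for ax, n in enumerate(k.shape):
        out = np.flip(out, axis=ax)
        if n % 2 == 0:
            out = np.roll(out, 1, axis=ax)
    return out


@dataclass(frozen=True)
class AcquisitionParams:
    """Geometry and timing metadata of an EPI acquisition.

    Parameters
    ----------
    matrix_shape : tuple of int
        Voxels per axis (readout, PE[, partition]).
    pe_axis : int
        Index of the phase-encode axis (default 1).
    partial_fourier : float
        Acquired fraction of the full PE extent, in (0.5, 1].  The acquired
        lines are the *top* ``round(pf * N_pe)`` rows, so the omitted band
        sits at the -PE edge.
    total_readout_time : float
        Seconds between the centres of the first and last acquired PE lines.
        An off-resonance of f Hz displaces signal by ``f * total_readout_time``
        voxels along PE.
    trajectory : str
        One of ``centric_1shot``, ``centric_2shot``, ``linear_up``,
        ``linear_down``.  Centric trajectories carry opposite blip polarities
        in the two k-space halves.
    lines_per_jump : int
        PE lines between jump blips in the centric trajectory (metadata only).
    """

    matrix_shape: Tuple[int, ...]
    pe_axis: int = 1
    partial_fourier: float = 0.75
    total_readout_time: float = 0.03
    trajectory: str = "centric_1shot"
    lines_per_jump: int = 4

    def __post_init__(self):
        object.__setattr__(self, "matrix_shape", tuple(int(n) for n in self.matrix_shape))
        if not self.matrix_shape or any(n < 1 for n in self.matrix_shape):
            raise ValueError(f"invalid matrix_shape {self.matrix_shape}")
        if not 0 <= self.pe_axis < len(self.matrix_shape):
            raise ValueError(f"pe_axis {self.pe_axis} invalid for shape {self.matrix_shape}")
        if not 0.5 < self.partial_fourier <= 1.0:
            raise ValueError("partial_fourier must lie in (0.5, 1]")
        if self.total_readout_time <= 0:
            raise ValueError("total_readout_time must be positive")
        if self.trajectory not in TRAJECTORIES:
            raise ValueError(f"unknown trajectory {self.trajectory!r}")
        if self.lines_per_jump < 1:
            raise ValueError("lines_per_jump must be >= 1")

    # -- derived geometry ---------------------------------------------------
    @property
    def n_pe(self) -> int:
        return self.matrix_shape[self.pe_axis]

    @property
    def center_line(self) -> int:
        """PE index of the DC line (centered convention)."""
        return self.n_pe // 2

    @property
    def n_acquired(self) -> int:
        """Number of acquired PE lines under partial Fourier."""
        return int(round(self.partial_fourier * self.n_pe))

    @property
    def first_acquired(self) -> int:
        """Lowest acquired PE index; the band below it is zero-filled."""
        return self.n_pe - self.n_acquired

    @property
    def is_centric(self) -> bool:
        return self.trajectory in CENTRIC_TRAJECTORIES

    def acquired_lines(self) -> np.ndarray:
        """Boolean PE-line mask of acquired rows (length ``n_pe``)."""
        mask = np.zeros(self.n_pe, dtype=bool)
        mask[self.first_acquired:] = True
        return mask

    def replace(self, **kw) -> "AcquisitionParams":
        return replace(self, **kw)


@dataclass
class FieldMap:
    """Per-voxel off-resonance in Hz.

    ``provenance`` records how the map was obtained: ``truth`` (simulator),
    ``gre`` (double-echo reference), ``topup`` (reversed-polarity
    registration) or ``single_kspace`` (the iterative single-k-space estimate).
    ``valid`` optionally marks voxels where the estimate is trustworthy
    (e.g. nonzero magnitude for the GRE method).
    """

    values: np.ndarray
    provenance: str = "truth"
    valid: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field map must be finite everywhere")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape

    def displacement_voxels(self, params: AcquisitionParams) -> np.ndarray:
        """PE displacement in voxels: ``values * total_readout_time``."""
        return self.values * params.total_readout_time


def as_field_values(field) -> np.ndarray:
    """Accept a FieldMap or a bare array of Hz values."""
    if isinstance(field, FieldMap):
        return field.values
    return np.asarray(field, dtype=float)


@dataclass
class KSpace:
    """Centered complex k-space with an acquired-PE-line mask."""

    data: np.ndarray
    acquired_mask: np.ndarray  # 1-D bool over PE lines
    params: AcquisitionParams

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=complex)
        self.acquired_mask = np.asarray(self.acquired_mask, dtype=bool)
        if self.data.shape != self.params.matrix_shape:
            raise ValueError(
                f"k-space shape {self.data.shape} != matrix_shape {self.params.matrix_shape}"
            )
        if self.acquired_mask.shape != (self.params.n_pe,):
            raise ValueError("acquired_mask must be 1-D over PE lines")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def line_slicer(self, lines: np.ndarray):
        """Index tuple selecting the given PE lines of the N-D array."""
        idx = [slice(None)] * self.data.ndim
        idx[self.params.pe_axis] = lines
        return tuple(idx)

    def zero_filled_image(self) -> np.ndarray:
        """Plain inverse transform of the (already zero-filled) k-space."""
        return ifft_centered(self.data)


@dataclass
class SplitPair:
    """Blip-up / blip-down partial k-spaces extracted from a centric k-space."""

    k_up: KSpace
    k_down: KSpace


@dataclass
class PerfusionSeries:
    """Label/control ASL series with M0 volumes and evaluation masks.

    Volume arrays are stacked along axis 0 (repetition index).
    """

    control: np.ndarray
    label: np.ndarray
    m0: np.ndarray
    gm_mask: np.ndarray
    bg_mask: np.ndarray

    def __post_init__(self):
        if self.control.shape != self.label.shape:
            raise ValueError("label/control counts or grids differ")
        if np.any(self.gm_mask & self.bg_mask):
            raise ValueError("gray-matter and background masks must be disjoint")

    @property
    def n_pairs(self) -> int:
        return self.control.shape[0]

    def perfusion_weighted(self) -> np.ndarray:
        """Per-pair control - label difference images."""
        return self.control - self.label

    def delta_m(self) -> np.ndarray:
        """Average control - label difference image."""
        return self.perfusion_weighted().mean(axis=0)

    def m0_mean(self) -> np.ndarray:
        return self.m0.mean(axis=0)
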