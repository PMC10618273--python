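"""File formats: NIfTI-1 for images, fields and masks; NPZ + YAML sidecar
for k-space; a plain-text sidecar mirroring the usual PE-direction /
total-readout-time convention for field maps."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import AcquisitionParams, FieldMap, KSpace

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_complex_nifti",
    "load_complex_nifti",
    "save_mask",
    "load_mask",
    "save_kspace",
    "load_kspace",
    "save_fieldmap",
    "load_fieldmap",
]

_AFFINE = np.eye(4)


def save_nifti(path, data: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), _AFFINE), str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_complex_nifti(stem, data: np.ndarray) -> None:
    """Complex volume as a magnitude + phase NIfTI pair (`<stem>_mag.nii.gz`,
    `<stem>_phase.nii.gz`)."""
    stem = str(stem)
    save_nifti(stem + "_mag.nii.gz", np.abs(data))
    save_nifti(stem + "_phase.nii.gz", np.angle(data))


def load_complex_nifti(stem) -> np.ndarray:
    stem = str(stem)
    mag = load_nifti(stem + "_mag.nii.gz")
    phase = load_nifti(stem + "_phase.nii.gz")
    return mag * np.exp(1j * phase)


def save_mask(path, mask: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _AFFINE), str(path))


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5


def save_kspace(stem, k: KSpace) -> None:
    """k-space as `<stem>.npz` (data, acquired_mask) plus `<stem>.yaml`
    holding the acquisition parameters."""
    stem = str(stem)
    np.savez(stem + ".npz", data=k.data, acquired_mask=k.acquired_mask)
    with open(stem + ".yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(k.params), fh)


def load_kspace(stem) -> KSpace:
    stem = str(stem)
    arrays = np.load(stem + ".npz")
    with open(stem + ".yaml") as fh:
        raw = yaml.safe_load(fh)
    raw["matrix_shape"] = tuple(raw["matrix_shape"])
    params = AcquisitionParams(**raw)
    return KSpace(data=arrays["data"], acquired_mask=arrays["acquired_mask"], params=params)


def save_fieldmap(stem, fmap: FieldMap, params: AcquisitionParams) -> None:
    """Field map in Hz and as a voxel-displacement map, with a text sidecar
    recording the PE axis sign convention and total readout time."""
    stem = str(stem)
    save_nifti(stem + "_hz.nii.gz", fmap.values)
    save_nifti(stem + "_voxels.nii.gz", fmap.displacement_voxels(params))
    pe_vec = ["0"] * max(len(params.matrix_shape), 3)
    pe_vec[params.pe_axis] = "1"
    with open(stem + "_acq.txt", "w") as fh:
        fh.write(" ".join(pe_vec) + f" {params.total_readout_time:.6f}\n")
        fh.write(" ".join("-1" if v == "1" else v for v in pe_vec)
                 + f" {params.total_readout_time:.6f}\n")


def load_fieldmap(stem, provenance: str = "single_kspace") -> FieldMap:
    return FieldMap(load_nifti(str(stem) + "_hz.nii.gz"), provenance=provenance)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
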