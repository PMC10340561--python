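"""Reading and writing 3D volumes and binary masks.

Volumes are kept in (x, y, z) axis order throughout the package, matching
the H x W x D patch convention used by the sampler and the network. NIfTI
(.nii / .nii.gz) is the on-disk format; the affine is passed through
untouched (no resampling, no reorientation). A plain .npz container is
accepted as an internal fixture format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

MODALITIES = ("mra_like", "ct_like", "unknown")


class ValidationError(ValueError):
    pass


@dataclass
class Volume:
    """A rank-3 scalar grid with voxel spacing in mm and a modality tag."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    modality: str = "unknown"
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(f"volume must be rank-3, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive values, got {self.spacing}")
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if bad:
            raise ValidationError(f"volume contains {bad} non-finite voxel(s)")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMask:
    """A rank-3 binary grid ({0,1}) aligned to a Volume."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError(f"mask values must be exactly {{0,1}}, found {vals[:10]}")
        self.data = arr.astype(np.uint8)
        if self.data.ndim != 3:
            raise ValidationError(f"mask must be rank-3, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.data.shape

    def check_aligned(self, vol: Volume):
        if self.data.shape != vol.data.shape:
            raise ValidationError(
                f"mask shape {self.data.shape} does not match volume shape {vol.data.shape}"
            )


def _load_any(path: Path):
    if path.suffix == ".npz":
        with np.load(path) as f:
            data = f["data"]
            spacing = tuple(f["spacing"]) if "spacing" in f else (1.0, 1.0, 1.0)
        return data, spacing, None
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine)


def read_volume(path, modality: str = "unknown") -> Volume:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    data, spacing, affine = _load_any(path)
    return Volume(np.asarray(data, dtype=np.float32), spacing, modality, affine)


def read_mask(path) -> LabelMask:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    data, spacing, affine = _load_any(path)
    arr = np.asarray(data)
    if not np.isfinite(arr).all():
        raise ValidationError("mask contains non-finite values")
    return LabelMask(np.rint(arr).astype(np.uint8), spacing, affine)


def write_volume(v, path) -> None:
    """Write a Volume (float32) or LabelMask (uint8) to NIfTI or .npz."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(v, LabelMask):
        data = v.data.astype(np.uint8)
    else:
        data = v.data.astype(np.float32)
    if path.suffix == ".npz":
        np.savez(path, data=data, spacing=np.asarray(v.spacing))
        return
    affine = v.affine
    if affine is None:
        affine = np.diag(list(v.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))
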