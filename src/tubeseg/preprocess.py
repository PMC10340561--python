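"""Intensity normalization, ROI masking, and label-preserving augmentation.

Z-score normalization is applied at whole-image level (before any patch
cropping) using the population standard deviation:

    x_out = (x_in - mean(x_in)) / std(x_in)

Augmentation applies the same geometric transform to image and label, with
trilinear interpolation for the image and nearest-neighbour for the label so
labels stay strictly binary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import LabelMask, ValidationError, Volume


def zscore(v: Volume) -> Volume:
    """Whole-volume z-score; constant volumes map to all zeros with a warning."""
    x = v.data
    sd = float(x.std())  # population std, no Bessel correction
    if sd == 0.0:
        warnings.warn("zscore: constant volume (std == 0); returning zeros")
        return Volume(np.zeros_like(x), v.spacing, v.modality, v.affine)
    out = (x - float(x.mean())) / sd
    return Volume(out.astype(np.float32), v.spacing, v.modality, v.affine)


def apply_roi(v: Volume, roi: LabelMask, background: float = 0.0) -> Volume:
    """Zero out (set to `background`) all voxels outside the ROI mask."""
    roi.check_aligned(v)
    out = np.where(roi.data > 0, v.data, np.float32(background))
    return Volume(out.astype(np.float32), v.spacing, v.modality, v.affine)


@dataclass
class AugmentSpec:
    """Random flip / affine / elastic deformation settings.

    Magnitudes default mild so that augmentation perturbs rather than
    destroys the thin foreground (the tubes are only a few voxels wide).
    """

    flip_axes: tuple = (0, 1, 2)
    flip_prob: float = 0.5
    rotation_max_deg: float = 10.0
    affine_scale_range: tuple = (0.95, 1.05)
    elastic_sigma: float = 4.0
    elastic_alpha: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValidationError("flip_prob must be in [0, 1]")
        if not (0.0 <= self.rotation_max_deg <= 180.0):
            raise ValidationError("rotation_max_deg must be in [0, 180]")


def _rotation_matrix(angles_rad) -> np.ndarray:
    ax, ay, az = angles_rad
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def augment(v: Volume, m: LabelMask, spec: AugmentSpec,
            rng: np.random.Generator | None = None):
    """Apply one random flip/affine/elastic draw to an image-label pair."""
    m.check_aligned(v)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    img = v.data.astype(np.float32)
    lab = m.data.astype(np.float32)

    for ax in spec.flip_axes:
        if rng.random() < spec.flip_prob:
            img = np.flip(img, axis=ax)
            lab = np.flip(lab, axis=ax)

    lo, hi = spec.affine_scale_range
    needs_affine = spec.rotation_max_deg > 0 or (lo, hi) != (1.0, 1.0)
    if needs_affine:
        angles = np.radians(rng.uniform(-spec.rotation_max_deg,
                                        spec.rotation_max_deg, size=3))
        scale = rng.uniform(lo, hi)
        mat = _rotation_matrix(angles) / scale
        center = (np.asarray(img.shape) - 1) / 2.0
        offset = center - mat @ center
        img = ndimage.affine_transform(img, mat, offset=offset, order=1, mode="nearest")
        lab = ndimage.affine_transform(lab, mat, offset=offset, order=0, mode="nearest")

    if spec.elastic_alpha > 0:
        disp = [
            ndimage.gaussian_filter(rng.normal(size=img.shape), spec.elastic_sigma)
            for _ in range(3)
        ]
        disp = [d / (np.abs(d).max() + 1e-12) * spec.elastic_alpha for d in disp]
        coords = np.meshgrid(*[np.arange(s) for s in img.shape], indexing="ij")
        warped = [c + d for c, d in zip(coords, disp)]
        img = ndimage.map_coordinates(img, warped, order=1, mode="nearest")
        lab = ndimage.map_coordinates(lab, warped, order=0, mode="nearest")

    out_v = Volume(np.ascontiguousarray(img), v.spacing, v.modality, v.affine)
    out_m = LabelMask(np.rint(np.ascontiguousarray(lab)).astype(np.uint8),
                      m.spacing, m.affine)
    return out_v, out_m
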