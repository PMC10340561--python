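"""Full-volume prediction by tiled sliding-window inference, plus the two
post-processing strategies: ROI filtering and connected-component cleanup.

Inference tiling uses the full-coverage convention (final tile clamped to
the volume edge); overlapping voxels average the contributing patch
probabilities. Components use 26-connectivity throughout, matching the
phantom generator's notion of connectedness.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .nn import Tensor, no_grad
from .patch_sampler import SamplingPlan, inference_origins, stitch
from .volume_io import LabelMask, ValidationError, Volume

_CONN26 = np.ones((3, 3, 3), dtype=int)


def predict_volume(model, v: Volume | np.ndarray, plan: SamplingPlan,
                   step=None) -> np.ndarray:
    """Tile, forward each patch, stitch. Returns (2, X, Y, Z) probabilities.

    The volume is expected to be normalized the same way the model was
    trained (z-score). Default stride = patch size (non-overlapping tiles
    with a clamped final tile)."""
    data = v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float32)
    origins = inference_origins(data.shape, plan.patch, step)
    px, py, pz = plan.patch
    probs = []
    model.eval()
    for o in origins:
        patch = data[o[0]:o[0] + px, o[1]:o[1] + py, o[2]:o[2] + pz]
        with no_grad():
            out = model(Tensor(patch[None, None].astype(np.float32)))
        probs.append(out.data[0])
    return stitch(probs, origins, data.shape)


def binarize(prob: np.ndarray) -> LabelMask:
    """Foreground where its probability strictly exceeds background's
    (argmax with ties going to background)."""
    prob = np.asarray(prob)
    if prob.ndim != 4 or prob.shape[0] != 2:
        raise ValidationError(f"expected (2, X, Y, Z) probabilities, got {prob.shape}")
    return LabelMask((prob[1] > prob[0]).astype(np.uint8))


def largest_component_filter(m: LabelMask, mode: str = "keep_largest",
                             min_size: int | None = None) -> LabelMask:
    """26-connected component filtering.

    keep_largest: retain only the largest foreground component.
    min_size: retain every component with at least `min_size` voxels.
    """
    lab, n = ndimage.label(m.data, structure=_CONN26)
    if n == 0:
        return LabelMask(np.zeros_like(m.data), m.spacing, m.affine)
    sizes = np.bincount(lab.ravel())[1:]
    if mode == "keep_largest":
        keep = {int(np.argmax(sizes)) + 1}
    elif mode == "min_size":
        if min_size is None:
            raise ValidationError("min_size mode requires min_size")
        keep = {i + 1 for i, s in enumerate(sizes) if s >= min_size}
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    out = np.isin(lab, list(keep)).astype(np.uint8)
    return LabelMask(out, m.spacing, m.affine)


def roi_filter(m: LabelMask, roi: LabelMask) -> LabelMask:
    """Voxel-wise conjunction: discard predictions outside the anatomical
    region of interest (brain tissue / lung parenchyma)."""
    if m.data.shape != roi.data.shape:
        raise ValidationError("prediction/ROI shape mismatch")
    return LabelMask((m.data & roi.data).astype(np.uint8), m.spacing, m.affine)
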