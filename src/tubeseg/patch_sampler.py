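"""Training-patch extraction ("sliding window sequence + random") and
inference-time tiling/stitching.

Two distinct origin conventions are used on purpose:

* Training convention (`sliding_origins`): x and y origins run over
  {0, s, 2s, ...} with k*s < X - p — the final aligned origin at X - p is
  EXCLUDED — while z origins include it (k*s <= Z - p). This asymmetric
  convention was reverse-engineered as the unique simple rule that
  reproduces the published patch totals for 448x448x128 images (see
  `count_training_patches`), and is pinned by an enumeration-oracle test.
  It leaves a margin uncovered, which is acceptable when sampling training
  patches but not for prediction.

* Inference convention (`inference_origins`): origins at multiples of the
  step with the final origin clamped to extent - patch, guaranteeing full
  coverage so every voxel gets a prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import LabelMask, ValidationError, Volume


class SamplingError(RuntimeError):
    pass


@dataclass
class SamplingPlan:
    patch: tuple = (64, 64, 32)
    step: tuple = (32, 32, 32)
    n_random: int = 30
    threshold: float = 0.001
    max_tries: int | None = None
    seed: int = 0

    def __post_init__(self):
        self.patch = tuple(int(p) for p in self.patch)
        self.step = tuple(int(s) for s in self.step)
        if any(p < 1 for p in self.patch):
            raise ValidationError("patch dims must be >= 1")
        if any(s < 1 for s in self.step):
            raise ValidationError("step dims must be >= 1")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValidationError("threshold must be in [0, 1]")
        if self.n_random < 0:
            raise ValidationError("n_random must be >= 0")
        if self.max_tries is None:
            self.max_tries = 1000 * max(self.n_random, 1)


@dataclass
class PatchRecord:
    origin: tuple
    source: str  # "sliding" | "random"
    label_fraction: float | None = None


def _check_fits(shape, patch):
    if any(p > s for p, s in zip(patch, shape)):
        raise ValidationError(f"patch {patch} larger than image {shape}")


def _axis_origins(extent: int, patch: int, step: int, include_final: bool):
    last = extent - patch
    if include_final:
        ks = range(0, last + 1, step)
    else:
        ks = range(0, last, step) if last > 0 else range(0)
    out = list(ks)
    return out if out else [0]


def sliding_origins(shape, plan: SamplingPlan):
    """Ordered training-patch origins; z-fastest lexicographic order."""
    _check_fits(shape, plan.patch)
    ax = _axis_origins(shape[0], plan.patch[0], plan.step[0], include_final=False)
    ay = _axis_origins(shape[1], plan.patch[1], plan.step[1], include_final=False)
    az = _axis_origins(shape[2], plan.patch[2], plan.step[2], include_final=True)
    return [(x, y, z) for x in ax for y in ay for z in az]


def inference_origins(shape, patch, step=None):
    """Full-coverage tiling origins (final origin clamped to extent-patch)."""
    _check_fits(shape, patch)
    if step is None:
        step = patch
    axes = []
    for ext, p, s in zip(shape, patch, step):
        o = list(range(0, ext - p + 1, s))
        if o[-1] != ext - p:
            o.append(ext - p)
        axes.append(o)
    return [(x, y, z) for x in axes[0] for y in axes[1] for z in axes[2]]


def label_fraction(label_patch) -> float:
    """Foreground voxels over total voxels in the patch."""
    arr = label_patch.data if isinstance(label_patch, LabelMask) else np.asarray(label_patch)
    if arr.size == 0:
        raise ValidationError("empty patch")
    return float(arr.sum()) / float(arr.size)


def random_origins(shape, label: LabelMask, plan: SamplingPlan,
                   rng: np.random.Generator | None = None):
    """Rejection-sample n_random origins with label fraction strictly above
    the plan threshold, uniform over the valid origin lattice."""
    _check_fits(shape, plan.patch)
    if label.data.shape != tuple(shape):
        raise ValidationError("label shape does not match image shape")
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    if plan.threshold >= 1.0:
        raise SamplingError("no patch can have label fraction strictly above 1.0")
    px, py, pz = plan.patch
    hi = [shape[i] - plan.patch[i] for i in range(3)]
    out = []
    tries = 0
    while len(out) < plan.n_random:
        if tries >= plan.max_tries:
            rate = len(out) / max(tries, 1)
            raise SamplingError(
                f"accepted only {len(out)}/{plan.n_random} random patches after "
                f"{tries} tries (acceptance rate {rate:.2%}); threshold "
                f"{plan.threshold} too strict for this label"
            )
        o = tuple(int(rng.integers(0, h + 1)) for h in hi)
        tries += 1
        frac = label_fraction(label.data[o[0]:o[0] + px, o[1]:o[1] + py, o[2]:o[2] + pz])
        if frac > plan.threshold:
            out.append(o)
    return out


def count_training_patches(n_images: int, shape, plan: SamplingPlan) -> int:
    """Total training patches: n_images * (sliding origins + random crops)."""
    return int(n_images) * (len(sliding_origins(shape, plan)) + plan.n_random)


def extract(v: Volume, m: LabelMask | None, plan: SamplingPlan,
            rng: np.random.Generator | None = None):
    """Extract (image patch, label patch, record) triples for training."""
    shape = v.data.shape
    if m is not None:
        m.check_aligned(v)
    origins = [(o, "sliding") for o in sliding_origins(shape, plan)]
    if plan.n_random > 0:
        if m is None:
            raise ValidationError("random cropping requires a label mask")
        origins += [(o, "random") for o in random_origins(shape, m, plan, rng)]
    px, py, pz = plan.patch
    out = []
    for o, src in origins:
        sl = (slice(o[0], o[0] + px), slice(o[1], o[1] + py), slice(o[2], o[2] + pz))
        img = v.data[sl]
        lab = m.data[sl] if m is not None else None
        rec = PatchRecord(o, src, None if lab is None else label_fraction(lab))
        out.append((img, lab, rec))
    return out


def stitch(prob_patches, origins, shape) -> np.ndarray:
    """Reassemble per-patch class-probability maps (C, px, py, pz) into a
    full volume, averaging where tiles overlap. Raises if any voxel is
    uncovered."""
    if len(prob_patches) != len(origins):
        raise ValidationError("patches and origins length mismatch")
    first = np.asarray(prob_patches[0])
    c = first.shape[0]
    acc = np.zeros((c,) + tuple(shape), dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.int32)
    for p, o in zip(prob_patches, origins):
        p = np.asarray(p)
        px, py, pz = p.shape[1:]
        if any(oo + pp > ss for oo, pp, ss in zip(o, (px, py, pz), shape)):
            raise ValidationError(f"patch at origin {o} exceeds volume {shape}")
        acc[:, o[0]:o[0] + px, o[1]:o[1] + py, o[2]:o[2] + pz] += p
        cnt[o[0]:o[0] + px, o[1]:o[1] + py, o[2]:o[2] + pz] += 1
    if (cnt == 0).any():
        raise SamplingError(f"{int((cnt == 0).sum())} voxel(s) not covered by any tile")
    return (acc / cnt).astype(np.float32)
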