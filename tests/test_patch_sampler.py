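"""Patch extraction: origin conventions, counting, random crops, stitching."""

import numpy as np
import pytest

from tubeseg.patch_sampler import (
    PatchRecord,
    SamplingError,
    SamplingPlan,
    count_training_patches,
    extract,
    inference_origins,
    label_fraction,
    random_origins,
    sliding_origins,
    stitch,
)
from tubeseg.volume_io import LabelMask, ValidationError, Volume


def brute_force_origins(shape, patch, step):
    """Independent enumeration of the training convention: x/y origins at
    multiples of the step strictly below extent - patch (guard: origin 0 if
    none), z origins at multiples up to and including extent - patch."""
    axes = []
    for i, inclusive in ((0, False), (1, False), (2, True)):
        ext, p, s = shape[i], patch[i], step[i]
        found = []
        k = 0
        while True:
            o = k * s
            if inclusive and o > ext - p:
                break
            if not inclusive and o >= ext - p:
                break
            found.append(o)
            k += 1
        axes.append(found if found else [0])
    return [(x, y, z) for x in axes[0] for y in axes[1] for z in axes[2]]


@pytest.mark.parametrize(
    "patch,step,n_axis",
    [
        ((64, 64, 32), (32, 32, 32), (12, 12, 4)),
        ((16, 16, 32), (16, 16, 32), (27, 27, 4)),
        ((128, 128, 32), (64, 64, 32), (5, 5, 4)),
    ],
)
def test_sliding_counts_on_standard_mra_geometry(patch, step, n_axis):
    plan = SamplingPlan(patch=patch, step=step, n_random=30)
    origins = sliding_origins((448, 448, 128), plan)
    assert len(origins) == n_axis[0] * n_axis[1] * n_axis[2]


def test_published_patch_totals_reproduced_exactly():
    shape = (448, 448, 128)
    cases = [((16, 16, 32), (16, 16, 32), 223896),
             ((64, 64, 32), (32, 32, 32), 46056),
             ((128, 128, 32), (64, 64, 32), 9880)]
    for patch, step, expected in cases:
        plan = SamplingPlan(patch=patch, step=step, n_random=30)
        assert count_training_patches(76, shape, plan) == expected


def test_sliding_matches_enumeration_oracle_on_random_geometries():
    rng = np.random.default_rng(3)
    for _ in range(50):
        patch = tuple(int(rng.integers(2, 20)) for _ in range(3))
        shape = tuple(p + int(rng.integers(0, 40)) for p in patch)
        step = tuple(int(rng.integers(1, 12)) for _ in range(3))
        plan = SamplingPlan(patch=patch, step=step, n_random=0)
        assert sliding_origins(shape, plan) == brute_force_origins(shape, patch, step)


def test_patch_equal_to_image_gives_single_origin():
    plan = SamplingPlan(patch=(64, 64, 32), step=(32, 32, 32), n_random=0)
    assert sliding_origins((64, 64, 32), plan) == [(0, 0, 0)]


def test_ordering_is_z_fastest():
    plan = SamplingPlan(patch=(4, 4, 4), step=(4, 4, 4), n_random=0)
    origins = sliding_origins((12, 12, 12), plan)
    assert origins[0] == (0, 0, 0) and origins[1] == (0, 0, 4)


def test_patch_larger_than_image_rejected():
    plan = SamplingPlan(patch=(16, 16, 16), step=(4, 4, 4))
    with pytest.raises(ValidationError):
        sliding_origins((8, 8, 8), plan)


def test_label_fraction_direct_counts():
    assert label_fraction(np.zeros((4, 4, 4))) == 0.0
    arr = np.zeros((4, 4, 4))
    arr.ravel()[:8] = 1
    assert label_fraction(arr) == 8 / 64
    assert label_fraction(np.ones((4, 4, 4))) == 1.0


def test_random_origins_threshold_and_determinism():
    rng_mask = np.zeros((20, 20, 20), np.uint8)
    rng_mask[8:12, 8:12, 8:12] = 1
    label = LabelMask(rng_mask)
    plan = SamplingPlan(patch=(8, 8, 8), step=(8, 8, 8), n_random=5,
                        threshold=0.0, seed=4)
    o1 = random_origins((20, 20, 20), label, plan)
    o2 = random_origins((20, 20, 20), label, plan)
    assert o1 == o2 and len(o1) == 5
    for o in o1:
        patch = rng_mask[o[0]:o[0] + 8, o[1]:o[1] + 8, o[2]:o[2] + 8]
        assert label_fraction(patch) > 0.0


def test_random_origins_impossible_threshold_raises():
    label = LabelMask(np.ones((8, 8, 8), np.uint8))
    plan = SamplingPlan(patch=(4, 4, 4), step=(4, 4, 4), n_random=2, threshold=1.0)
    with pytest.raises(SamplingError):
        random_origins((8, 8, 8), label, plan)


def test_random_origins_reports_acceptance_rate_on_failure():
    label = LabelMask(np.zeros((8, 8, 8), np.uint8))  # nothing passes > 0.5
    plan = SamplingPlan(patch=(4, 4, 4), step=(4, 4, 4), n_random=2,
                        threshold=0.5, max_tries=50)
    with pytest.raises(SamplingError, match="acceptance rate"):
        random_origins((8, 8, 8), label, plan)


def test_extract_matches_direct_slicing(small_phantom):
    vol, mask, _ = small_phantom
    plan = SamplingPlan(patch=(16, 16, 16), step=(16, 16, 16), n_random=3,
                        threshold=0.0, seed=5)
    triples = extract(vol, mask, plan)
    n_slide = len(sliding_origins(vol.shape, plan))
    assert len(triples) == n_slide + 3
    for img, lab, rec in triples[::4]:
        o = rec.origin
        sl = tuple(slice(o[i], o[i] + 16) for i in range(3))
        assert np.array_equal(img, vol.data[sl])
        assert np.array_equal(lab, mask.data[sl])
        assert rec.label_fraction == lab.mean()


def test_extract_without_random_crops(small_phantom):
    vol, mask, _ = small_phantom
    plan = SamplingPlan(patch=(16, 16, 16), step=(16, 16, 16), n_random=0)
    triples = extract(vol, mask, plan)
    assert all(r.source == "sliding" for _, _, r in triples)


def test_inference_origins_cover_every_voxel():
    shape, patch = (50, 33, 20), (16, 16, 16)
    covered = np.zeros(shape, bool)
    for o in inference_origins(shape, patch):
        covered[o[0]:o[0] + 16, o[1]:o[1] + 16, o[2]:o[2] + 16] = True
    assert covered.all()


def test_stitch_partition_is_exact():
    rng = np.random.default_rng(6)
    vol = rng.random((2, 8, 8, 8)).astype(np.float32)
    vol /= vol.sum(axis=0, keepdims=True)
    patches, origins = [], []
    for o in inference_origins((8, 8, 8), (4, 4, 4)):
        patches.append(vol[:, o[0]:o[0] + 4, o[1]:o[1] + 4, o[2]:o[2] + 4])
        origins.append(o)
    out = stitch(patches, origins, (8, 8, 8))
    assert np.array_equal(out, vol)


def test_stitch_averages_overlap_and_keeps_probabilities_normalized():
    p1 = np.stack([np.full((4, 4, 4), 0.8), np.full((4, 4, 4), 0.2)])
    p2 = np.stack([np.full((4, 4, 4), 0.4), np.full((4, 4, 4), 0.6)])
    out = stitch([p1, p2], [(0, 0, 0), (2, 0, 0)], (6, 4, 4))
    assert np.allclose(out[1, 2:4], 0.4)  # mean of 0.2 and 0.6
    assert np.allclose(out.sum(axis=0), 1.0, atol=1e-6)


def test_stitch_rejects_uncovered_voxels():
    p = np.zeros((2, 4, 4, 4))
    with pytest.raises(SamplingError):
        stitch([p], [(0, 0, 0)], (8, 4, 4))
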