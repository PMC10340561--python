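"""Phantom generator: determinism, geometry, rasterization oracle,
foreground-fraction control, intensity regimes."""

import numpy as np
import pytest
from scipy import ndimage

from tubeseg.phantom import (
    CenterlineTree,
    ConfigurationError,
    PhantomConfig,
    foreground_fraction,
    generate_tree,
    make_dataset,
    rasterize_tree,
    render_intensity,
)


def test_single_generation_is_one_segment():
    cfg = PhantomConfig(grid=(32, 32, 32), generations=1, root_radius=2.0,
                        target_fg_fraction=0.05, seed=3)
    tree = generate_tree(cfg)
    assert tree.depth == 1
    assert len(tree.edges) == 1


def test_same_seed_same_tree():
    cfg = PhantomConfig(seed=11)
    t1, t2 = generate_tree(cfg), generate_tree(cfg)
    assert np.array_equal(t1.nodes, t2.nodes)
    assert np.array_equal(t1.radii, t2.radii)
    assert t1.edges == t2.edges


def test_radii_follow_decay_recurrence():
    cfg = PhantomConfig(grid=(96, 96, 96), generations=4, root_radius=4.0,
                        radius_decay=0.7, target_fg_fraction=0.03, seed=5)
    tree = generate_tree(cfg)
    gen4 = tree.radii[tree.generation == 4]
    assert len(gen4) > 0
    assert gen4.max() <= 0.7 ** 3 * 4.0 + 1e-9
    # child radius never exceeds parent radius
    for p, c in tree.edges:
        assert tree.radii[c] <= tree.radii[p] + 1e-9


def _brute_force_rasterize(tree, grid):
    shape = tuple(grid)
    out = np.zeros(shape, dtype=np.uint8)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                pt = np.array([x, y, z], dtype=float)
                for p, c in tree.edges:
                    p0, p1 = tree.nodes[p], tree.nodes[c]
                    d = p1 - p0
                    dd = d @ d
                    t = 0.0 if dd < 1e-12 else float(np.clip((pt - p0) @ d / dd, 0, 1))
                    dist = np.linalg.norm(pt - (p0 + t * d))
                    rad = tree.radii[p] + (tree.radii[c] - tree.radii[p]) * t
                    if dist <= rad:
                        out[x, y, z] = 1
                        break
    return out


def test_rasterization_matches_brute_force_oracle():
    cfg = PhantomConfig(grid=(24, 24, 24), generations=3, root_radius=1.8,
                        target_fg_fraction=0.06, seed=9)
    tree = generate_tree(cfg)
    fast = rasterize_tree(tree, cfg.grid).data
    slow = _brute_force_rasterize(tree, cfg.grid)
    assert np.array_equal(fast, slow)


def test_axis_aligned_segment_gives_discrete_disks():
    nodes = np.array([[4.0, 8.0, 8.0], [14.0, 8.0, 8.0]])
    tree = CenterlineTree(nodes=nodes, radii=np.array([2.0, 2.0]),
                          edges=[(0, 1)], generation=np.array([1, 2]))
    mask = rasterize_tree(tree, (20, 16, 16)).data
    yy, zz = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
    disk = ((yy - 8) ** 2 + (zz - 8) ** 2 <= 4.0).astype(np.uint8)
    for x in range(5, 14):  # interior cross-sections
        assert np.array_equal(mask[x], disk)


def test_empty_tree_rasterizes_to_zero():
    tree = CenterlineTree(np.zeros((0, 3)), np.zeros(0), [], np.zeros(0, int))
    assert rasterize_tree(tree, (8, 8, 8)).data.sum() == 0


def test_mask_is_single_26connected_component(small_phantom):
    _, mask, _ = small_phantom
    _, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3)))
    assert n == 1


def test_fraction_control_median_within_20_percent():
    fracs = []
    for s in range(20):
        cfg = PhantomConfig(seed=s)
        fracs.append(foreground_fraction(rasterize_tree(generate_tree(cfg), cfg.grid)))
    med = float(np.median(fracs))
    assert abs(med - 0.015) / 0.015 < 0.20


def test_make_dataset_deterministic_and_within_band():
    cfg = PhantomConfig(seed=77)
    d1 = make_dataset(3, cfg)
    d2 = make_dataset(3, cfg)
    for (v1, m1), (v2, m2) in zip(d1, d2):
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(m1.data, m2.data)
    # three phantoms are distinct from each other
    assert not np.array_equal(d1[0][1].data, d1[1][1].data)
    for _, m in d1:
        assert 0.0075 <= foreground_fraction(m) <= 0.0225


def test_make_dataset_guards():
    with pytest.raises(ConfigurationError):
        make_dataset(0, PhantomConfig())


def test_bright_tube_intensities(small_phantom):
    _, mask, cfg = small_phantom
    from dataclasses import replace

    noiseless = render_intensity(mask, replace(cfg, noise_sd=0.0))
    assert set(np.unique(noiseless.data)) == {cfg.bg_mean, cfg.fg_mean}
    noisy = render_intensity(mask, cfg)
    fg = noisy.data[mask.data > 0].mean()
    bg = noisy.data[mask.data == 0].mean()
    assert fg > bg


def test_dark_lumen_intensities(small_phantom):
    from dataclasses import replace

    from scipy.ndimage import binary_dilation

    _, mask, cfg = small_phantom
    dl = render_intensity(mask, replace(cfg, modality="dark_lumen"))
    m = mask.data.astype(bool)
    wall = binary_dilation(m, iterations=2) & ~m
    surround = ~binary_dilation(m, iterations=2)
    assert dl.data[m].mean() < dl.data[wall].mean()
    assert dl.data[wall].mean() > dl.data[surround].mean()


def test_zero_contrast_rejected(small_phantom):
    from dataclasses import replace

    _, mask, cfg = small_phantom
    with pytest.raises(ConfigurationError):
        render_intensity(mask, replace(cfg, fg_mean=cfg.bg_mean))


def test_config_invariants():
    with pytest.raises(ConfigurationError):
        PhantomConfig(root_radius=0.5)
    with pytest.raises(ConfigurationError):
        PhantomConfig(radius_decay=1.0)
    with pytest.raises(ConfigurationError):
        PhantomConfig(target_fg_fraction=0.3)
    with pytest.raises(ConfigurationError):
        PhantomConfig(grid=(8, 8, 8), root_radius=3.0)
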