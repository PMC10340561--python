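import numpy as np
import pytest

from tubeseg.phantom import PhantomConfig, generate_tree, rasterize_tree, render_intensity


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One 48^3 phantom (volume, mask, config) shared across tests."""
    cfg = PhantomConfig(grid=(48, 48, 48), generations=4, root_radius=2.0,
                        target_fg_fraction=0.02, seed=7)
    tree = generate_tree(cfg)
    mask = rasterize_tree(tree, cfg.grid)
    vol = render_intensity(mask, cfg)
    return vol, mask, cfg
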