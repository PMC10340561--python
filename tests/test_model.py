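"""Architecture contracts: shapes, ablation flags, attention coefficients,
gradient flow, determinism, checkpointing."""

import numpy as np
import pytest

from tubeseg.model import (
    ModelConfig,
    UARAI,
    build_model,
    load_checkpoint,
    save_checkpoint,
)
from tubeseg.nn import Tensor, no_grad
from tubeseg.volume_io import ValidationError

RNG = np.random.default_rng(0)


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(ModelConfig(base_channels=2, dropout=0.0, seed=1))


@pytest.fixture(scope="module")
def tiny_input():
    return Tensor(RNG.normal(size=(1, 1, 32, 32, 16)).astype(np.float32))


def test_encoder_channel_schedule(tiny_model, tiny_input):
    c = tiny_model.cfg.base_channels
    e0, e1, e2, e3, f1 = tiny_model.encode(tiny_input)
    assert e0.shape[1:3] == (c, 32)
    assert e1.shape[1:3] == (2 * c, 16)
    assert e2.shape[1:3] == (4 * c, 8)
    assert e3.shape[1:3] == (8 * c, 4)
    assert f1.shape[1:] == (16 * c, 2, 2, 1)


def test_forward_output_shape_and_softmax(tiny_model, tiny_input):
    tiny_model.eval()
    with no_grad():
        y = tiny_model(tiny_input)
    assert y.shape == (1, 2, 32, 32, 16)
    assert np.abs(y.data.sum(axis=1) - 1.0).max() < 1e-6
    assert np.isfinite(y.data).all()


def test_forward_deterministic_in_eval(tiny_model, tiny_input):
    tiny_model.eval()
    with no_grad():
        y1 = tiny_model(tiny_input)
        y2 = tiny_model(tiny_input)
    assert np.array_equal(y1.data, y2.data)


def test_input_validation(tiny_model):
    with pytest.raises(ValidationError):
        tiny_model(Tensor(np.zeros((1, 1, 30, 32, 16), np.float32)))  # not /16
    with pytest.raises(ValidationError):
        tiny_model(Tensor(np.zeros((1, 3, 32, 32, 16), np.float32)))  # channels


def test_msfa_intermediate_and_output_shapes(tiny_model, tiny_input):
    with no_grad():
        e0, e1, f3, f2, f1 = tiny_model.encode(tiny_input)
        fmf = tiny_model.msfa_forward(f3, f2, f1)
    assert fmf.shape == (1, 1, 2, 2, 1)


def test_inception_preserves_spatial_dims(tiny_model):
    x = Tensor(RNG.normal(size=(1, 1, 4, 4, 2)).astype(np.float32))
    with no_grad():
        y = tiny_model.inception_forward(x)
    assert y.shape[2:] == (4, 4, 2)


def test_reverse_attention_coefficients_in_open_unit_interval(tiny_model, tiny_input):
    tiny_model.eval()
    with no_grad():
        e0, e1, f3, f2, f1 = tiny_model.encode(tiny_input)
        fmf = tiny_model.msfa_forward(f3, f2, f1)
        d, r, w = tiny_model.reverse_attention_step(0, carry=fmf, skip=f1)
    assert r.shape[1] == 1
    assert (r.data > 0).all() and (r.data < 1).all()
    assert w.shape == f1.shape  # MR broadcast across skip channels
    # Eq identity: R + sigmoid(logit) = 1 by construction
    logit_sig = 1.0 - r.data
    assert np.allclose(r.data + logit_sig, 1.0)


def test_sigmoid_zero_logits_give_half():
    x = Tensor(np.zeros((1, 1, 4, 4, 4), np.float32))
    assert np.allclose(1.0 - x.sigmoid().data, 0.5)


def test_baseline_has_no_attention_or_msfa_weights():
    m = build_model(ModelConfig(base_channels=2, msfa=False, ra=False, icp=False))
    names = [k for k, _ in m.named_parameters()]
    assert not any("msfa" in n or "ra" in n.split(".")[0] or "branch" in n for n in names)


def test_flags_add_parameters_monotonically():
    def n_params(**flags):
        return build_model(ModelConfig(base_channels=2, **flags)).num_parameters()

    base = n_params(msfa=False, ra=False, icp=False)
    msfa = n_params(msfa=True, ra=False, icp=False)
    ra = n_params(msfa=False, ra=True, icp=False)
    both = n_params(msfa=True, ra=True, icp=False)
    full = n_params(msfa=True, ra=True, icp=True)
    assert base < msfa < both < full
    assert base < ra <= both


def test_icp_requires_a_site():
    with pytest.raises(ValidationError):
        ModelConfig(msfa=False, ra=False, icp=True)


def test_flags_change_outputs():
    x = Tensor(RNG.normal(size=(1, 1, 16, 16, 16)).astype(np.float32))
    outs = []
    for flags in [dict(msfa=False, ra=False, icp=False),
                  dict(msfa=True, ra=False, icp=False),
                  dict(msfa=True, ra=True, icp=False),
                  dict(msfa=True, ra=True, icp=True)]:
        m = build_model(ModelConfig(base_channels=2, dropout=0.0, seed=5, **flags))
        m.eval()
        with no_grad():
            outs.append(m(x).data)
    for a, b in zip(outs, outs[1:]):
        assert not np.array_equal(a, b)


def test_every_parameter_receives_gradient(tiny_model):
    # spatial dims >= 32 so the bottleneck keeps > 1 voxel per axis pair:
    # instance norm over a single voxel is degenerate and blocks gradients
    tiny_model.train()
    x = Tensor(RNG.normal(size=(1, 1, 32, 32, 32)).astype(np.float32))
    target = Tensor(RNG.normal(size=(1, 2, 32, 32, 32)).astype(np.float32))
    y = tiny_model(x)
    ((y * target).sum()).backward()
    dead = [k for k, p in tiny_model.named_parameters()
            if p.grad is None or np.abs(p.grad).max() == 0]
    tiny_model.zero_grad()
    assert dead == []


def test_checkpoint_roundtrip(tmp_path, tiny_model, tiny_input):
    path = tmp_path / "model.npz"
    save_checkpoint(tiny_model, path)
    back = load_checkpoint(path)
    assert back.cfg == tiny_model.cfg
    tiny_model.eval()
    back.eval()
    with no_grad():
        y1 = tiny_model(tiny_input)
        y2 = back(tiny_input)
    assert np.array_equal(y1.data, y2.data)


def test_config_validation():
    with pytest.raises(ValidationError):
        ModelConfig(base_channels=0)
    with pytest.raises(ValidationError):
        ModelConfig(dropout=1.0)
    with pytest.raises(ValidationError):
        ModelConfig(depth=3)
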