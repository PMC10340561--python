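"""End-to-end experiment helpers: phantom generation through evaluation.

These functions wire the package's stages together with a single seed so a
whole experiment is reproducible bit-for-bit. The desk-scale defaults
(C=4 network, 32^3 training patches, a dozen 64^3 phantoms) are sized for a
single CPU; the same code runs at any scale.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .infer_postprocess import binarize, largest_component_filter, predict_volume
from .model import ModelConfig, build_model
from .patch_sampler import SamplingPlan, extract
from .phantom import PhantomConfig, make_dataset
from .preprocess import zscore
from .train_eval import TrainConfig, confusion, evaluate, metrics, train


def make_patch_sets(dataset, plan: SamplingPlan, seed: int):
    """Extract training patches from every (Volume, LabelMask) pair."""
    rng = np.random.default_rng(seed)
    patches = []
    for v, m in dataset:
        patches += [(img, lab) for img, lab, _ in extract(v, m, plan, rng)]
    return patches


def phantom_recovery_experiment(
    seed: int = 0,
    n_train: int = 8,
    n_val: int = 2,
    n_test: int = 4,
    phantom_cfg: PhantomConfig | None = None,
    model_cfg: ModelConfig | None = None,
    plan: SamplingPlan | None = None,
    train_cfg: TrainConfig | None = None,
):
    """Train on synthetic phantoms, evaluate on held-out ones.

    Returns a dict with the trained model, the loss history, and per-image
    metrics before and after keep-largest-component post-processing.
    """
    ss = np.random.SeedSequence(seed)
    s_phantom, s_patch, s_model, s_train = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)
    ]
    pcfg = phantom_cfg if phantom_cfg is not None else PhantomConfig(seed=s_phantom)
    pcfg = replace(pcfg, seed=s_phantom)
    data = make_dataset(n_train + n_val + n_test, pcfg)
    data = [(zscore(v), m) for v, m in data]
    d_train = data[:n_train]
    d_val = data[n_train:n_train + n_val]
    d_test = data[n_train + n_val:]

    if plan is None:
        plan = SamplingPlan(patch=(32, 32, 32), step=(32, 32, 32),
                            n_random=6, threshold=0.001, seed=s_patch)
    train_patches = make_patch_sets(d_train, plan, s_patch)
    val_patches = make_patch_sets(d_val, plan, s_patch + 1)

    mcfg = model_cfg if model_cfg is not None else ModelConfig(base_channels=4)
    mcfg = replace(mcfg, seed=s_model)
    model = build_model(mcfg)

    tcfg = train_cfg if train_cfg is not None else TrainConfig(
        batch_size=4, epochs=10, lr=3e-3, early_stop_patience=10, seed=s_train
    )
    model, history = train(model, train_patches, val_patches, tcfg)

    raw = evaluate(model, d_test, plan)
    post = evaluate(model, d_test, plan,
                    postprocess=lambda m: largest_component_filter(m, "keep_largest"))
    return {
        "model": model,
        "history": history,
        "raw": raw,
        "post": post,
        "plan": plan,
        "test_set": d_test,
    }


def overfit_sanity_run(seed: int = 0, n_patches: int = 4, epochs: int = 60):
    """Fit a small-capacity model to a handful of patches used as both
    train and validation set; returns the final training-set Dice."""
    ss = np.random.SeedSequence([seed, 99])
    s1, s2, s3 = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]
    pcfg = PhantomConfig(seed=s1)
    data = [(zscore(v), m) for v, m in make_dataset(2, pcfg)]
    plan = SamplingPlan(patch=(32, 32, 32), step=(32, 32, 32),
                        n_random=2, threshold=0.005, seed=s2)
    patches = make_patch_sets(data, plan, s2)[:n_patches]
    model = build_model(ModelConfig(base_channels=4, dropout=0.0, seed=s3))
    tcfg = TrainConfig(batch_size=n_patches, epochs=epochs, lr=3e-3,
                       early_stop_patience=epochs, seed=s3)
    model, history = train(model, patches, patches, tcfg)
    dices = []
    for img, lab in patches:
        prob = predict_volume(model, img, plan)
        pred = binarize(prob)
        dices.append(metrics(confusion(pred.data, lab)).dice)
    return float(np.mean(dices)), history
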