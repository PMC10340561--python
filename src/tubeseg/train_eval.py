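"""Dice-loss training and segmentation metrics.

The loss is the soft Dice complement

    Dsc(g, p) = 2 sum(g_i p_i) / (sum(g_i^2) + sum(p_i^2) + eps)
    loss      = 1 - Dsc

computed on foreground probabilities; evaluation metrics use hard binary
masks and the confusion-count definitions

    Recall = TP/(TP+FN), Precision = TP/(TP+FP), Dice = 2TP/(2TP+FP+FN),
    IoU = TP/(TP+FP+FN)

Dice and IoU of a single confusion table are linked by J = D/(2-D), which
`dice_to_iou` exposes as a consistency utility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Tensor, no_grad
from .volume_io import LabelMask, ValidationError

EPS = 1e-6


@dataclass
class TrainConfig:
    batch_size: int = 8
    epochs: int = 200
    lr: float = 1e-3
    early_stop_patience: int = 50
    seed: int = 0
    val_fraction: float = 0.2

    def __post_init__(self):
        if self.lr <= 0:
            raise ValidationError("lr must be > 0")
        if self.early_stop_patience < 1:
            raise ValidationError("early_stop_patience must be >= 1")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValidationError("confusion counts must be non-negative")

    def __add__(self, other):
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP,
            self.TN + other.TN, self.FN + other.FN,
        )


@dataclass
class MetricsReport:
    precision: float
    recall: float
    dice: float
    iou: float
    aggregation: str = "single"


def dice_loss(pred, gt, eps: float = EPS):
    """Soft Dice loss on the foreground channel.

    pred: probabilities in [0,1] (Tensor or array); gt: binary labels of the
    same shape. Returns a Tensor when pred is a Tensor (differentiable),
    else a float.
    """
    is_tensor = isinstance(pred, Tensor)
    p = pred if is_tensor else Tensor(np.asarray(pred, dtype=np.float32))
    g_arr = gt.data if isinstance(gt, LabelMask) else np.asarray(gt)
    if p.shape != g_arr.shape:
        raise ValidationError(f"shape mismatch: pred {p.shape} vs gt {g_arr.shape}")
    g = Tensor(g_arr.astype(np.float32))
    num = (p * g).sum() * 2.0
    den = (p * p).sum() + (g * g).sum() + eps
    loss = 1.0 - num / den
    return loss if is_tensor else float(loss.item())


def _batches(n, batch_size, rng):
    idx = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield idx[i:i + batch_size]


def _epoch_loss(model, patches, cfg, opt=None, rng=None):
    total, count = 0.0, 0
    order = _batches(len(patches), cfg.batch_size, rng) if rng is not None else [
        np.arange(i, min(i + cfg.batch_size, len(patches)))
        for i in range(0, len(patches), cfg.batch_size)
    ]
    for idx in order:
        imgs = np.stack([patches[j][0] for j in idx])[:, None].astype(np.float32)
        labs = np.stack([patches[j][1] for j in idx]).astype(np.float32)
        if opt is None:
            with no_grad():
                prob = model(Tensor(imgs))
            loss_val = dice_loss(prob.data[:, 1], labs)
        else:
            prob = model(Tensor(imgs))
            loss = dice_loss(prob[:, 1], labs)
            loss_val = loss.item()
            if not np.isfinite(loss_val):
                raise RuntimeError(f"non-finite training loss: {loss_val}")
            loss.backward()
            opt.step()
            opt.zero_grad()
        total += loss_val * len(idx)
        count += len(idx)
    return total / max(count, 1)


def train(model, train_patches, val_patches, cfg: TrainConfig):
    """Adam / Dice-loss training with early stopping on validation loss.

    Early stopping: a counter increments on every epoch without improvement
    and training stops after the epoch where it exceeds the patience. The
    best-validation weights are restored before returning.

    Returns (model, history) with history a list of per-epoch dicts.
    """
    if not train_patches:
        raise ValidationError("no training patches")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    best_loss, best_state, stale = np.inf, None, 0
    history = []
    for epoch in range(1, cfg.epochs + 1):
        model.train()
        tr = _epoch_loss(model, train_patches, cfg, opt=opt, rng=rng)
        model.eval()
        va = _epoch_loss(model, val_patches, cfg) if val_patches else tr
        history.append({"epoch": epoch, "train_loss": tr, "val_loss": va})
        if va < best_loss - 1e-6:
            best_loss, stale = va, 0
            best_state = model.state_dict()
        else:
            stale += 1
            if stale > cfg.early_stop_patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def confusion(pred: LabelMask | np.ndarray, gt: LabelMask | np.ndarray,
              roi: LabelMask | None = None) -> ConfusionCounts:
    p = pred.data if isinstance(pred, LabelMask) else np.asarray(pred)
    g = gt.data if isinstance(gt, LabelMask) else np.asarray(gt)
    if p.shape != g.shape:
        raise ValidationError("pred/gt shape mismatch")
    for name, a in (("pred", p), ("gt", g)):
        if not np.isin(a, (0, 1)).all():
            raise ValidationError(f"{name} is not binary")
    if roi is not None:
        r = roi.data.astype(bool)
        p, g = p[r], g[r]
    p = p.astype(bool)
    g = g.astype(bool)
    return ConfusionCounts(
        TP=int((p & g).sum()), FP=int((p & ~g).sum()),
        TN=int((~p & ~g).sum()), FN=int((~p & g).sum()),
    )


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Precision/recall/Dice/IoU; all metrics are 1 when TP=FP=FN=0
    (nothing to find, nothing found)."""
    if c.TP == 0 and c.FP == 0 and c.FN == 0:
        return MetricsReport(1.0, 1.0, 1.0, 1.0)
    prec = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else 0.0
    rec = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    dice = 2 * c.TP / (2 * c.TP + c.FP + c.FN)
    iou = c.TP / (c.TP + c.FP + c.FN)
    return MetricsReport(prec, rec, dice, iou)


def dice_to_iou(d: float) -> float:
    """Jaccard index implied by a Dice score: J = D / (2 - D)."""
    if not (0.0 <= d <= 1.0):
        raise ValidationError("dice must be in [0, 1]")
    return d / (2.0 - d)


def evaluate(model, dataset, plan, postprocess=None, rois=None):
    """Per-image full-volume evaluation plus a pooled variant.

    dataset: list of (Volume, LabelMask) with z-scored volumes;
    postprocess: optional callable LabelMask -> LabelMask applied to each
    prediction; returns a dict with per-image metrics, their mean/std, and
    pooled metrics from summed confusion counts.
    """
    from .infer_postprocess import binarize, predict_volume

    if not dataset:
        raise ValidationError("empty dataset")
    per_image = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for i, (vol, gt) in enumerate(dataset):
        prob = predict_volume(model, vol, plan)
        pred = binarize(prob)
        if postprocess is not None:
            pred = postprocess(pred)
        roi = rois[i] if rois is not None else None
        c = confusion(pred, gt, roi)
        pooled = pooled + c
        per_image.append(metrics(c))
    names = ("precision", "recall", "dice", "iou")
    arr = {k: np.array([getattr(m, k) for m in per_image]) for k in names}
    return {
        "per_image": per_image,
        "mean": {k: float(v.mean()) for k, v in arr.items()},
        "std": {k: float(v.std()) for k, v in arr.items()},
        "pooled": metrics(pooled),
    }
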