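"""Training loop, cosine-annealed Adam, checkpointing and transfer learning.

The reference protocol trains with Adam (first-moment coefficient 0.9),
an initial learning rate of 1e-4 decayed by cosine annealing over the full
run, batch size 28 and 100 epochs, on images split 8:1:1 into
train/val/test. Transfer learning warm-starts all weights from a source
checkpoint and fine-tunes on the new soil/crop domain; a data-volume curve
re-runs the fine-tune on nested training subsets of increasing size.

Desk-scale experiments in the tests use much smaller images, sets and
epoch counts; the protocol itself is unchanged.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Adam
from .io_formats import ImageSample, LabelMask
from .losses import LossConfig, combined_loss_from_logits, one_hot
from .metrics import (
    ConfusionCounts,
    SegMetrics,
    compute_metrics,
    confusion_counts,
    evaluate_dataset,
)
from .network import ConfigurationError, ModelConfig, SegmentationNetwork, build_model


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 28
    lr0: float = 1e-4
    beta1: float = 0.9  # Adam first-moment coefficient ("momentum")
    beta2: float = 0.999
    eta_min: float = 0.0
    seed: int = 0
    deterministic: bool = True
    loss: LossConfig = field(default_factory=LossConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    input_size: tuple = (224, 224)
    stop_iou: float | None = None  # early stop once monitored IoU reaches this

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        h, w = self.input_size
        if h % 32 or w % 32:
            raise ValueError(f"input_size must be divisible by 32, got {self.input_size}")


@dataclass
class Checkpoint:
    weights: dict
    model_config: ModelConfig
    optimizer_state: dict
    epoch: int
    history: list
    provenance: dict

    def best_val_iou(self) -> float:
        ious = [h["val_iou"] for h in self.history if h.get("val_iou") is not None]
        return max(ious) if ious else float("nan")


def cosine_lr(epoch: int, cfg: TrainConfig) -> float:
    """Cosine-annealed learning rate; epoch 0 -> lr0, final epoch -> eta_min."""
    if cfg.epochs == 0:
        return cfg.lr0
    return cfg.eta_min + (cfg.lr0 - cfg.eta_min) * (
        1.0 + np.cos(np.pi * epoch / cfg.epochs)
    ) / 2.0


# ------------------------------------------------------------ preprocessing


def _fit_to(arr: np.ndarray, size: tuple, pad_value=0):
    """Centre crop/pad a (H, W) or (H, W, C) array to `size`."""
    th, tw = size
    h, w = arr.shape[:2]
    # crop
    if h > th:
        top = (h - th) // 2
        arr = arr[top : top + th]
    if w > tw:
        left = (w - tw) // 2
        arr = arr[:, left : left + tw]
    # pad
    h, w = arr.shape[:2]
    if h < th or w < tw:
        pads = [((th - h) // 2, th - h - (th - h) // 2),
                ((tw - w) // 2, tw - w - (tw - w) // 2)]
        pads += [(0, 0)] * (arr.ndim - 2)
        arr = np.pad(arr, pads, constant_values=pad_value)
    return arr


def samples_to_arrays(samples, input_size):
    """Stack ImageSamples into (n,3,H,W) float inputs and (n,H,W) int masks."""
    xs, ys = [], []
    for s in samples:
        img = _fit_to(s.image, input_size)
        msk = _fit_to(s.mask.data, input_size)
        xs.append(img.transpose(2, 0, 1).astype(np.float32) / 255.0)
        ys.append(msk.astype(np.int64))
    return np.stack(xs), np.stack(ys)


# -------------------------------------------------------------- checkpoints


def _config_hash(cfg: TrainConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def save_checkpoint(ckpt: Checkpoint, path) -> None:
    meta = {
        "model_config": asdict(ckpt.model_config),
        "epoch": ckpt.epoch,
        "history": ckpt.history,
        "provenance": ckpt.provenance,
    }
    arrays = {f"w::{k}": v for k, v in ckpt.weights.items()}
    arrays.update({f"opt::{k}": np.asarray(v) for k, v in ckpt.optimizer_state.items()})
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> Checkpoint:
    p = str(path)
    if not Path(p).exists() and Path(p + ".npz").exists():
        p += ".npz"
    try:
        with np.load(p) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            weights = {k[3:]: data[k] for k in data.files if k.startswith("w::")}
            opt = {k[5:]: data[k] for k in data.files if k.startswith("opt::")}
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise IOError(f"cannot load checkpoint {path}: {exc}") from exc
    return Checkpoint(
        weights=weights,
        model_config=ModelConfig(**{**meta["model_config"],
                                    "psa_kernel_sizes": tuple(meta["model_config"]["psa_kernel_sizes"]),
                                    "psa_group_counts": tuple(meta["model_config"]["psa_group_counts"])}),
        optimizer_state=opt,
        epoch=meta["epoch"],
        history=meta["history"],
        provenance=meta["provenance"],
    )


def network_from_checkpoint(ckpt: Checkpoint) -> SegmentationNetwork:
    net = build_model(ckpt.model_config, seed=ckpt.provenance.get("seed", 0))
    net.load_state_dict(ckpt.weights)
    return net


# ------------------------------------------------------------------ fitting


def _iter_modules(module):
    yield module
    for _, child in module._children():
        yield from _iter_modules(child)


def recalibrate_batchnorm(net: SegmentationNetwork, x: np.ndarray, batch_size: int):
    """Set BatchNorm running statistics to the training-set average.

    Small batches make the default exponentially-averaged statistics noisy
    and stale, which can wreck inference-mode predictions; re-estimating
    them with one pass over the training data is the standard remedy.
    """
    from .network import BatchNorm2d

    bns = [m for m in _iter_modules(net) if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    saved_momentum = [bn.momentum for bn in bns]
    was_training = net.training
    net.train()
    with ad.no_grad():
        for i, start in enumerate(range(0, len(x), batch_size)):
            for bn in bns:  # cumulative average over batches
                bn.momentum = i / (i + 1.0)
            net(x[start : start + batch_size])
    for bn, m0 in zip(bns, saved_momentum):
        bn.momentum = m0
    net.train(was_training)


def _evaluate(net: SegmentationNetwork, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> SegMetrics:
    preds = []
    for i in range(0, len(x), batch_size):
        p = net.predict_proba(x[i : i + batch_size])
        preds.append(p.argmax(axis=1))
    pred = np.concatenate(preds)
    pairs = [(pred[i], y[i]) for i in range(len(y))]
    return evaluate_dataset(pairs, mode="micro")


def _fit(net, train_set, val_set, cfg: TrainConfig, provenance: dict) -> Checkpoint:
    if not train_set:
        raise ValueError("training set is empty")
    xtr, ytr = samples_to_arrays(train_set, cfg.input_size)
    if val_set:
        xval, yval = samples_to_arrays(val_set, cfg.input_size)
    else:
        # no validation set: monitor training-set metrics, pooled from the
        # training forward passes themselves (no extra inference pass)
        xval = yval = None
    gtr = one_hot(ytr, cfg.model.num_classes)

    opt = Adam(net.parameters(), lr=cfg.lr0, beta1=cfg.beta1, beta2=cfg.beta2)
    rng = np.random.default_rng(cfg.seed)
    history = []
    best = {"iou": -1.0, "weights": None, "epoch": -1}
    n = len(xtr)
    bs = min(cfg.batch_size, n)

    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg)
        opt.lr = lr
        net.train()
        order = rng.permutation(n)
        losses = []
        pooled = ConfusionCounts(0, 0, 0, 0)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            logits = net(xtr[idx])
            loss = combined_loss_from_logits(logits, gtr[idx], cfg.loss)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value} at epoch {epoch} (lr={lr:.3g}); aborting"
                )
            pred = logits.data.argmax(axis=1)
            for j, k in enumerate(idx):
                pooled = pooled + confusion_counts(pred[j], ytr[k])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(value)
        if xval is not None:
            recalibrate_batchnorm(net, xtr, bs)
            val = _evaluate(net, xval, yval, bs)
        else:
            val = compute_metrics(pooled)
        record = {
            "epoch": epoch,
            "lr": float(lr),
            "train_loss": float(np.mean(losses)),
            "val_pa": val.pixel_accuracy,
            "val_iou": val.iou,
            "val_f1": val.f1,
        }
        history.append(record)
        if val.iou > best["iou"]:
            best = {"iou": val.iou, "weights": net.state_dict(), "epoch": epoch}
        if cfg.stop_iou is not None and val.iou >= cfg.stop_iou:
            break

    if cfg.epochs and xval is None:
        # inference-mode statistics for the saved weights
        recalibrate_batchnorm(net, xtr, bs)
    return Checkpoint(
        weights=net.state_dict(),
        model_config=cfg.model,
        optimizer_state=opt.state_dict(),
        epoch=len(history),
        history=history,
        provenance={
            **provenance,
            "seed": cfg.seed,
            "config_hash": _config_hash(cfg),
            "best_epoch": best["epoch"],
            "best_val_iou": best["iou"],
        },
    )


def train(train_set, val_set, cfg: TrainConfig) -> Checkpoint:
    """Train a fresh network; returns the final checkpoint with history.

    The best-validation-IoU weights are recorded in provenance
    (``best_epoch``/``best_val_iou``); the returned weights are final-epoch.
    """
    net = build_model(cfg.model, seed=cfg.seed)
    return _fit(net, train_set, val_set, cfg, provenance={"transfer": False})


def _topology(mc: ModelConfig) -> dict:
    t = {
        "encoder": mc.encoder,
        "use_psa": mc.use_psa,
        "in_channels": mc.in_channels,
        "num_classes": mc.num_classes,
    }
    if mc.encoder == "plain":
        t["base_width"] = mc.base_width
    if mc.use_psa:
        t.update(
            psa_branches=mc.psa_branches,
            psa_kernel_sizes=tuple(mc.psa_kernel_sizes),
            psa_group_counts=tuple(mc.psa_group_counts),
            se_reduction=mc.se_reduction,
        )
    return t


def finetune(base: Checkpoint, new_train_set, new_val_set, cfg: TrainConfig) -> Checkpoint:
    """Warm-start all weights from `base` and train on the new domain."""
    t_base, t_new = _topology(base.model_config), _topology(cfg.model)
    diffs = [k for k in set(t_base) | set(t_new) if t_base.get(k) != t_new.get(k)]
    if diffs:
        raise ConfigurationError(
            f"checkpoint topology incompatible with cfg.model; differing fields: {sorted(diffs)}"
        )
    net = build_model(cfg.model, seed=cfg.seed)
    net.load_state_dict(base.weights)
    return _fit(net, new_train_set, new_val_set, cfg, provenance={"transfer": True})


def epochs_to_stability(history, tolerance: float = 0.005) -> int:
    """First epoch after which val IoU stays within `tolerance` of its final value."""
    ious = np.array([h["val_iou"] for h in history])
    if len(ious) == 0:
        return 0
    stable = np.abs(ious - ious[-1]) <= tolerance
    for e in range(len(ious)):
        if stable[e:].all():
            return e
    return len(ious) - 1


def data_volume_curve(base: Checkpoint, pool, sizes, test_set, cfg: TrainConfig):
    """Fine-tune on nested subsets of `pool` and evaluate on a fixed test set.

    Returns a list of rows {size, metrics, epochs_to_stability}. Subsets are
    nested (each extends the previous) so rows are comparable.
    """
    sizes = list(sizes)
    if sorted(sizes) != sizes:
        raise ValueError("sizes must be ascending")
    if sizes and sizes[-1] > len(pool):
        raise ValueError(f"size {sizes[-1]} exceeds pool of {len(pool)}")
    order = np.random.default_rng(cfg.seed).permutation(len(pool))
    xte, yte = samples_to_arrays(test_set, cfg.input_size)
    rows = []
    for size in sizes:
        subset = [pool[i] for i in order[:size]]
        ckpt = finetune(base, subset, None, cfg)
        net = network_from_checkpoint(ckpt)
        m = _evaluate(net, xte, yte, min(cfg.batch_size, max(len(xte), 1)))
        rows.append(
            {
                "size": size,
                "metrics": m,
                "epochs_to_stability": epochs_to_stability(ckpt.history),
            }
        )
    return rows


def predict(ckpt, image) -> LabelMask:
    """Segment one RGB image (H, W, 3); output mask matches input size.

    The image is padded to the next multiple of 32 for the forward pass and
    the prediction is cropped back; per-pixel class = argmax of softmax.
    """
    net = ckpt if isinstance(ckpt, SegmentationNetwork) else network_from_checkpoint(ckpt)
    image = np.asarray(image, dtype=np.uint8)
    h, w = image.shape[:2]
    th = int(np.ceil(max(h, 32) / 32) * 32)
    tw = int(np.ceil(max(w, 32) / 32) * 32)
    padded = _fit_to(image, (th, tw))
    x = padded.transpose(2, 0, 1).astype(np.float32)[None] / 255.0
    proba = net.predict_proba(x)
    pred = proba.argmax(axis=1)[0].astype(np.uint8)
    top, left = (th - h) // 2, (tw - w) // 2
    return LabelMask(pred[top : top + h, left : left + w], num_classes=2)
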