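"""Combined Dice-Focal objective for class-imbalanced root segmentation.

The Dice side works on per-class soft confusion counts over a training
batch of N pixels:

    TP_p(c) = sum_n p_n(c) g_n(c)
    FN_p(c) = sum_n (1 - p_n(c)) g_n(c)
    FP_p(c) = sum_n p_n(c) (1 - g_n(c))

    L_Dice = C - sum_c TP_p(c) / (TP_p(c) + a FN_p(c) + b FP_p(c) + eps)

with a (alpha) weighting false negatives and b (beta) false positives;
a = b = 0.5 recovers the classic soft Dice loss. The focal side has two
modes. ``canonical`` is the standard focal loss,

    L_fl = (1/N) sum_c sum_n g_n(c) (1 - p_n(c))^gamma (-log(p_n(c) + eps)),

which vanishes at p = g and grows as predictions worsen. ``as_printed``
evaluates the bare sum  -(1/N) sum_c sum_n g_n(c) (1 - p_n(c)), a
nonpositive quantity that *decreases* as predictions worsen (0 at p = g,
-1 at p = 1-g); it is retained for auditability but cannot serve as a
minimization objective, which is why ``canonical`` is the default.

All functions accept either plain numpy arrays or autodiff tensors; the
tensor path is what the training loop differentiates through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, softmax

FOCAL_MODES = ("canonical", "as_printed")


@dataclass
class LossConfig:
    alpha: float = 0.5  # false-negative weight in the Dice denominator
    beta: float = 0.5  # false-positive weight
    focal_mode: str = "canonical"
    gamma: float = 2.0  # canonical focal exponent
    focal_weight: float = 1.0
    epsilon: float = 1e-6

    def __post_init__(self):
        if self.focal_mode not in FOCAL_MODES:
            raise ValueError(
                f"focal_mode must be one of {FOCAL_MODES}, got {self.focal_mode!r}"
            )
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("alpha, beta and gamma must be nonnegative")


@dataclass
class SoftConfusion:
    """Per-class soft counts; entries are length-C vectors."""

    tp: np.ndarray
    fn: np.ndarray
    fp: np.ndarray


def _check_field(p, g):
    pshape = p.shape if hasattr(p, "shape") else np.shape(p)
    gshape = g.shape if hasattr(g, "shape") else np.shape(g)
    if tuple(pshape) != tuple(gshape):
        raise ValueError(f"probability field {tuple(pshape)} and one-hot truth "
                         f"{tuple(gshape)} differ in shape")
    if len(pshape) != 4:
        raise ValueError(f"expected (batch, C, H, W) fields, got {tuple(pshape)}")


def one_hot(mask: np.ndarray, num_classes: int = 2) -> np.ndarray:
    """One-hot encode an integer mask batch (n, H, W) -> (n, C, H, W)."""
    mask = np.asarray(mask)
    if mask.ndim == 2:
        mask = mask[None]
    out = np.zeros((mask.shape[0], num_classes) + mask.shape[1:], np.float32)
    for c in range(num_classes):
        out[:, c] = mask == c
    return out


def soft_confusion(p, g) -> SoftConfusion:
    """Soft TP/FN/FP per class, summed over all pixels of the batch."""
    _check_field(p, g)
    ax = (0, 2, 3)
    tp = (p * g).sum(axis=ax)
    fn = ((1.0 - p) * g).sum(axis=ax)
    fp = (p * (1.0 - g)).sum(axis=ax)
    return SoftConfusion(tp=tp, fn=fn, fp=fp)


def dice_term(sc: SoftConfusion, cfg: LossConfig):
    """Tversky-style Dice loss from soft counts; value in [0, C].

    A class entirely absent from both prediction and truth (all three soft
    counts zero) scores a perfect overlap ratio of 1, so a perfect
    prediction yields 0 even when one class is missing from the batch.
    """
    num_classes = sc.tp.shape[0]
    counts = [c.data if isinstance(c, Tensor) else np.asarray(c)
              for c in (sc.tp, sc.fn, sc.fp)]
    absent = (sum(counts) == 0).astype(np.float32)
    eps = cfg.epsilon * (1.0 - absent)  # absent classes score exactly 1
    ratio = (sc.tp + absent) / (
        sc.tp + cfg.alpha * sc.fn + cfg.beta * sc.fp + absent + eps
    )
    return float(num_classes) - ratio.sum()


def focal_term(p, g, cfg: LossConfig):
    """Focal loss in the configured mode (see module docstring)."""
    _check_field(p, g)
    n_pixels = float(np.prod(p.shape) / p.shape[1])  # batch * H * W
    if cfg.focal_mode == "as_printed":
        total = (g * (1.0 - p)).sum()
        return -(1.0 / n_pixels) * total
    # canonical: (1/N) sum g (1-p)^gamma (-log(p + eps))
    logp = (p + cfg.epsilon).log() if isinstance(p, Tensor) else np.log(p + cfg.epsilon)
    total = (g * (1.0 - p) ** cfg.gamma * (-1.0 * logp)).sum()
    return (1.0 / n_pixels) * total


def combined_loss(p, g, cfg: LossConfig | None = None):
    """Dice term + focal_weight x focal term."""
    cfg = cfg or LossConfig()
    return dice_term(soft_confusion(p, g), cfg) + cfg.focal_weight * focal_term(p, g, cfg)


def combined_loss_from_logits(logits: Tensor, g: np.ndarray, cfg: LossConfig | None = None):
    """Differentiable loss from raw network logits and one-hot ground truth."""
    p = softmax(logits, axis=1)
    return combined_loss(p, g, cfg)
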