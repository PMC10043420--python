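"""Oracle tests for the Dice-Focal objective.

Expected values are hand evaluations of the soft-count definitions on
micro-examples small enough to do on paper.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rhizoseg import _autodiff as ad
from rhizoseg._autodiff import Tensor
from rhizoseg.losses import (
    LossConfig,
    combined_loss,
    combined_loss_from_logits,
    dice_term,
    focal_term,
    one_hot,
    soft_confusion,
)


def field_all_class1(p1: float, n=4):
    """n pixels, all truly class 1, predicted class-1 probability p1."""
    p = np.empty((1, 2, 1, n), np.float32)
    p[0, 1] = p1
    p[0, 0] = 1.0 - p1
    g = np.zeros_like(p)
    g[0, 1] = 1.0
    return p, g


def random_field(rng, n=32, c=2):
    logits = rng.normal(size=(1, c, 4, n // 4)).astype(np.float32)
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    p = e / e.sum(axis=1, keepdims=True)
    labels = rng.integers(0, c, size=(1, 4, n // 4))
    return p, one_hot(labels, c)


# ------------------------------------------------------------ soft confusion


def test_soft_confusion_uniform_half_example():
    # 4 pixels all true class 1 at p=0.5: TP1=2, FN1=2, FP1=0; TP0=0, FP0=2
    p, g = field_all_class1(0.5)
    sc = soft_confusion(p, g)
    np.testing.assert_allclose(sc.tp, [0.0, 2.0], atol=1e-6)
    np.testing.assert_allclose(sc.fn, [0.0, 2.0], atol=1e-6)
    np.testing.assert_allclose(sc.fp, [2.0, 0.0], atol=1e-6)


def test_soft_confusion_perfect_and_worst():
    p, g = field_all_class1(1.0)
    sc = soft_confusion(p, g)
    np.testing.assert_allclose(sc.fn, 0, atol=1e-6)
    np.testing.assert_allclose(sc.fp, 0, atol=1e-6)
    np.testing.assert_allclose(sc.tp, g.sum(axis=(0, 2, 3)), atol=1e-6)
    # worst case p = 1 - g
    sc = soft_confusion(1.0 - g, g)
    np.testing.assert_allclose(sc.tp, 0, atol=1e-6)
    np.testing.assert_allclose(sc.fn, g.sum(axis=(0, 2, 3)), atol=1e-6)


def test_soft_confusion_conserves_truth_mass(rng):
    p, g = random_field(rng)
    sc = soft_confusion(p, g)
    np.testing.assert_allclose(sc.tp + sc.fn, g.sum(axis=(0, 2, 3)), rtol=1e-6)


def test_soft_confusion_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        soft_confusion(np.zeros((1, 2, 2, 2)), np.zeros((1, 2, 2, 3)))


# ---------------------------------------------------------------- dice term


def test_dice_perfect_prediction_is_zero():
    p, g = field_all_class1(1.0)
    assert abs(dice_term(soft_confusion(p, g), LossConfig())) < 1e-5


def test_dice_worst_case_is_class_count():
    p, g = field_all_class1(0.0)
    assert abs(dice_term(soft_confusion(p, g), LossConfig()) - 2.0) < 1e-5


def test_dice_uniform_half_hand_value():
    # class 1 ratio: 2/(2+0.5*2+0) = 2/3; class 0 ratio: 0 -> loss 2 - 2/3
    p, g = field_all_class1(0.5)
    cfg = LossConfig(alpha=0.5, beta=0.5)
    assert abs(dice_term(soft_confusion(p, g), cfg) - 4.0 / 3.0) < 1e-6


def test_dice_equals_classic_soft_dice_at_half_weights(rng):
    for _ in range(5):
        p, g = random_field(rng)
        sc = soft_confusion(p, g)
        classic = sum(
            1.0 - 2.0 * sc.tp[c] / (2.0 * sc.tp[c] + sc.fn[c] + sc.fp[c] + 1e-6)
            for c in range(2)
        )
        ours = dice_term(sc, LossConfig(alpha=0.5, beta=0.5, epsilon=5e-7))
        assert abs(float(ours) - float(classic)) < 1e-5


# --------------------------------------------------------------- focal term


def test_focal_zero_at_perfect_prediction_both_modes():
    p, g = field_all_class1(1.0)
    assert abs(focal_term(p, g, LossConfig(focal_mode="canonical"))) < 1e-4
    assert abs(focal_term(p, g, LossConfig(focal_mode="as_printed"))) < 1e-6


def test_focal_as_printed_is_minus_one_at_worst_case():
    p, g = field_all_class1(0.0)
    assert abs(focal_term(p, g, LossConfig(focal_mode="as_printed")) + 1.0) < 1e-6


def test_focal_canonical_gamma0_uniform_is_log2():
    p, g = field_all_class1(0.5)
    got = focal_term(p, g, LossConfig(focal_mode="canonical", gamma=0.0))
    assert abs(got - np.log(2.0)) < 1e-4


def test_focal_mode_validated():
    with pytest.raises(ValueError, match="focal_mode"):
        LossConfig(focal_mode="typo")


# ------------------------------------------------------------ combined loss


def test_combined_zero_at_perfect_and_positive_otherwise(rng):
    p, g = field_all_class1(1.0)
    assert abs(combined_loss(p, g)) < 1e-4
    for _ in range(5):
        p, g = random_field(rng)
        assert combined_loss(p, g) > 0.0


def test_combined_decreases_toward_truth():
    p_true = field_all_class1(1.0)[1].copy()
    g = p_true
    p_worst = 1.0 - g
    values = []
    for t in np.linspace(0.0, 0.98, 10):
        p = (1 - t) * p_worst + t * g
        p = np.clip(p, 1e-6, 1.0)
        values.append(float(combined_loss(p, g)))
    assert all(a > b for a, b in zip(values, values[1:]))


def test_loss_is_permutation_invariant(rng):
    p, g = random_field(rng, n=64)
    perm = rng.permutation(64)
    pp = p.reshape(1, 2, 64)[:, :, perm].reshape(1, 2, 4, 16)
    gp = g.reshape(1, 2, 64)[:, :, perm].reshape(1, 2, 4, 16)
    for mode in ("canonical", "as_printed"):
        cfg = LossConfig(focal_mode=mode)
        assert np.isclose(float(combined_loss(p, g, cfg)),
                          float(combined_loss(pp, gp, cfg)), rtol=1e-5)


def test_gradient_descent_drives_prediction_to_truth(rng):
    """Plain GD on softmax logits recovers the mask on a 16x16 toy field."""
    labels = (rng.random((1, 16, 16)) < 0.15).astype(int)
    g = one_hot(labels, 2)
    logits = Tensor(rng.normal(size=(1, 2, 16, 16)).astype(np.float32),
                    requires_grad=True)
    cfg = LossConfig()
    for _ in range(200):
        loss = combined_loss_from_logits(logits, g, cfg)
        logits.zero_grad()
        loss.backward()
        logits.data -= 20.0 * logits.grad
    pred = logits.data.argmax(axis=1)
    assert (pred == labels).all()


@given(st.integers(0, 10_000))
def test_combined_loss_from_logits_matches_probability_path(seed):
    rng = np.random.default_rng(seed)
    logits_np = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
    g = one_hot(rng.integers(0, 2, (1, 4, 4)), 2)
    via_logits = combined_loss_from_logits(Tensor(logits_np), g).item()
    e = np.exp(logits_np - logits_np.max(axis=1, keepdims=True))
    p = e / e.sum(axis=1, keepdims=True)
    assert np.isclose(via_logits, float(combined_loss(p, g)), rtol=1e-5, atol=1e-6)
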