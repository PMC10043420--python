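"""Training loop, schedule, checkpointing and transfer-learning mechanics.

Runs use a narrow plain U-Net on 64x64 synthetic frames so each fit takes
seconds; the optimization protocol itself (Adam, cosine annealing,
Dice-Focal loss) is the same one used at full scale.
"""

import dataclasses

import numpy as np
import pytest

import rhizoseg as rz
from rhizoseg.network import ConfigurationError
from rhizoseg.training import (
    _fit_to,
    epochs_to_stability,
    network_from_checkpoint,
    recalibrate_batchnorm,
    samples_to_arrays,
)


def tiny_cfg(small_unet, **over):
    defaults = dict(
        epochs=2, batch_size=4, lr0=1e-3, seed=0,
        model=small_unet(), input_size=(64, 64),
    )
    defaults.update(over)
    return rz.TrainConfig(**defaults)


# ---------------------------------------------------------------- schedule


def test_cosine_schedule_endpoints_and_midpoint(small_unet):
    cfg = tiny_cfg(small_unet, epochs=100, lr0=1e-4)
    assert rz.cosine_lr(0, cfg) == pytest.approx(1e-4)
    assert rz.cosine_lr(100, cfg) == pytest.approx(0.0, abs=1e-12)
    assert rz.cosine_lr(50, cfg) == pytest.approx(5e-5)
    eta = tiny_cfg(small_unet, epochs=10, lr0=1e-3, eta_min=1e-5)
    assert rz.cosine_lr(10, eta) == pytest.approx(1e-5)
    assert rz.cosine_lr(0, tiny_cfg(small_unet, epochs=0)) == pytest.approx(1e-3)


def test_paper_scale_protocol_is_representable(small_unet):
    """The reference setup (batch 28, 100 epochs, lr 1e-4) round-trips."""
    cfg = rz.TrainConfig(epochs=100, batch_size=28, lr0=1e-4, beta1=0.9,
                         model=small_unet())
    assert (cfg.epochs, cfg.batch_size, cfg.lr0, cfg.beta1) == (100, 28, 1e-4, 0.9)
    ckpt = rz.train(  # epochs=0: config echo without optimization
        [rz.generate_sample(rz.SyntheticConfig(canvas=(64, 64)), seed=0).sample],
        None,
        dataclasses.replace(cfg, epochs=0, input_size=(64, 64)),
    )
    assert ckpt.provenance["seed"] == cfg.seed
    assert "config_hash" in ckpt.provenance


# -------------------------------------------------------------- preprocessing


def test_fit_to_crops_and_pads_centrally():
    img = np.arange(36, dtype=np.uint8).reshape(6, 6)
    cropped = _fit_to(img, (4, 4))
    np.testing.assert_array_equal(cropped, img[1:5, 1:5])
    padded = _fit_to(img, (8, 8))
    assert padded.shape == (8, 8)
    np.testing.assert_array_equal(padded[1:7, 1:7], img)


# ------------------------------------------------------------------ fitting


def test_zero_epochs_returns_initial_weights(tiny_samples, small_unet):
    cfg = tiny_cfg(small_unet, epochs=0)
    ckpt = rz.train(tiny_samples[:2], None, cfg)
    assert ckpt.history == [] and ckpt.epoch == 0
    init = rz.build_model(cfg.model, seed=cfg.seed).state_dict()
    for k, v in ckpt.weights.items():
        np.testing.assert_array_equal(v, init[k])


def test_training_is_reproducible(tiny_samples, small_unet):
    cfg = tiny_cfg(small_unet, epochs=2)
    h1 = rz.train(tiny_samples[:4], tiny_samples[4:], cfg).history
    h2 = rz.train(tiny_samples[:4], tiny_samples[4:], cfg).history
    assert h1 == h2
    assert [h["epoch"] for h in h1] == [0, 1]
    assert all(np.isfinite(h["train_loss"]) for h in h1)


def test_loss_decreases_over_short_overfit(tiny_samples, small_unet):
    cfg = tiny_cfg(small_unet, epochs=12, batch_size=6)
    hist = rz.train(tiny_samples, None, cfg).history
    losses = [h["train_loss"] for h in hist]
    n10 = max(1, len(losses) // 10)
    assert np.median(losses[-2 * n10 :]) < np.median(losses[: 2 * n10])


def test_empty_train_set_rejected(small_unet):
    with pytest.raises(ValueError, match="empty"):
        rz.train([], None, tiny_cfg(small_unet))


def test_nan_loss_aborts_with_diagnostics(tiny_samples, small_unet):
    cfg = tiny_cfg(small_unet, lr0=np.inf, epochs=3)
    with pytest.raises(RuntimeError, match="epoch"):
        rz.train(tiny_samples[:4], None, cfg)


# -------------------------------------------------------------- checkpoints


def test_checkpoint_round_trip_preserves_predictions(tiny_samples, small_unet, tmp_path):
    cfg = tiny_cfg(small_unet, epochs=1)
    ckpt = rz.train(tiny_samples[:4], None, cfg)
    before = rz.predict(ckpt, tiny_samples[0].image).data
    rz.save_checkpoint(ckpt, tmp_path / "model.npz")
    again = rz.load_checkpoint(tmp_path / "model.npz")
    assert again.model_config == ckpt.model_config
    assert again.history == ckpt.history
    np.testing.assert_array_equal(rz.predict(again, tiny_samples[0].image).data, before)


def test_checkpoint_load_error(tmp_path):
    (tmp_path / "bad.npz").write_bytes(b"not a checkpoint")
    with pytest.raises(IOError):
        rz.load_checkpoint(tmp_path / "bad.npz")


# ----------------------------------------------------------------- transfer


def test_finetune_zero_epochs_keeps_base_weights(tiny_samples, small_unet):
    base = rz.train(tiny_samples[:4], None, tiny_cfg(small_unet, epochs=1))
    ft = rz.finetune(base, tiny_samples[4:], None, tiny_cfg(small_unet, epochs=0))
    for k, v in ft.weights.items():
        np.testing.assert_array_equal(v, base.weights[k])
    assert ft.provenance["transfer"] is True


def test_finetune_rejects_topology_mismatch(tiny_samples, small_unet):
    base = rz.train(tiny_samples[:4], None, tiny_cfg(small_unet, epochs=0))
    other = tiny_cfg(small_unet, model=rz.ModelConfig(variant="unet", base_width=16))
    with pytest.raises(ConfigurationError, match="base_width"):
        rz.finetune(base, tiny_samples[:2], None, other)


def test_data_volume_curve_rows(tiny_samples, small_unet):
    base = rz.train(tiny_samples[:2], None, tiny_cfg(small_unet, epochs=1))
    rows = rz.data_volume_curve(
        base, tiny_samples[2:], [2, 4], tiny_samples[:2],
        tiny_cfg(small_unet, epochs=1),
    )
    assert [r["size"] for r in rows] == [2, 4]
    for r in rows:
        assert 0.0 <= r["metrics"].iou <= 1.0
        assert 0 <= r["epochs_to_stability"] <= 1
    with pytest.raises(ValueError, match="exceeds"):
        rz.data_volume_curve(base, tiny_samples[2:], [99], tiny_samples[:2],
                             tiny_cfg(small_unet))


def test_epochs_to_stability_definition():
    hist = [{"val_iou": v} for v in (0.1, 0.5, 0.9, 0.902, 0.899, 0.9)]
    assert epochs_to_stability(hist, tolerance=0.005) == 2
    assert epochs_to_stability([], tolerance=0.005) == 0
    assert epochs_to_stability(hist, tolerance=1.0) == 0


# ----------------------------------------------------------------- predict


def test_predict_contract_on_odd_sized_image(tiny_samples, small_unet):
    ckpt = rz.train(tiny_samples[:2], None, tiny_cfg(small_unet, epochs=1))
    img = tiny_samples[0].image[:50, :61]  # not divisible by 32
    mask = rz.predict(ckpt, img)
    assert mask.shape == (50, 61)
    assert set(np.unique(mask.data)) <= {0, 1}


def test_batchnorm_recalibration_changes_running_stats(tiny_samples, small_unet):
    net = rz.build_model(small_unet(), seed=0)
    x, _ = samples_to_arrays(tiny_samples, (64, 64))
    bn = net.encoder.stages[0].block1.bn
    before = bn.running_mean.copy()
    recalibrate_batchnorm(net, x, batch_size=3)
    assert not np.allclose(bn.running_mean, before)
    assert bn.momentum == 0.9  # restored afterwards
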