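"""Architecture contracts: shapes, attention normalization, gradient flow."""

import numpy as np
import pytest

import rhizoseg as rz
from rhizoseg import _autodiff as ad
from rhizoseg.losses import combined_loss_from_logits, one_hot
from rhizoseg.network import (
    ConfigurationError,
    ModelConfig,
    PSABlock,
    build_model,
)


def small_psa_unet(width=32):
    # narrower PSA grouping so the attention block fits the reduced widths
    return ModelConfig(variant="p_unet", base_width=width,
                       psa_group_counts=(1, 2, 4, 8))


# ------------------------------------------------------------------- shapes


@pytest.mark.parametrize("h,w", [(64, 64), (96, 64), (128, 128)])
@pytest.mark.parametrize("batch", [1, 2])
def test_shape_contract_small_unet(small_unet, h, w, batch, rng):
    net = build_model(small_unet(), seed=0)
    y = net(rng.random((batch, 3, h, w)).astype(np.float32))
    assert y.shape == (batch, 2, h, w)


def test_indivisible_spatial_dims_error(small_unet, rng):
    net = build_model(small_unet(), seed=0)
    with pytest.raises(ValueError, match="32"):
        net(rng.random((1, 3, 100, 100)).astype(np.float32))


def test_plain_encoder_deepest_map_is_one_sixteenth(small_unet, rng):
    """A 224x224 input pools down to a 14x14 deepest feature map."""
    net = build_model(small_unet(), seed=0)
    x = ad.Tensor(rng.random((1, 3, 224, 224)).astype(np.float32))
    feats = net.encoder(x.transpose(0, 2, 3, 1))
    spatial = [f.shape[1:3] for f in feats]
    assert spatial == [(224, 224), (112, 112), (56, 56), (28, 28), (14, 14)]


def test_resnet_encoder_stride_and_width_table(rng):
    net = build_model(ModelConfig(variant="r_unet"), seed=0)
    x = ad.Tensor(rng.random((1, 3, 64, 64)).astype(np.float32))
    feats = net.encoder(x.transpose(0, 2, 3, 1))
    shapes = [tuple(f.shape[1:]) for f in feats]
    assert shapes == [
        (32, 32, 64), (16, 16, 256), (8, 8, 512), (4, 4, 1024), (2, 2, 2048),
    ]


def test_r_unet_and_unet_decoders_have_same_topology():
    """Same stage count and spatial behaviour; only channel widths differ."""
    plain = build_model(ModelConfig(variant="unet"), seed=0)
    res = build_model(ModelConfig(variant="r_unet"), seed=0)
    assert len(plain.decoder) == len(res.decoder) == 4
    plain_cat = [s.convs.block1.conv.weight.shape[2] for s in plain.decoder]
    res_cat = [s.convs.block1.conv.weight.shape[2] for s in res.decoder]
    # skip-concatenation widths enumerated from the stride/width tables
    assert plain_cat == [1024, 512, 256, 128]
    assert res_cat == [2048, 1024, 512, 128]
    assert plain.final_up is None and res.final_up is not None


def test_d_unet_shares_unet_topology():
    a = build_model(ModelConfig(variant="unet"), seed=0)
    b = build_model(ModelConfig(variant="d_unet"), seed=0)
    assert [k for k, _ in a.named_parameters()] == [k for k, _ in b.named_parameters()]
    assert not a.psa_blocks() and not b.psa_blocks()


def test_pru_net_has_one_psa_block_per_decoder_stage():
    net = build_model(ModelConfig(variant="pru_net"), seed=0)
    assert len(net.psa_blocks()) == 4
    assert net.num_parameters() > 0


# ---------------------------------------------------------------------- PSA


def test_psa_preserves_shape_and_normalizes_weights(rng):
    cfg = ModelConfig(variant="pru_net")
    block = PSABlock(np.random.default_rng(0), 128, cfg)
    x = ad.Tensor(rng.random((2, 8, 8, 128)).astype(np.float32))
    y = block(x)
    assert y.shape == x.shape
    w = block.branch_weights(x)  # (n, S, C/S)
    np.testing.assert_allclose(w.sum(axis=1), 1.0, rtol=1e-5)


def test_psa_uniform_weights_when_se_logits_identical(rng):
    cfg = ModelConfig(variant="pru_net")
    block = PSABlock(np.random.default_rng(0), 128, cfg)
    for se in block.se_heads:  # zero SE heads -> identical (zero) logits
        se.fc1.weight.data[:] = 0
        se.fc1.bias.data[:] = 0
        se.fc2.weight.data[:] = 0
        se.fc2.bias.data[:] = 0
    w = block.branch_weights(ad.Tensor(rng.random((1, 8, 8, 128)).astype(np.float32)))
    np.testing.assert_allclose(w, 0.25, rtol=1e-6)


def test_psa_divisibility_errors_name_the_stage():
    cfg = ModelConfig(variant="pru_net")
    with pytest.raises(ConfigurationError, match="decoder-x"):
        PSABlock(np.random.default_rng(0), 130, cfg, stage="decoder-x")
    with pytest.raises(ConfigurationError, match="group count"):
        PSABlock(np.random.default_rng(0), 16, cfg, stage="decoder-x")


def test_p_unet_needs_compatible_widths():
    with pytest.raises(ConfigurationError):
        build_model(ModelConfig(variant="p_unet", base_width=8), seed=0)
    net = build_model(small_psa_unet(), seed=0)
    assert len(net.psa_blocks()) == 4


# ----------------------------------------------------------- training hooks


def test_every_parameter_receives_gradient(rng):
    net = build_model(small_psa_unet(), seed=0)
    x = rng.random((2, 3, 64, 64)).astype(np.float32)
    g = one_hot(rng.integers(0, 2, (2, 64, 64)), 2)
    loss = combined_loss_from_logits(net(x), g)
    loss.backward()
    missing = [k for k, p in net.named_parameters() if p.grad is None]
    assert missing == []
    assert all(np.isfinite(p.grad).all() for p in net.parameters())


def test_forward_is_deterministic(small_unet, rng):
    net = build_model(small_unet(), seed=0)
    x = rng.random((1, 3, 64, 64)).astype(np.float32)
    np.testing.assert_array_equal(net.predict_proba(x), net.predict_proba(x))


def test_same_seed_same_initialization(small_unet):
    a = build_model(small_unet(), seed=5)
    b = build_model(small_unet(), seed=5)
    for (ka, pa), (kb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert ka == kb
        np.testing.assert_array_equal(pa.data, pb.data)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError, match="variant"):
        ModelConfig(variant="segnet")
    with pytest.raises(ConfigurationError, match="psa_branches"):
        ModelConfig(psa_kernel_sizes=(3, 5))
    with pytest.raises(ConfigurationError, match="pretrained"):
        build_model(ModelConfig(variant="r_unet", pretrained_encoder=True))


def test_state_dict_round_trip(small_unet, rng):
    net = build_model(small_unet(), seed=0)
    x = rng.random((1, 3, 64, 64)).astype(np.float32)
    ref = net.predict_proba(x)
    other = build_model(small_unet(), seed=99)
    other.load_state_dict(net.state_dict())
    np.testing.assert_array_equal(other.predict_proba(x), ref)
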