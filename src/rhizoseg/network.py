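"""Segmentation networks: baseline U-Net and its residual/attention variants.

The improved network ("PRU-Net") keeps the U-Net encoder-decoder topology
but (i) replaces the plain double-convolution encoder with a ResNet50
bottleneck backbone and (ii) inserts a Pyramid Split Attention (PSA) block
after every skip concatenation in the decoder. The ablation grid:

==========  ===========  ====
variant     encoder      PSA
==========  ===========  ====
unet        plain        no
d_unet      plain        no   (differs from unet only in the loss)
r_unet      resnet50     no
p_unet      plain        yes
pru_net     resnet50     yes
==========  ===========  ====

Plain encoder stages sit at strides 1/2/4/8/16 with widths
64/128/256/512/1024 (a 224x224 input yields 112/56/28/14 pooled maps);
the ResNet50 encoder taps the stem and stages 1-4 at strides 2/4/8/16/32
with widths 64/256/512/1024/2048. Every decoder stage is a 2x2 transposed
convolution, skip concatenation, optional PSA, then two 3x3 same-padded
convolutions (BatchNorm + ReLU). A 1x1 convolution maps to class logits.
Spatial input dimensions must be divisible by 32.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Module, Tensor

VARIANTS = ("unet", "r_unet", "p_unet", "d_unet", "pru_net")


class ConfigurationError(ValueError):
    pass


@dataclass
class ModelConfig:
    variant: str = "pru_net"
    in_channels: int = 3
    num_classes: int = 2
    base_width: int = 64
    psa_branches: int = 4
    psa_kernel_sizes: tuple = (3, 5, 7, 9)
    psa_group_counts: tuple = (1, 4, 8, 16)
    se_reduction: int = 4
    pretrained_encoder: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; options: {VARIANTS}"
            )
        if len(self.psa_kernel_sizes) != self.psa_branches or len(
            self.psa_group_counts
        ) != self.psa_branches:
            raise ConfigurationError(
                "psa_kernel_sizes and psa_group_counts must each have psa_branches entries"
            )
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")

    @property
    def encoder(self) -> str:
        return "resnet50" if self.variant in ("r_unet", "pru_net") else "plain"

    @property
    def use_psa(self) -> bool:
        return self.variant in ("p_unet", "pru_net")


# ------------------------------------------------------------------ layers


def _he_init(rng, shape, fan_in):
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng, cin, cout, k, stride=1, padding=None, groups=1, bias=True):
        super().__init__()
        if padding is None:
            padding = k // 2
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (cin // groups) * k * k
        self.weight = Tensor(
            _he_init(rng, (k, k, cin // groups, cout), fan_in), requires_grad=True
        )
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return ad.conv2d(
            x, self.weight, self.bias, stride=self.stride,
            padding=self.padding, groups=self.groups,
        )


class ConvTranspose2x2(Module):
    """2x2 stride-2 up-convolution (the decoder's upsampling step)."""

    def __init__(self, rng, cin, cout):
        super().__init__()
        self.weight = Tensor(_he_init(rng, (cin, 2, 2, cout), cin), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True)

    def forward(self, x):
        return ad.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.9):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)

    def forward(self, x):
        c = x.shape[-1]
        if self.training:
            mu = x.mean(axis=(0, 1, 2), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 1, 2), keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.reshape(c)
            self.running_var = m * self.running_var + (1 - m) * var.data.reshape(c)
            xhat = xc * (var + self.eps) ** (-0.5)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv
        return xhat * self.gamma + self.beta


class ConvBNReLU(Module):
    def __init__(self, rng, cin, cout, k=3, stride=1):
        super().__init__()
        self.conv = Conv2d(rng, cin, cout, k, stride=stride, bias=False)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class DoubleConv(Module):
    """Two 3x3 same-padded convolutions with BatchNorm + ReLU."""

    def __init__(self, rng, cin, cout):
        super().__init__()
        self.block1 = ConvBNReLU(rng, cin, cout)
        self.block2 = ConvBNReLU(rng, cout, cout)

    def forward(self, x):
        return self.block2(self.block1(x))


class SqueezeExcite(Module):
    """Global pool -> bottleneck -> ReLU -> expand -> sigmoid channel weights."""

    def __init__(self, rng, c, reduction):
        super().__init__()
        hidden = max(c // reduction, 1)
        self.fc1 = Conv2d(rng, c, hidden, 1, bias=True)
        self.fc2 = Conv2d(rng, hidden, c, 1, bias=True)

    def forward(self, x):
        s = x.mean(axis=(1, 2), keepdims=True)
        return self.fc2(self.fc1(s).relu())  # raw logits, (n, c, 1, 1)


class PSABlock(Module):
    """Pyramid Split Attention over C channels.

    Channels split into S equal groups; branch i runs a k_i x k_i grouped
    convolution, a squeeze-excitation head scores each branch's channels,
    the scores are softmax-normalized ACROSS branches per channel slot, and
    each branch is rescaled by its normalized weights before channels are
    concatenated back to C.
    """

    def __init__(self, rng, c, cfg: ModelConfig, stage: str = ""):
        super().__init__()
        s = cfg.psa_branches
        if c % s:
            raise ConfigurationError(
                f"PSA at {stage or 'stage'}: {c} channels not divisible by {s} branches"
            )
        cs = c // s
        for k, g in zip(cfg.psa_kernel_sizes, cfg.psa_group_counts):
            if cs % g:
                raise ConfigurationError(
                    f"PSA at {stage or 'stage'}: branch share {cs} not divisible by "
                    f"group count {g} (kernel {k})"
                )
        self.n_branches = s
        self.share = cs
        self.branch_convs = [
            Conv2d(rng, cs, cs, k, groups=g, bias=True)
            for k, g in zip(cfg.psa_kernel_sizes, cfg.psa_group_counts)
        ]
        self.se_heads = [SqueezeExcite(rng, cs, cfg.se_reduction) for _ in range(s)]

    def forward(self, x, force_uniform: bool = False):
        s, cs = self.n_branches, self.share
        feats = [
            conv(x[..., i * cs : (i + 1) * cs])
            for i, conv in enumerate(self.branch_convs)
        ]
        logits = [se(f) for se, f in zip(self.se_heads, feats)]  # (n, 1, 1, cs) each
        scores = ad.stack(logits, axis=3)  # (n, 1, 1, S, cs)
        weights = ad.softmax(scores, axis=3)
        if force_uniform:
            weights = Tensor(np.full_like(weights.data, 1.0 / s))
        out = [f * weights[:, :, :, i] for i, f in enumerate(feats)]
        return ad.concat(out, axis=3)

    def branch_weights(self, x) -> np.ndarray:
        """Softmax-normalized branch weights for input x: (n, S, C/S)."""
        with ad.no_grad():
            feats = [
                conv(x[..., i * self.share : (i + 1) * self.share])
                for i, conv in enumerate(self.branch_convs)
            ]
            logits = [se(f) for se, f in zip(self.se_heads, feats)]
            w = ad.softmax(ad.stack(logits, axis=3), axis=3)
        return w.data[:, 0, 0]  # (n, S, C/S)


class Bottleneck(Module):
    """ResNet bottleneck: 1x1 reduce -> 3x3 -> 1x1 expand, identity shortcut."""

    expansion = 4

    def __init__(self, rng, cin, planes, stride=1):
        super().__init__()
        cout = planes * self.expansion
        self.conv1 = Conv2d(rng, cin, planes, 1, bias=False)
        self.bn1 = BatchNorm2d(planes)
        self.conv2 = Conv2d(rng, planes, planes, 3, stride=stride, bias=False)
        self.bn2 = BatchNorm2d(planes)
        self.conv3 = Conv2d(rng, planes, cout, 1, bias=False)
        self.bn3 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down_conv = Conv2d(rng, cin, cout, 1, stride=stride, bias=False)
            self.down_bn = BatchNorm2d(cout)
        else:
            self.down_conv = None

    def forward(self, x):
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        shortcut = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (y + shortcut).relu()


# ---------------------------------------------------------------- encoders


class PlainEncoder(Module):
    """Classic U-Net contracting path: double conv + 2x2 max pool, widths x2."""

    def __init__(self, rng, in_channels, w):
        super().__init__()
        self.widths = [w, 2 * w, 4 * w, 8 * w, 16 * w]
        self.stages = [
            DoubleConv(rng, in_channels, w),
            DoubleConv(rng, w, 2 * w),
            DoubleConv(rng, 2 * w, 4 * w),
            DoubleConv(rng, 4 * w, 8 * w),
            DoubleConv(rng, 8 * w, 16 * w),
        ]

    def forward(self, x):
        feats = []
        for i, stage in enumerate(self.stages):
            if i > 0:
                x = ad.maxpool2d(x, 2, 2)
            x = stage(x)
            feats.append(x)
        return feats  # strides 1/2/4/8/16


class ResNet50Encoder(Module):
    """ResNet50 backbone tapped at the stem and the four bottleneck stages."""

    def __init__(self, rng, in_channels):
        super().__init__()
        self.widths = [64, 256, 512, 1024, 2048]
        self.stem_conv = Conv2d(rng, in_channels, 64, 7, stride=2, padding=3, bias=False)
        self.stem_bn = BatchNorm2d(64)
        self.layer1 = self._make_layer(rng, 64, 64, 3, stride=1)
        self.layer2 = self._make_layer(rng, 256, 128, 4, stride=2)
        self.layer3 = self._make_layer(rng, 512, 256, 6, stride=2)
        self.layer4 = self._make_layer(rng, 1024, 512, 3, stride=2)

    @staticmethod
    def _make_layer(rng, cin, planes, blocks, stride):
        layers = [Bottleneck(rng, cin, planes, stride=stride)]
        for _ in range(blocks - 1):
            layers.append(Bottleneck(rng, planes * 4, planes))
        return layers

    @staticmethod
    def _run(layers, x):
        for layer in layers:
            x = layer(x)
        return x

    def forward(self, x):
        s0 = self.stem_bn(self.stem_conv(x)).relu()  # 64 @ /2
        x = ad.maxpool2d(s0, 3, 2, padding=1)  # /4
        s1 = self._run(self.layer1, x)  # 256 @ /4
        s2 = self._run(self.layer2, s1)  # 512 @ /8
        s3 = self._run(self.layer3, s2)  # 1024 @ /16
        s4 = self._run(self.layer4, s3)  # 2048 @ /32
        return [s0, s1, s2, s3, s4]


# ----------------------------------------------------------------- network


class DecoderStage(Module):
    """Upsample -> skip concat -> (PSA) -> double conv."""

    def __init__(self, rng, cin, skip_c, cout, cfg: ModelConfig, name):
        super().__init__()
        # upsampling also reduces channels to the stage width before concat
        self.up = ConvTranspose2x2(rng, cin, cout)
        cat_c = cout + skip_c
        self.psa = PSABlock(rng, cat_c, cfg, stage=name) if cfg.use_psa else None
        self.convs = DoubleConv(rng, cat_c, cout)

    def forward(self, x, skip):
        x = self.up(x)
        x = ad.concat([x, skip], axis=3)
        if self.psa is not None:
            x = self.psa(x)
        return self.convs(x)


class SegmentationNetwork(Module):
    """Assembled encoder/decoder with a 1x1 classification head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        if config.encoder == "resnet50":
            self.encoder = ResNet50Encoder(rng, config.in_channels)
            dec_widths = [1024, 512, 256, 64]
        else:
            self.encoder = PlainEncoder(rng, config.in_channels, config.base_width)
            w = config.base_width
            dec_widths = [8 * w, 4 * w, 2 * w, w]
        enc_widths = self.encoder.widths
        self.decoder = []
        cin = enc_widths[-1]
        for i, cout in enumerate(dec_widths):
            skip_c = enc_widths[-2 - i]
            self.decoder.append(
                DecoderStage(rng, cin, skip_c, cout, config, name=f"decoder{i}")
            )
            cin = cout
        if config.encoder == "resnet50":
            # the stem skip sits at stride 2: one extra up block restores stride 1
            self.final_up = ConvTranspose2x2(rng, cin, cin)
            self.final_conv = ConvBNReLU(rng, cin, cin)
        else:
            self.final_up = None
        self.head = Conv2d(rng, cin, config.num_classes, 1, bias=True)

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        n, c, h, w = x.shape
        if h % 32 or w % 32:
            raise ValueError(
                f"spatial dims must be divisible by 32, got {h}x{w}"
            )
        y = x.transpose(0, 2, 3, 1)  # compute in channels-last layout
        feats = self.encoder(y)
        y = feats[-1]
        for i, stage in enumerate(self.decoder):
            y = stage(y, feats[-2 - i])
        if self.final_up is not None:
            y = self.final_conv(self.final_up(y))
        return self.head(y).transpose(0, 3, 1, 2)

    def predict_proba(self, x) -> np.ndarray:
        """Class probabilities (softmax over logits), eval mode, no graph."""
        was_training = self.training
        self.eval()
        try:
            with ad.no_grad():
                logits = self.forward(x)
                p = ad.softmax(logits, axis=1)
        finally:
            self.train(was_training)
        return p.data

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def psa_blocks(self):
        return [s.psa for s in self.decoder if s.psa is not None]


def build_model(config: ModelConfig, seed: int = 0) -> SegmentationNetwork:
    """Instantiate a variant of the segmentation network.

    ``unet``/``d_unet``: plain double-conv encoder, no attention.
    ``r_unet``: ResNet50 encoder. ``p_unet``: plain encoder with PSA in all
    decoder stages. ``pru_net``: ResNet50 encoder + PSA (the improved model).
    """
    if config.pretrained_encoder:
        raise ConfigurationError(
            "no pretrained encoder weights ship with this package; "
            "set pretrained_encoder=False and warm-start via finetune()"
        )
    return SegmentationNetwork(config, seed=seed)
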