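"""Architecture builders: DAGMNet, generic UNet, FCN, and parameter census.

DAGMNet is a four-level 3D encoder-decoder with an image-pyramid encoding
path (MNet-style), dual attention gates (DAG) between encoder and decoder
at every level, UNet3+-style intraskip connections into a final fuse block,
and deep supervision (a sigmoid side head at every decoder level plus the
fused main head).  All conv blocks are two 3^3 convolutions with batch
normalization and SeLU.

Several wiring details of this architecture family admit more than one
reading; where that happened, the reading whose trainable-parameter census
lands on the reference budget (10.7 M at N_f = 32, CH3) was fixed as THE
wiring.  Key pinned choices:

* the image pyramid is encoded in feature space — only the level-1 stem
  sees the raw C-channel input, deeper levels re-encode average-pooled
  image-path features (this also makes the CH3-CH2 parameter difference
  exactly the 27*N_f first-layer delta);
* the dual attention gate applies its channel gate to the accumulated
  encoder features and its spatial gate to both inputs, and emits the
  concatenation of the two gated streams;
* all upsampling (decoder-to-decoder and intraskips into the fuse block)
  uses stride-2 transposed convolutions, chained per octave for the deeper
  intraskips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "NetworkConfig", "DAGBlock", "DAGMNet", "UNet", "FCN",
    "build_network", "build_dagmnet", "build_unet", "build_fcn",
    "build_dag_block", "count_parameters", "census_report",
    "UNET_NF", "FCN_NF",
]

#: feature widths of the generic benchmarks, fixed so their trainable
#: totals land at the reference budgets (10.0 M UNet, 10.1 M FCN)
UNET_NF = 44
FCN_NF = 50

#: spatial squeeze width of the sAG excitation convs
SAG_EXCITE = 32


@dataclass(frozen=True)
class NetworkConfig:
    """Declarative architecture description.

    CH3 models take (DWI, ADC, IS) channels, CH2 models (DWI, ADC).
    ``input_shape`` documents the nominal working grid; the networks are
    fully convolutional and accept any spatial shape divisible by 8.
    """

    arch: str = "dagmnet"
    in_channels: int = 3
    nf: int = 32
    levels: int = 4
    input_shape: tuple[int, int, int] = (96, 112, 48)

    def __post_init__(self):
        if self.arch not in ("dagmnet", "unet", "fcn"):
            raise ValueError(f"unknown architecture {self.arch!r}")
        if self.in_channels not in (2, 3):
            raise ValueError("in_channels must be 2 (DWI,ADC) or 3 (+IS)")
        if self.nf < 1:
            raise ValueError("nf must be >= 1")
        if self.levels != 4:
            raise ValueError("these architectures are defined at 4 levels")


class _UpConv(nn.Module):
    """Stride-2 transposed conv + BN + SeLU (one octave of upsampling)."""

    def __init__(self, cin, cout):
        self.up = nn.ConvTranspose3d(cin, cout, stride=2)
        self.bn = nn.BatchNorm3d(cout)

    def __call__(self, x):
        return nn.selu(self.bn(self.up(x)))


class _LinUpConv(nn.Module):
    """Trilinear 2x resize + 1^3 channel-mixing conv + BN + SeLU."""

    def __init__(self, cin, cout):
        self.conv = nn.Conv3d(cin, cout, 1)
        self.bn = nn.BatchNorm3d(cout)

    def __call__(self, x):
        return nn.selu(self.bn(self.conv(nn.upsample2x_linear(x))))


class _RefineConv(nn.Module):
    """Single 3^3 conv + BN + SeLU refinement stage."""

    def __init__(self, cin, cout):
        self.conv = nn.Conv3d(cin, cout, 3)
        self.bn = nn.BatchNorm3d(cout)

    def __call__(self, x):
        return nn.selu(self.bn(self.conv(x)))


class _Head(nn.Module):
    """3^3 conv + sigmoid prediction head (one output channel).

    The bias starts at -2 so the initial prediction is mostly background
    (lesions are a sparse class); this shortens the burn-in where the
    network must first learn to silence the background.
    """

    def __init__(self, cin):
        self.conv = nn.Conv3d(cin, 1, 3)
        self.conv.bias.data[:] = -2.0

    def __call__(self, x):
        return nn.sigmoid(self.conv(x))


class DAGBlock(nn.Module):
    """Dual attention gate conditioning encoder features for the decoder.

    input-1: image-path features at this scale (c1 channels).
    input-2: accumulated encoder features (c2 channels).

    cAG squeezes input-2 spatially (global average + max pooling), maps the
    concatenated descriptor through a dense layer with sigmoid, and excites
    input-2 channels.  sAG squeezes each input channel-wise (channel max,
    channel mean, and a 1^3 conv projection), excites each with a 5^3
    SeLU conv, sums, and calibrates with a 1^3 sigmoid conv into one
    spatial weight map.  The block output concatenates both spatially
    gated streams: (c1 + c2) channels.
    """

    def __init__(self, c1: int, c2: int, excite: int = SAG_EXCITE):
        self.c1, self.c2 = c1, c2
        self.cag_dense = nn.Dense(2 * c2, c2)
        self.sag_proj1 = nn.Conv3d(c1, 1, 1)
        self.sag_proj2 = nn.Conv3d(c2, 1, 1)
        self.sag_excite1 = nn.Conv3d(3, excite, 5)
        self.sag_excite2 = nn.Conv3d(3, excite, 5)
        self.sag_out = nn.Conv3d(excite, 1, 1)

    def channel_gate(self, x2: Tensor) -> Tensor:
        desc = nn.concat([nn.global_avg_pool(x2), nn.global_max_pool(x2)],
                         axis=1)
        w = nn.sigmoid(self.cag_dense(desc))          # (N, c2)
        w = nn.reshape(w, (*w.data.shape, 1, 1, 1))
        return nn.mul(x2, w)

    def spatial_gate(self, x1: Tensor, x2: Tensor) -> Tensor:
        def squeeze(x, proj):
            return nn.concat([nn.channel_max(x), nn.channel_mean(x), proj(x)],
                             axis=1)
        e1 = nn.selu(self.sag_excite1(squeeze(x1, self.sag_proj1)))
        e2 = nn.selu(self.sag_excite2(squeeze(x2, self.sag_proj2)))
        return nn.sigmoid(self.sag_out(nn.add(e1, e2)))  # (N,1,D,H,W)

    def __call__(self, x1: Tensor, x2: Tensor) -> Tensor:
        s = self.spatial_gate(x1, x2)
        gated2 = nn.mul(self.channel_gate(x2), s)
        gated1 = nn.mul(x1, s)
        return nn.concat([gated1, gated2], axis=1)


class DAGMNet(nn.Module):
    """The attention-gated multi-scale network (main architecture)."""

    def __init__(self, cfg: NetworkConfig):
        if cfg.arch != "dagmnet":
            raise ValueError("config is not a dagmnet config")
        self.cfg = cfg
        F = cfg.nf
        feats = [F, 2 * F, 4 * F, 8 * F]
        self.feats = feats

        # image-pyramid path: stem sees the raw input, deeper levels
        # re-encode pooled image-path features
        self.img_blocks = [nn.ConvBlock(cfg.in_channels, F)] + \
            [nn.ConvBlock(F, F) for _ in range(3)]
        # accumulated encoder path (level 1 is the stem itself)
        self.enc_blocks = [nn.ConvBlock(F + feats[l - 1], feats[l])
                           for l in range(1, 4)]
        self.dags = [DAGBlock(F, feats[l]) for l in range(4)]
        # decoders: level 4 takes DAG only; levels 1-3 concat upsampled deeper
        self.dec4 = nn.ConvBlock(F + feats[3], feats[3])
        self.ups = [_UpConv(feats[l + 1], feats[l]) for l in range(3)]
        self.dec_blocks = [nn.ConvBlock(F + 2 * feats[l], feats[l])
                           for l in range(3)]
        # intraskips into the fuse block: chained stride-2 transposed convs
        self.skip1 = nn.Conv3d(F, F, 1)
        self.skip1_bn = nn.BatchNorm3d(F)
        self.skips = [[_UpConv(feats[l], F)] + [_UpConv(F, F)
                                                for _ in range(l - 1)]
                      for l in range(1, 4)]
        self.fuse = nn.ConvBlock(4 * F, F)
        self.head_fuse = _Head(F)
        self.side_heads = [_Head(feats[l]) for l in range(4)]

    def __call__(self, x: Tensor) -> dict:
        """x: (N, C, D, H, W) -> main 'fuse' output + 4 side outputs.

        Side output l lives at 1/2^l of the input scale (level 1 at full
        resolution); all outputs are sigmoid probabilities.
        """
        img = [self.img_blocks[0](x)]
        for l in range(1, 4):
            img.append(self.img_blocks[l](nn.avgpool3d(img[-1])))
        enc = [img[0]]
        for l in range(1, 4):
            enc.append(self.enc_blocks[l - 1](
                nn.concat([img[l], nn.maxpool3d(enc[-1])], axis=1)))
        gated = [self.dags[l](img[l], enc[l]) for l in range(4)]
        dec = [None] * 4
        dec[3] = self.dec4(gated[3])
        for l in (2, 1, 0):
            dec[l] = self.dec_blocks[l](
                nn.concat([gated[l], self.ups[l](dec[l + 1])], axis=1))
        skips = [nn.selu(self.skip1_bn(self.skip1(dec[0])))]
        for l in range(1, 4):
            t = dec[l]
            for up in self.skips[l - 1]:
                t = up(t)
            skips.append(t)
        fused = self.fuse(nn.concat(skips, axis=1))
        return {"fuse": self.head_fuse(fused),
                "side": [self.side_heads[l](dec[l]) for l in range(4)]}


class UNet(nn.Module):
    """Generic 4-level UNet with interskip concatenation, single head."""

    def __init__(self, cfg: NetworkConfig):
        F = cfg.nf
        feats = [F, 2 * F, 4 * F, 8 * F]
        self.cfg = cfg
        self.enc = [nn.ConvBlock(cfg.in_channels, F)] + \
            [nn.ConvBlock(feats[l - 1], feats[l]) for l in range(1, 4)]
        self.ups = [_LinUpConv(feats[l + 1], feats[l]) for l in range(3)]
        self.dec = [nn.ConvBlock(2 * feats[l], feats[l]) for l in range(3)]
        self.head = _Head(F)

    def __call__(self, x: Tensor) -> dict:
        skips = []
        for l, block in enumerate(self.enc):
            x = block(x if l == 0 else nn.maxpool3d(x))
            skips.append(x)
        y = skips[3]
        for l in (2, 1, 0):
            y = self.dec[l](nn.concat([skips[l], self.ups[l](y)], axis=1))
        return {"fuse": self.head(y), "side": []}


class FCN(nn.Module):
    """Encoder plus upsampling head, no skip concatenations."""

    def __init__(self, cfg: NetworkConfig):
        F = cfg.nf
        feats = [F, 2 * F, 4 * F, 8 * F]
        self.cfg = cfg
        self.enc = [nn.ConvBlock(cfg.in_channels, F)] + \
            [nn.ConvBlock(feats[l - 1], feats[l]) for l in range(1, 4)]
        self.ups = [_LinUpConv(feats[l + 1], feats[l]) for l in range(3)]
        self.dec = [_RefineConv(feats[l], feats[l]) for l in range(3)]
        self.head = _Head(F)

    def __call__(self, x: Tensor) -> dict:
        for l, block in enumerate(self.enc):
            x = block(x if l == 0 else nn.maxpool3d(x))
        y = x
        for l in (2, 1, 0):
            y = self.dec[l](self.ups[l](y))
        return {"fuse": self.head(y), "side": []}


def build_dag_block(nf_level: int, nf_img: int | None = None) -> DAGBlock:
    """A dual attention gate for ``nf_level`` accumulated-feature channels."""
    if nf_level < 1:
        raise ValueError("nf_level must be >= 1")
    return DAGBlock(nf_img if nf_img is not None else nf_level, nf_level)


def build_dagmnet(cfg: NetworkConfig, seed: int | None = 0) -> DAGMNet:
    nn.rng_init(seed)
    return DAGMNet(cfg)


def build_unet(cfg: NetworkConfig, seed: int | None = 0) -> UNet:
    nn.rng_init(seed)
    if cfg.arch != "unet":
        raise ValueError("config is not a unet config")
    return UNet(cfg)


def build_fcn(cfg: NetworkConfig, seed: int | None = 0) -> FCN:
    nn.rng_init(seed)
    if cfg.arch != "fcn":
        raise ValueError("config is not an fcn config")
    return FCN(cfg)


_BUILDERS = {"dagmnet": build_dagmnet, "unet": build_unet, "fcn": build_fcn}


def build_network(name: str, seed: int | None = 0, nf: int | None = None):
    """Build by released-model name, e.g. 'dagmnet_ch3', 'unet_ch2'."""
    arch, _, ch = name.lower().partition("_ch")
    channels = int(ch) if ch else 3
    if nf is None:
        nf = {"dagmnet": 32, "unet": UNET_NF, "fcn": FCN_NF}[arch]
    cfg = NetworkConfig(arch=arch, in_channels=channels, nf=nf)
    return _BUILDERS[arch](cfg, seed=seed)


def count_parameters(net: nn.Module) -> int:
    """Exact count of trainable scalars (kernels, biases, BN scale/shift)."""
    return net.n_parameters()


def census_report(net: nn.Module) -> str:
    """Per-layer parameter census; the last line is the grand total."""
    lines = []
    total = 0
    for name, p in net.named_parameters():
        total += p.data.size
        lines.append(f"{name:55s} {str(p.data.shape):24s} {p.data.size:>10d}")
    lines.append(f"{'TOTAL':55s} {'':24s} {total:>10d}  "
                 f"({total / 1e6:.1f} M)")
    return "\n".join(lines)
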