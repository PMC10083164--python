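"""Generator, discriminator and projection heads for contrastive unpaired
translation.

The generator is a residual encoder-decoder: a stem convolution, two stride-2
downsampling stages, ``n_res_blocks`` residual blocks (the encoder), then two
nearest-upsample+conv stages and an output convolution (the decoder).  Encoder
layers are indexed atomically from the input (index 0 = the input itself), so
the contrastive feature taps {0, 4, 8, 12, 16} resolve to input, first
downsampling conv, second downsampling norm, and two residual-block outputs in
the 9-block configuration.
"""

from __future__ import annotations

import numpy as np

from ..nn import (Tensor, Module, Conv2d, InstanceNorm2d, Linear, Identity,
                  ReLU, LeakyReLU)

__all__ = ["ResnetGenerator", "PatchDiscriminator", "ProjectionHeads",
           "ResBlock"]


class ResBlock(Module):
    def __init__(self, ch: int, *, rng: np.random.Generator):
        self.conv1 = Conv2d(ch, ch, 3, padding=1, rng=rng)
        self.norm1 = InstanceNorm2d(ch)
        self.conv2 = Conv2d(ch, ch, 3, padding=1, rng=rng)
        self.norm2 = InstanceNorm2d(ch)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        return x + self.norm2(self.conv2(h))


class ResnetGenerator(Module):
    """G = G_dec(G_enc(x)); output spatial shape equals input shape.

    Works on images in [0, 1]; internally rescaled to [-1, 1] with a tanh
    output head mapped back.  Inputs must have spatial sides that are
    multiples of 4 (two stride-2 stages); :func:`octpt.cutgan.model.convert`
    handles padding of arbitrary sizes.
    """

    MIN_SIZE = 16

    def __init__(self, base_width: int = 64, n_res_blocks: int = 9,
                 stem_kernel: int = 7, in_ch: int = 1, *,
                 rng: np.random.Generator):
        w = base_width
        sk = stem_kernel
        self.base_width = w
        self.n_res_blocks = n_res_blocks
        self.encoder = [
            Identity(),                                      # 0: input
            Conv2d(in_ch, w, sk, padding=sk // 2, rng=rng),  # 1
            InstanceNorm2d(w),                               # 2
            ReLU(),                                          # 3
            Conv2d(w, 2 * w, 3, stride=2, padding=1, rng=rng),   # 4
            InstanceNorm2d(2 * w),                           # 5
            ReLU(),                                          # 6
            Conv2d(2 * w, 4 * w, 3, stride=2, padding=1, rng=rng),  # 7
            InstanceNorm2d(4 * w),                           # 8
            ReLU(),                                          # 9
        ] + [ResBlock(4 * w, rng=rng) for _ in range(n_res_blocks)]  # 10..
        self.dec_conv1 = Conv2d(4 * w, 2 * w, 3, padding=1, rng=rng)
        self.dec_norm1 = InstanceNorm2d(2 * w)
        self.dec_conv2 = Conv2d(2 * w, w, 3, padding=1, rng=rng)
        self.dec_norm2 = InstanceNorm2d(w)
        self.out_conv = Conv2d(w, in_ch, sk, padding=sk // 2, rng=rng)

    # -- encoder --------------------------------------------------------------
    def n_encoder_layers(self) -> int:
        return len(self.encoder)

    def encoder_channels(self, index: int) -> int:
        """Feature channels emitted at an encoder tap index."""
        w = self.base_width
        if index == 0:
            return 1
        if 1 <= index <= 3:
            return w
        if 4 <= index <= 6:
            return 2 * w
        return 4 * w

    def encode(self, x01: Tensor, taps: tuple[int, ...] = ()) -> tuple[Tensor, dict[int, Tensor]]:
        """Run the encoder on a [0, 1] image batch, returning the final
        feature map and the requested intermediate taps."""
        for t in taps:
            if not (0 <= t < len(self.encoder)):
                raise IndexError(
                    f"nce layer {t} does not exist (encoder has "
                    f"{len(self.encoder)} atomic layers)")
        h = x01 * 2.0 - 1.0
        feats: dict[int, Tensor] = {}
        for i, layer in enumerate(self.encoder):
            h = layer(h)
            if i in taps:
                feats[i] = h
        return h, feats

    def decode(self, h: Tensor) -> Tensor:
        from ..nn.functional import upsample_nearest2x
        h = self.dec_norm1(self.dec_conv1(upsample_nearest2x(h))).relu()
        h = self.dec_norm2(self.dec_conv2(upsample_nearest2x(h))).relu()
        return (self.out_conv(h).tanh() + 1.0) * 0.5

    def forward(self, x01: Tensor) -> Tensor:
        h, _ = self.encode(x01)
        return self.decode(h)


class PatchDiscriminator(Module):
    """Patch-level critic: maps an image batch to a grid of per-patch raw
    scores (least-squares mode) to which a sigmoid is applied in vanilla
    mode.  Three conv stages; receptive field 16x16 pixels."""

    RECEPTIVE_FIELD = 16

    def __init__(self, width: int = 64, in_ch: int = 1, *,
                 rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, width, 4, stride=2, padding=1, rng=rng)
        self.act1 = LeakyReLU(0.2)
        self.conv2 = Conv2d(width, 2 * width, 4, stride=2, padding=1, rng=rng)
        self.norm2 = InstanceNorm2d(2 * width)
        self.act2 = LeakyReLU(0.2)
        self.conv3 = Conv2d(2 * width, 1, 4, stride=1, padding=1, rng=rng)

    def forward(self, x01: Tensor) -> Tensor:
        h = self.act1(self.conv1(x01 * 2.0 - 1.0))
        h = self.act2(self.norm2(self.conv2(h)))
        return self.conv3(h)


class ProjectionHeads(Module):
    """One two-layer MLP per contrastive tap, mapping a feature column to a
    fixed-dimension embedding (unit-normalised by the caller)."""

    def __init__(self, generator: ResnetGenerator, nce_layers: tuple[int, ...],
                 embed_dim: int = 256, *, rng: np.random.Generator):
        self.nce_layers = tuple(nce_layers)
        self.embed_dim = embed_dim
        self.heads = []
        for layer in self.nce_layers:
            c = generator.encoder_channels(layer)
            self.heads.append(_MLPHead(c, embed_dim, rng=rng))

    def head_for(self, layer: int) -> "_MLPHead":
        return self.heads[self.nce_layers.index(layer)]


class _MLPHead(Module):
    def __init__(self, in_dim: int, embed_dim: int, *, rng: np.random.Generator):
        self.fc1 = Linear(in_dim, embed_dim, rng=rng)
        self.fc2 = Linear(embed_dim, embed_dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())
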