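"""MurAN / MurSS network.

Two co-centered patches of the same pixel size but different magnification
enter a *shared-weight* convolutional backbone. The high-resolution stream
supplies content: a mid-level feature map ``M`` (stride 4) and a deep
feature that passes through an embedded-Gaussian non-local (self-attention)
block and is bilinearly upsampled to ``H'`` at M's resolution. The
low-resolution stream supplies context: its deep feature is globally
average-pooled into a vector ``G`` describing the wide field of view.
``M`` is projected pointwise to ``M'`` and fused with the context through
adaptive instance normalization — each channel of ``M'`` is standardized
over space and then rescaled/shifted by statistics derived from ``G`` —
giving ``M''``. ``H'`` and ``M''`` are concatenated and fed to the heads:

* prediction head ``f`` -> class scores ``O``
* selection head ``g``  -> selection score ``S`` in [0, 1] (MurSS only)
* auxiliary head ``h``  -> training-time class scores ``A`` (MurSS only)

Head outputs are produced at stride 4 and bilinearly upsampled to the
input size. Logits (not hard labels) are upsampled.

Two ways of deriving the AdaIN statistics from ``G`` are supported.
``adain_mode="split"`` (default) sets the context width to twice the
mid-channel width and splits the pooled vector into the scale and shift
halves — entirely parameter-free. ``adain_mode="projected"`` keeps an
arbitrary context width and applies a learned pointwise projection to the
required ``2 * C_mid`` channels.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from ._nn.autograd import Tensor, as_tensor, concat, softmax, upsample_bilinear2d
from ._nn.layers import BatchNorm2d, Conv2d, Module, NonLocalBlock, ReLU, Sequential

ADAIN_EPS = 1e-5


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``c_mid`` is the width of the mid-level feature (the published
    configuration uses 32); the deep/context width is ``2 * c_mid`` in
    split mode so that the pooled context vector supplies exactly one scale
    and one shift per mid channel.
    """

    c_stem: int = 16
    c_mid: int = 32
    c_deep: int | None = None  # default: 2*c_mid (split) / 4*c_mid (projected)
    n_classes: int = 3
    adain_mode: str = "split"  # "split" (parameter-free) or "projected"
    seed: int = 0

    def __post_init__(self):
        if self.adain_mode not in ("split", "projected"):
            raise ValueError("adain_mode must be 'split' or 'projected'")
        if self.c_deep is None:
            self.c_deep = 2 * self.c_mid if self.adain_mode == "split" else 4 * self.c_mid
        if self.adain_mode == "split" and self.c_deep != 2 * self.c_mid:
            raise ValueError("split mode requires c_deep == 2 * c_mid")

    def to_dict(self):
        return asdict(self)


def adain(content, gamma, beta, eps: float = ADAIN_EPS) -> Tensor:
    """Adaptive instance normalization.

    Per sample and per channel, the content feature is standardized over
    its spatial extent (population variance, ``eps`` inside the square
    root) and then scaled by ``gamma`` and shifted by ``beta``:

        out[b, c] = gamma[b, c] * (x[b, c] - mu[b, c]) / sigma[b, c] + beta[b, c]

    There are no learnable parameters; the statistics come entirely from
    the context branch. ``gamma``/``beta`` are (B, C) or (B, C, 1, 1).
    """
    x = as_tensor(content)
    gamma, beta = as_tensor(gamma), as_tensor(beta)
    b, c = x.shape[0], x.shape[1]
    if gamma.shape[1] != c or beta.shape[1] != c:
        raise ValueError("context channel count does not match content")
    if gamma.ndim == 2:
        gamma = gamma.reshape(b, c, 1, 1)
    if beta.ndim == 2:
        beta = beta.reshape(b, c, 1, 1)
    mu = x.mean(axis=(2, 3), keepdims=True)
    var = ((x - mu) ** 2).mean(axis=(2, 3), keepdims=True)
    sigma = (var + eps).sqrt()
    return gamma * ((x - mu) / sigma) + beta


class _ResBlock(Module):
    def __init__(self, c, rng):
        self.conv1 = Conv2d(c, c, 3, rng=rng)
        self.conv2 = Conv2d(c, c, 3, rng=rng)

    def forward(self, x):
        y = self.conv2(self.conv1(x).relu())
        return (x + y).relu()


class Backbone(Module):
    """Small residual encoder, fully convolutional.

    Four downsampling stages; the mid tap sits at stride 4 with ``c_mid``
    channels, the deep tap at stride 16 with ``c_deep`` channels. One
    parameter set serves both resolution streams.
    """

    STRIDE_MID = 4
    STRIDE_DEEP = 16

    def __init__(self, cfg: ModelConfig, rng):
        self.stem = Conv2d(3, cfg.c_stem, 3, stride=2, rng=rng)
        self.down1 = Conv2d(cfg.c_stem, cfg.c_mid, 3, stride=2, rng=rng)
        self.res_mid = _ResBlock(cfg.c_mid, rng)
        self.down2 = Conv2d(cfg.c_mid, cfg.c_deep, 3, stride=2, rng=rng)
        self.down3 = Conv2d(cfg.c_deep, cfg.c_deep, 3, stride=2, rng=rng)
        self.res_deep = _ResBlock(cfg.c_deep, rng)

    def forward(self, x):
        """Returns ``(mid, deep)`` features at strides 4 and 16."""
        h, w = x.shape[2], x.shape[3]
        if h % self.STRIDE_DEEP or w % self.STRIDE_DEEP:
            raise ValueError(
                f"input size {h}x{w} not divisible by backbone stride "
                f"{self.STRIDE_DEEP}"
            )
        x = self.stem(x).relu()
        mid = self.res_mid(self.down1(x).relu())
        deep = self.res_deep(self.down3(self.down2(mid).relu()).relu())
        return mid, deep


class MurSSNet(Module):
    """The full dual-resolution selective segmentation network."""

    def __init__(self, config: ModelConfig | None = None):
        cfg = config or ModelConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = Backbone(cfg, rng)
        self.non_local = NonLocalBlock(cfg.c_deep, rng=rng)
        self.proj_high = Conv2d(cfg.c_deep, cfg.c_mid, 1, rng=rng)  # deep -> H' width
        self.proj_mid = Conv2d(cfg.c_mid, cfg.c_mid, 1, rng=rng)  # M -> M'
        if cfg.adain_mode == "projected":
            self.proj_context = Conv2d(cfg.c_deep, 2 * cfg.c_mid, 1, rng=rng)
        trunk_c = 2 * cfg.c_mid
        self.head_f = Sequential(
            Conv2d(trunk_c, trunk_c, 3, rng=rng), ReLU(),
            Conv2d(trunk_c, cfg.n_classes, 1, rng=rng),
        )
        # Selection head: a 3x3 conv first (rejection targets boundary
        # regions, and spatial contrast between neighboring trunk cells is
        # what a pointwise layer cannot measure), then batch normalization
        # before the sigmoid so the selection logits cannot collectively
        # saturate while coverage is being balanced against risk.
        self.head_g = Sequential(
            Conv2d(trunk_c, cfg.c_mid, 3, rng=rng), ReLU(),
            Conv2d(cfg.c_mid, 1, 1, rng=rng),
            BatchNorm2d(1, gamma_init=2.0),
        )
        self.head_h = Sequential(
            Conv2d(trunk_c, trunk_c, 3, rng=rng), ReLU(),
            Conv2d(trunk_c, cfg.n_classes, 1, rng=rng),
        )

    # -- pieces ----------------------------------------------------------
    def backbone_forward(self, image):
        """Shared-weight feature extraction; see :class:`Backbone`."""
        return self.backbone(as_tensor(image))

    def context_vector(self, deep_low) -> Tensor:
        """Global average pool of the low-stream deep feature: (B, C, 1, 1)."""
        return deep_low.mean(axis=(2, 3), keepdims=True)

    def context_stats(self, G: Tensor):
        """Derive the AdaIN (gamma, beta) pair from the context vector."""
        cfg = self.config
        if cfg.adain_mode == "projected":
            G = self.proj_context(G)
        gamma = G[:, : cfg.c_mid]
        beta = G[:, cfg.c_mid :]
        return gamma, beta

    def _trunk(self, i_high, i_low) -> Tensor:
        i_high, i_low = as_tensor(i_high), as_tensor(i_low)
        if i_high.shape != i_low.shape:
            raise ValueError("high- and low-resolution inputs must share shape")
        mid, deep_high = self.backbone(i_high)
        _, deep_low = self.backbone(i_low)
        att = self.non_local(deep_high)
        h_prime = upsample_bilinear2d(
            self.proj_high(att), Backbone.STRIDE_DEEP // Backbone.STRIDE_MID
        )
        m_prime = self.proj_mid(mid)
        gamma, beta = self.context_stats(self.context_vector(deep_low))
        m_fused = adain(m_prime, gamma, beta)
        return concat([h_prime, m_fused], axis=1)

    def _to_input_size(self, logits):
        return upsample_bilinear2d(logits, Backbone.STRIDE_MID)

    # -- forward passes ---------------------------------------------------
    def muran_forward(self, i_high, i_low, return_probs: bool = True):
        """Prediction-only pass: per-pixel class scores ``O`` at input size."""
        trunk = self._trunk(i_high, i_low)
        logits = self._to_input_size(self.head_f(trunk))
        return softmax(logits, axis=1) if return_probs else logits

    def murss_forward(self, i_high, i_low):
        """Selective pass: ``(O_logits, S, A_logits)`` at input size.

        ``S`` is sigmoid-bounded in [0, 1]; class outputs are raw scores
        (normalize with a per-pixel softmax for probabilities).
        """
        trunk = self._trunk(i_high, i_low)
        o = self._to_input_size(self.head_f(trunk))
        s = self._to_input_size(self.head_g(trunk)).sigmoid()
        a = self._to_input_size(self.head_h(trunk))
        return o, s, a

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())
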