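"""Global attention mechanism (GAM): sequential channel then spatial gating.

Candling images are mostly dark background; the informative signal is the
small translucent region.  GAM rescales a feature map elementwise with two
sigmoid-bounded attention maps computed in sequence:

* channel gate — the map is permuted so channels trail, passed through a
  two-layer perceptron with a C/r bottleneck (keeping the full 3-D layout,
  i.e. one gate value per channel *and* position), permuted back, squashed
  through a sigmoid, and multiplied into the input:  F2 = Mc(F1) ⊗ F1.
* spatial gate — two 7x7 convolutions (C -> C/r -> C, batch norm + ReLU in
  between) followed by a sigmoid:  F3 = Ms(F2) ⊗ F2.

Both gates lie strictly in (0, 1), so attention can only attenuate; with all
weights zeroed each gate is exactly 0.5, which the tests use as a closed-form
oracle (full GAM = 0.25 x input).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import autograd as ag
from . import nn

__all__ = ["GamConfig", "ChannelAttention", "SpatialAttention", "GAM",
           "channel_attention", "spatial_attention", "gam"]


@dataclass
class GamConfig:
    channels: int
    reduction_ratio: int = 16

    def __post_init__(self):
        if self.channels <= 0 or self.reduction_ratio <= 0:
            raise ValueError("channels and reduction_ratio must be positive")
        if self.channels % self.reduction_ratio:
            raise ValueError(
                f"reduction_ratio {self.reduction_ratio} must divide "
                f"channels {self.channels}"
            )

    @property
    def reduced(self):
        return self.channels // self.reduction_ratio


class ChannelAttention(nn.Module):
    def __init__(self, config: GamConfig):
        super().__init__()
        self.config = config
        c, cr = config.channels, config.reduced
        self.fc1 = nn.Linear(c, cr)
        self.act = nn.ReLU()
        self.fc2 = nn.Linear(cr, c)

    def forward(self, x):
        x = ag.as_tensor(x)
        if x.shape[1] != self.config.channels:
            raise ValueError(
                f"expected {self.config.channels} channels, got {x.shape[1]}"
            )
        g = ag.moveaxis(x, 1, -1)  # NCHW -> NHWC: channels trail for the MLP
        g = self.fc2(self.act(self.fc1(g)))
        g = ag.sigmoid(ag.moveaxis(g, -1, 1))
        return ag.mul(g, x)


class SpatialAttention(nn.Module):
    def __init__(self, config: GamConfig):
        super().__init__()
        self.config = config
        c, cr = config.channels, config.reduced
        self.conv1 = nn.Conv2d(c, cr, 7, padding=3)
        self.bn = nn.BatchNorm2d(cr)
        self.act = nn.ReLU()
        self.conv2 = nn.Conv2d(cr, c, 7, padding=3)

    def forward(self, x):
        x = ag.as_tensor(x)
        if x.shape[1] != self.config.channels:
            raise ValueError(
                f"expected {self.config.channels} channels, got {x.shape[1]}"
            )
        g = self.conv2(self.act(self.bn(self.conv1(x))))
        return ag.mul(ag.sigmoid(g), x)


class GAM(nn.Module):
    """channel_attention then spatial_attention; shape preserved."""

    def __init__(self, config: GamConfig):
        super().__init__()
        self.config = config
        self.channel = ChannelAttention(config)
        self.spatial = SpatialAttention(config)

    def forward(self, x):
        return self.spatial(self.channel(x))


def channel_attention(x, module: ChannelAttention):
    return module(x)


def spatial_attention(x, module: SpatialAttention):
    return module(x)


def gam(x, module: GAM):
    return module(x)
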