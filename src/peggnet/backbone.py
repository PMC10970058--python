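"""Configurable ConvNeXt feature extractor.

The classifier family is parameterized by per-stage block counts
``depths = [d1..d4]`` and stage widths ``dims = [dim1..dim4]``.  The six
named presets cover the five published sizes (tiny through xlarge) plus the
reduced ``nano`` dimensioning ([64, 128, 256, 512]) used as the trunk of the
preserved-egg classifier.

A ConvNeXt block is: 7x7 depthwise convolution -> layer norm ->
1x1 expansion (x4, as a linear map in channels-last layout) -> GELU ->
1x1 projection -> learnable per-channel scale (initialized small) ->
stochastic-depth residual add.  The stem is a 4x4/4 convolution + norm;
stages are separated by norm + 2x2/2 downsampling convolutions; the head is
global average pool -> norm -> linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import autograd as ag
from . import nn

__all__ = [
    "BackboneConfig",
    "PRESETS",
    "ConvNeXtBlock",
    "ConvNeXt",
    "build_backbone",
    "forward_features",
    "count_parameters",
    "format_param_count",
]

#: Table of named variants: (depths, dims).
PRESETS = {
    "tiny": ([3, 3, 9, 3], [96, 192, 384, 768]),
    "small": ([3, 3, 27, 3], [96, 192, 384, 768]),
    "base": ([3, 3, 27, 3], [128, 256, 512, 1024]),
    "large": ([3, 3, 27, 3], [192, 384, 768, 1536]),
    "xlarge": ([3, 3, 27, 3], [256, 512, 1024, 2048]),
    "nano": ([3, 3, 9, 3], [64, 128, 256, 512]),
}


@dataclass
class BackboneConfig:
    """Hyperparameters distinguishing ConvNeXt variants."""

    depths: list = field(default_factory=lambda: [3, 3, 9, 3])
    dims: list = field(default_factory=lambda: [96, 192, 384, 768])
    num_classes: int = 5
    drop_path_rate: float = 0.0
    layer_scale_init: float = 1e-6

    def __post_init__(self):
        self.depths = list(self.depths)
        self.dims = list(self.dims)
        if len(self.depths) != 4 or len(self.dims) != 4:
            raise ValueError("depths and dims must each have length 4")
        if any(d <= 0 for d in self.depths) or any(c <= 0 for c in self.dims):
            raise ValueError("depths and dims must be positive")
        if not (0 <= self.drop_path_rate < 1):
            raise ValueError("drop_path_rate must lie in [0, 1)")

    @classmethod
    def preset(cls, name, **overrides):
        try:
            depths, dims = PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; valid: {sorted(PRESETS)}"
            ) from None
        return cls(depths=list(depths), dims=list(dims), **overrides)

    def to_yaml(self):
        return yaml.safe_dump(
            {
                "depths": self.depths,
                "dims": self.dims,
                "num_classes": self.num_classes,
                "drop_path_rate": self.drop_path_rate,
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text):
        return cls(**yaml.safe_load(text))


class ConvNeXtBlock(nn.Module):
    def __init__(self, dim, drop_path=0.0, layer_scale_init=1e-6):
        super().__init__()
        self.dwconv = nn.Conv2d(dim, dim, 7, padding=3, groups=dim)
        self.norm = nn.LayerNorm(dim)
        self.pwconv1 = nn.Linear(dim, 4 * dim)
        self.act = nn.GELU()
        self.pwconv2 = nn.Linear(4 * dim, dim)
        self.gamma = nn.Parameter(np.full(dim, layer_scale_init))
        self.drop_path = nn.DropPath(drop_path)

    def forward(self, x):
        y = self.dwconv(x)
        y = ag.moveaxis(y, 1, -1)  # NCHW -> NHWC
        y = self.norm(y)
        y = self.pwconv1(y)
        y = self.act(y)
        y = self.pwconv2(y)
        y = ag.mul(y, self.gamma)
        y = ag.moveaxis(y, -1, 1)
        return ag.add(x, self.drop_path(y))


class ConvNeXt(nn.Module):
    """Four-stage ConvNeXt classifier exposing per-stage feature maps."""

    def __init__(self, config: BackboneConfig):
        super().__init__()
        self.config = config
        dims, depths = config.dims, config.depths
        self.stem = nn.Sequential(
            nn.Conv2d(3, dims[0], 4, stride=4),
            nn.LayerNorm(dims[0], data_format="channels_first"),
        )
        self.downsamplers = [
            nn.Sequential(
                nn.LayerNorm(dims[i], data_format="channels_first"),
                nn.Conv2d(dims[i], dims[i + 1], 2, stride=2),
            )
            for i in range(3)
        ]
        # stochastic depth linearly increasing over block index
        rates = np.linspace(0, config.drop_path_rate, sum(depths))
        self.stages = []
        k = 0
        for i in range(4):
            blocks = [
                ConvNeXtBlock(dims[i], drop_path=rates[k + j],
                              layer_scale_init=config.layer_scale_init)
                for j in range(depths[i])
            ]
            k += depths[i]
            self.stages.append(nn.Sequential(*blocks))
        self.norm = nn.LayerNorm(dims[-1])
        self.head = nn.Linear(dims[-1], config.num_classes)

    def _check_input(self, x):
        if x.ndim != 4:
            raise ValueError("expected NCHW input")
        if x.shape[1] != 3:
            raise ValueError(f"expected 3 input channels, got {x.shape[1]}")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input spatial size must be divisible by 32")

    def forward_features(self, x):
        """Return the four per-stage feature maps (NCHW tensors)."""
        x = ag.as_tensor(x)
        self._check_input(x)
        feats = []
        x = self.stem(x)
        for i in range(4):
            if i:
                x = self.downsamplers[i - 1](x)
            x = self.stages[i](x)
            feats.append(x)
        return feats

    def forward(self, x):
        f4 = self.forward_features(x)[-1]
        pooled = ag.global_avg_pool(f4)
        return self.head(self.norm(pooled))


def build_backbone(config):
    """Build a ConvNeXt from a :class:`BackboneConfig` or preset name."""
    if isinstance(config, str):
        config = BackboneConfig.preset(config)
    return ConvNeXt(config)


def forward_features(model, x):
    return model.forward_features(x)


def count_parameters(model):
    """Exact count of trainable scalar parameters."""
    return sum(int(p.data.size) for p in model.parameters())


def format_param_count(n):
    """Round half-up to 0.1M, the convention used for reported model sizes."""
    millions = np.floor(n / 1e5 + 0.5) / 10
    return f"{millions:.1f}M"
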