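"""ConvNeXt_PEgg: nano trunk + attention on the lateral paths + a two-step
multi-scale feature-fusion (MSFF) neck.

Deep stages carry semantics, shallow stages carry local detail; the neck
merges them top-down so the classifier sees both.  With the nano trunk
(dims [64, 128, 256, 512]) and a 224x224 input:

* step 1 — the stage-4 map (512 @ 7x7) is reduced to 256 channels by a 1x1
  convolution and upsampled 2x to 14x14, concatenated with the (attended)
  stage-3 map (256 @ 14x14) into a 512-wide stream, and fused by three
  ConvNeXt blocks at width 512;
* step 2 — the fused map (512 @ 14x14) is reduced to 128 channels and
  upsampled to 28x28, concatenated with the (attended) stage-2 map
  (128 @ 28x28) into a 256-wide stream, and fused by three ConvNeXt blocks
  at width 256.  Step 2 mirrors step 1 at half width: the deep stream is
  always brought down to the lateral width before concatenation.

GAM modules sit on the stage-2 and stage-3 lateral paths only (just before
fusion); the trunk itself is untouched.  The head is global average pool ->
layer norm -> linear over the final fused map.  The attention bottleneck is
held at width 8 on both placements (r=32 on 256 channels, r=16 on 128); this
fixed plan reproduces the reported model sizes — trunk 12.5M, +MSFF 20.6M,
+GAM 21.0M — at 0.1M rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from . import nn
from .attention import GAM, GamConfig
from .backbone import BackboneConfig, ConvNeXt, ConvNeXtBlock, count_parameters

__all__ = [
    "MsffConfig",
    "ReduceUpsample",
    "FusionStage",
    "ConvNeXtPEgg",
    "reduce_and_upsample",
    "fuse",
    "build_pegg",
    "build_msff",
    "classify",
    "DEFAULT_GAM_CONFIGS",
]

#: Attention configs for the stage-2 and stage-3 placements (bottleneck 8).
DEFAULT_GAM_CONFIGS = (
    GamConfig(channels=128, reduction_ratio=16),
    GamConfig(channels=256, reduction_ratio=32),
)


@dataclass
class MsffConfig:
    """Channel plan of the fusion neck (frozen to the published model)."""

    fusion_block_count: int = 3
    fuse1_channels: int = 512   # concat of reduced stage 4 (256) + stage 3 (256)
    fuse2_channels: int = 256   # concat of reduced fused1 (128) + stage 2 (128)
    upsample_mode: str = "bilinear"

    def __post_init__(self):
        if self.fusion_block_count <= 0:
            raise ValueError("fusion_block_count must be positive")
        if self.upsample_mode not in ("nearest", "bilinear"):
            raise ValueError("upsample_mode must be 'nearest' or 'bilinear'")


class ReduceUpsample(nn.Module):
    """1x1 channel reduction followed by 2x spatial upsampling."""

    def __init__(self, in_channels, target_channels, mode="bilinear"):
        super().__init__()
        if target_channels <= 0:
            raise ValueError("target_channels must be positive")
        self.mode = mode
        self.reduce = nn.Conv2d(in_channels, target_channels, 1)

    def forward(self, x):
        return ag.upsample2x(self.reduce(x), mode=self.mode)


class FusionStage(nn.Module):
    """Concatenate (deep, lateral) and run ConvNeXt blocks at the joint width."""

    def __init__(self, width, block_count=3, layer_scale_init=1e-6):
        super().__init__()
        self.width = width
        self.blocks = nn.Sequential(
            *[ConvNeXtBlock(width, layer_scale_init=layer_scale_init)
              for _ in range(block_count)]
        )

    def forward(self, deep, lateral):
        deep, lateral = ag.as_tensor(deep), ag.as_tensor(lateral)
        if deep.shape[2:] != lateral.shape[2:]:
            raise ValueError(
                f"spatial mismatch: {deep.shape[2:]} vs {lateral.shape[2:]}"
            )
        return self.blocks(ag.concat([deep, lateral], axis=1))


def reduce_and_upsample(x, target_channels, mode="bilinear", module=None):
    """Functional form: build (or reuse) a ReduceUpsample and apply it."""
    x = ag.as_tensor(x)
    if module is None:
        module = ReduceUpsample(x.shape[1], target_channels, mode=mode)
    return module(x)


def fuse(deep, lateral, blocks: FusionStage):
    return blocks(deep, lateral)


class ConvNeXtPEgg(nn.Module):
    """The assembled preserved-egg classifier (5 logits)."""

    def __init__(self, backbone_cfg=None, gam_cfgs=DEFAULT_GAM_CONFIGS,
                 msff_cfg=None, with_gam=True, input_size=224):
        super().__init__()
        backbone_cfg = backbone_cfg or BackboneConfig.preset("nano")
        msff_cfg = msff_cfg or MsffConfig()
        dims = backbone_cfg.dims
        half1 = msff_cfg.fuse1_channels // 2
        half2 = msff_cfg.fuse2_channels // 2
        if dims[3] <= 0 or dims[2] != half1 or dims[1] != half2:
            raise ValueError(
                "backbone dims incompatible with the fusion channel plan: "
                f"need stage-3 width {half1} and stage-2 width {half2}, "
                f"got {dims[2]} and {dims[1]}"
            )
        self.msff_cfg = msff_cfg
        self.input_size = input_size
        self.with_gam = with_gam
        self.backbone = ConvNeXt(backbone_cfg)
        # the trunk's own classification head is unused in the assembly
        self.backbone.norm = nn.Identity()
        self.backbone.head = nn.Identity()
        if with_gam:
            cfg2, cfg3 = sorted(gam_cfgs, key=lambda c: c.channels)
            if cfg2.channels != dims[1] or cfg3.channels != dims[2]:
                raise ValueError("GAM configs must match stage-2/stage-3 widths")
            self.gam2 = GAM(cfg2)
            self.gam3 = GAM(cfg3)
        else:
            self.gam2 = nn.Identity()
            self.gam3 = nn.Identity()
        mode = msff_cfg.upsample_mode
        ls = backbone_cfg.layer_scale_init
        self.reduce4 = ReduceUpsample(dims[3], half1, mode=mode)
        self.fuse1 = FusionStage(msff_cfg.fuse1_channels,
                                 msff_cfg.fusion_block_count, layer_scale_init=ls)
        self.reduce_f1 = ReduceUpsample(msff_cfg.fuse1_channels, half2, mode=mode)
        self.fuse2 = FusionStage(msff_cfg.fuse2_channels,
                                 msff_cfg.fusion_block_count, layer_scale_init=ls)
        self.norm = nn.LayerNorm(msff_cfg.fuse2_channels)
        self.head = nn.Linear(msff_cfg.fuse2_channels, backbone_cfg.num_classes)

    def forward(self, x):
        _, f2, f3, f4 = self.backbone.forward_features(x)
        fused1 = self.fuse1(self.reduce4(f4), self.gam3(f3))
        fused2 = self.fuse2(self.reduce_f1(fused1), self.gam2(f2))
        pooled = ag.global_avg_pool(fused2)
        return self.head(self.norm(pooled))


def build_pegg(backbone_cfg=None, gam_cfgs=DEFAULT_GAM_CONFIGS, msff_cfg=None,
               input_size=224):
    """The full model: nano trunk + GAM + MSFF (rounds to 21.0M parameters)."""
    return ConvNeXtPEgg(backbone_cfg, gam_cfgs, msff_cfg, with_gam=True,
                        input_size=input_size)


def build_msff(backbone_cfg=None, msff_cfg=None, input_size=224):
    """Ablation without attention: trunk + MSFF only (20.6M parameters)."""
    return ConvNeXtPEgg(backbone_cfg, msff_cfg=msff_cfg, with_gam=False,
                        input_size=input_size)


def classify(model, image):
    """Probability vector(s) over the five classes for preprocessed input.

    ``image`` is a (3, S, S) or (N, 3, S, S) float array with S equal to the
    model's configured input size.
    """
    x = np.asarray(image.data if isinstance(image, ag.Tensor) else image)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    size = getattr(model, "input_size", None)
    if size is not None and x.shape[2:] != (size, size):
        raise ValueError(
            f"expected preprocessed {size}x{size} input, got {x.shape[2:]}"
        )
    was_training = model.training
    model.eval()
    try:
        probs = ag.softmax(model(ag.Tensor(x)), axis=-1).data
    finally:
        model.train(was_training)
    return probs[0] if squeeze else probs
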