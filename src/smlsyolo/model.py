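"""Model assembly from configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn.modules import Module
from .star_backbone import CSPBackbone, StarNet
from .neck import Neck
from .segment_ls_head import BaselineSegment, SegmentLS, HeadOutput


@dataclass
class ModelConfig:
    variant: str = "smls"            # "smls" | "yolov8n_seg"
    nc: int = 1
    reg_max: int = 16
    nm: int = 32
    image_size: int = 640
    # star backbone
    backbone_dims: tuple = (24, 48, 96, 192)
    backbone_depths: tuple = (1, 2, 2, 1)
    stem_ch: int = 24
    mlp_ratio: int = 4
    dw_kernel: int = 7
    # neck
    neck_channels: tuple = (32, 64, 96)
    neck_blocks: int = 1
    use_mhsa: bool = True
    mhsa_heads: int = 4
    pos_enc: bool = True
    # head
    head_width: int = 104
    proto_mid: int = 32
    # baseline widths
    baseline_width: tuple = (16, 32, 64, 128, 256)
    baseline_depths: tuple = (1, 2, 2, 1)
    baseline_nc: int = 80
    baseline_npr: int = 64

    def __post_init__(self):
        if self.variant not in ("smls", "yolov8n_seg"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.image_size % 32:
            raise ValueError("image_size must be a multiple of 32")
        for name in ("nc", "reg_max", "nm", "head_width", "proto_mid"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("backbone_dims", "backbone_depths", "neck_channels",
                  "baseline_width", "baseline_depths"):
            if k in d:
                d[k] = tuple(d[k])
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


# desk-scale variant used for CPU training demonstrations and tests
TINY_OVERRIDES = dict(
    backbone_dims=(16, 32, 64, 128), backbone_depths=(1, 1, 1, 1),
    stem_ch=16, neck_channels=(32, 64, 128), head_width=32, proto_mid=32,
    nm=16, image_size=256, mhsa_heads=4,
)


def tiny_config(**overrides) -> ModelConfig:
    kw = dict(TINY_OVERRIDES)
    kw.update(overrides)
    return ModelConfig(**kw)


class SegmentationModel(Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.PCG64(seed))
        g32 = cfg.image_size // 32
        if cfg.variant == "smls":
            self.backbone = StarNet(rng, cfg.backbone_dims, cfg.backbone_depths,
                                    cfg.stem_ch, cfg.mlp_ratio, cfg.dw_kernel)
            ch = tuple(cfg.backbone_dims[1:])
            self.neck = Neck(rng, ch, cfg.neck_channels, inner="star",
                             n_blocks=cfg.neck_blocks, use_mhsa=cfg.use_mhsa,
                             mhsa_heads=cfg.mhsa_heads, grid=(g32, g32),
                             pos_enc=cfg.pos_enc)
            self.head = SegmentLS(rng, cfg.neck_channels, cfg.head_width,
                                  cfg.nc, cfg.reg_max, cfg.nm, cfg.proto_mid)
        else:
            w = cfg.baseline_width
            self.backbone = CSPBackbone(rng, w, cfg.baseline_depths)
            ch = (w[2], w[3], w[4])
            self.neck = Neck(rng, ch, ch, inner="bottleneck",
                             n_blocks=1, use_mhsa=False)
            self.head = BaselineSegment(rng, ch, cfg.baseline_nc,
                                        cfg.reg_max, cfg.nm, cfg.baseline_npr)

    def forward(self, x) -> HeadOutput:
        p = self.backbone(x)
        n3, n4, n5 = self.neck(p["P3"], p["P4"], p["P5"])
        return self.head(n3, n4, n5)


def build_model(cfg: ModelConfig, seed: int = 0) -> SegmentationModel:
    return SegmentationModel(cfg, seed=seed)
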