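"""Segmentation heads.

``SegmentLS`` is the lightweight head: every pyramid level is projected by a
per-level 1x1 conv + GroupNorm to a common width, then a single stack of two
3x3 conv + GroupNorm layers — its weights shared across all levels —
processes the three maps, and shared 1x1 output convs emit box-regression
logits (4 * reg_max distribution bins per side), class logits and per-
instance mask coefficients.  A learnable scalar Scale per level rescales the
decoded regression distances so the shared weights can serve three strides.
Instance masks are assembled YOLACT-style from a prototype stack produced by
a separate path off the stride-8 map.

``BaselineSegment`` is the reference YOLOv8-style decoupled head with
unshared per-level branches, kept for the parameter/FLOP comparison and for
ablations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import autograd as A
from .nn.modules import Conv2d, Module, ModuleList, Parameter, Sequential
from .layers import ConvBN, ConvGN


@dataclass
class HeadOutput:
    """Raw per-scale network outputs plus the prototype stack."""

    reg: list          # per level: (N, 4*reg_max, H, W)
    cls: list          # per level: (N, nc, H, W)
    coef: list         # per level: (N, nm, H, W)
    protos: object     # (N, nm, H/4, W/4)
    strides: tuple = (8, 16, 32)
    scales: list = field(default_factory=lambda: [1.0, 1.0, 1.0])
    reg_max: int = 16


class Scale(Module):
    """One learnable scalar, initialised to 1, applied multiplicatively."""

    def __init__(self, init: float = 1.0):
        super().__init__()
        self.value = Parameter(np.array(init, dtype=np.float32))

    def forward(self, x):
        return A.mul(x, self.value)


def scale_apply(x, s: Scale):
    return s(x)


class Proto(Module):
    """Prototype-mask path: conv -> 2x upsample -> conv -> 1x1 conv."""

    def __init__(self, rng, c_in: int, c_mid: int, nm: int, norm: str = "gn"):
        super().__init__()
        Block = ConvGN if norm == "gn" else ConvBN
        self.cv1 = Block(rng, c_in, c_mid, 3)
        self.cv2 = Block(rng, c_mid, c_mid, 3)
        if norm == "gn":
            self.cv3 = Conv2d(rng, c_mid, nm, 1, bias=True)
        else:
            self.cv3 = ConvBN(rng, c_mid, nm, 1)

    def forward(self, x):
        return self.cv3(self.cv2(A.upsample_nearest2x(self.cv1(x))))


class SegmentLS(Module):
    def __init__(self, rng, ch: tuple[int, int, int], width: int = 96,
                 nc: int = 1, reg_max: int = 16, nm: int = 32,
                 proto_mid: int = 48, gn_groups: int = 16):
        super().__init__()
        self.ch = tuple(ch)
        self.nc, self.reg_max, self.nm = nc, reg_max, nm
        self.proj = ModuleList(
            [ConvGN(rng, c, width, 1, groups_norm=gn_groups) for c in ch])
        self.shared = Sequential([
            ConvGN(rng, width, width, 3, groups_norm=gn_groups),
            ConvGN(rng, width, width, 3, groups_norm=gn_groups),
        ])
        self.reg_out = Conv2d(rng, width, 4 * reg_max, 1, bias=True)
        self.cls_out = Conv2d(rng, width, nc, 1, bias=True)
        self.coef_out = Conv2d(rng, width, nm, 1, bias=True)
        self.scales = ModuleList([Scale() for _ in ch])
        self.proto = Proto(rng, ch[0], proto_mid, nm, norm="gn")
        # biases: regression starts near one stride unit per side, class
        # logits at a low-probability prior — stabilises early training
        self.reg_out.bias.data[...] = 1.0
        self.cls_out.bias.data[...] = -4.6

    def forward(self, n3, n4, n5) -> HeadOutput:
        feats = (n3, n4, n5)
        for f, c in zip(feats, self.ch):
            if f.shape[1] != c:
                raise ValueError(
                    f"head level channel mismatch: got {f.shape[1]}, expected {c}")
        reg, cls, coef = [], [], []
        for f, p in zip(feats, self.proj):
            y = self.shared(p(f))
            reg.append(self.reg_out(y))
            cls.append(self.cls_out(y))
            coef.append(self.coef_out(y))
        return HeadOutput(reg=reg, cls=cls, coef=coef,
                          protos=self.proto(n3),
                          scales=[s.value for s in self.scales],
                          reg_max=self.reg_max)


class BaselineSegment(Module):
    """YOLOv8-seg decoupled head: unshared per-level branches + prototypes."""

    def __init__(self, rng, ch: tuple[int, int, int], nc: int = 80,
                 reg_max: int = 16, nm: int = 32, npr: int = 64):
        super().__init__()
        self.ch = tuple(ch)
        self.nc, self.reg_max, self.nm = nc, reg_max, nm
        c2 = ch[0]                    # regression hidden width
        c3 = ch[0]                    # classification hidden width
        c4 = max(ch[0] // 4, nm)      # mask-coefficient hidden width
        self.reg_branch = ModuleList([
            Sequential([ConvBN(rng, c, c2, 3), ConvBN(rng, c2, c2, 3),
                        Conv2d(rng, c2, 4 * reg_max, 1, bias=True)])
            for c in ch])
        self.cls_branch = ModuleList([
            Sequential([ConvBN(rng, c, c3, 3), ConvBN(rng, c3, c3, 3),
                        Conv2d(rng, c3, nc, 1, bias=True)])
            for c in ch])
        self.coef_branch = ModuleList([
            Sequential([ConvBN(rng, c, c4, 3), ConvBN(rng, c4, c4, 3),
                        Conv2d(rng, c4, nm, 1, bias=True)])
            for c in ch])
        self.proto = Proto(rng, ch[0], npr, nm, norm="bn")
        for br in self.reg_branch:
            br[-1].bias.data[...] = 1.0
        for br in self.cls_branch:
            br[-1].bias.data[...] = -4.6

    def forward(self, n3, n4, n5) -> HeadOutput:
        feats = (n3, n4, n5)
        for f, c in zip(feats, self.ch):
            if f.shape[1] != c:
                raise ValueError(
                    f"head level channel mismatch: got {f.shape[1]}, expected {c}")
        reg = [b(f) for b, f in zip(self.reg_branch, feats)]
        cls = [b(f) for b, f in zip(self.cls_branch, feats)]
        coef = [b(f) for b, f in zip(self.coef_branch, feats)]
        return HeadOutput(reg=reg, cls=cls, coef=coef,
                          protos=self.proto(n3), reg_max=self.reg_max)
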