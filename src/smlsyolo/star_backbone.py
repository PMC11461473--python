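"""Star-operation backbone (StarNet-style feature extractor).

The *star operation* multiplies two learned linear projections of the same
feature map element-wise, ``act(f1(x)) * f2(x)``.  The product of two linear
forms contains all pairwise feature interactions, so a narrow network gains
the expressive power of a much higher-dimensional (implicit, polynomial-
kernel-like) feature space at the cost of one extra point-wise convolution.
The backbone stacks a stride-2 stem and four stages of
(stride-2 downsampling conv -> StarBlocks) and exposes the last three stage
outputs as a stride-8/16/32 feature pyramid.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn import autograd as A
from .nn.modules import BatchNorm2d, Conv2d, Module, ModuleList, Sequential
from .layers import ConvBN


def star_operation(x, branch1, branch2, act=A.relu6):
    """``act(branch1(x)) * branch2(x)`` — element-wise feature interaction."""
    a = branch1(x) if callable(branch1) else branch1
    b = branch2(x) if callable(branch2) else branch2
    if a.shape != b.shape:
        raise ValueError(f"star_operation branch shapes differ: {a.shape} vs {b.shape}")
    return A.mul(act(a), b)


@dataclass
class StarBlockConfig:
    dim: int
    mlp_ratio: int = 4
    dw_kernel: int = 7

    def __post_init__(self):
        if self.dim < 1 or self.mlp_ratio < 1:
            raise ValueError("dim and mlp_ratio must be >= 1")
        if self.dw_kernel % 2 == 0:
            raise ValueError("dw_kernel must be odd")


class StarBlock(Module):
    """Residual block built around the star operation.

    depthwise conv + BN -> two parallel 1x1 expansions -> star operation ->
    1x1 projection + BN -> depthwise conv -> residual add.  Bias is carried
    by convs that are not followed by a normalisation layer.
    """

    def __init__(self, rng, dim: int, mlp_ratio: int = 4, dw_kernel: int = 7):
        super().__init__()
        StarBlockConfig(dim, mlp_ratio, dw_kernel)  # validate
        hidden = dim * mlp_ratio
        self.dw1 = Conv2d(rng, dim, dim, dw_kernel, groups=dim, bias=False)
        self.bn1 = BatchNorm2d(dim)
        self.f1 = Conv2d(rng, dim, hidden, 1, bias=True)
        self.f2 = Conv2d(rng, dim, hidden, 1, bias=True)
        self.g = Conv2d(rng, hidden, dim, 1, bias=False)
        self.bn2 = BatchNorm2d(dim)
        self.dw2 = Conv2d(rng, dim, dim, dw_kernel, groups=dim, bias=True)

    def forward(self, x):
        y = self.bn1(self.dw1(x))
        z = star_operation(y, self.f1, self.f2)
        z = self.dw2(self.bn2(self.g(z)))
        return A.add(x, z)


class StarNet(Module):
    """Four-stage star-operation backbone emitting a stride-8/16/32 pyramid."""

    def __init__(self, rng, dims=(24, 48, 96, 192), depths=(1, 1, 2, 1),
                 stem_ch: int = 32, mlp_ratio: int = 4, dw_kernel: int = 7):
        super().__init__()
        if len(dims) != 4 or len(depths) != 4:
            raise ValueError("dims and depths must have four entries")
        self.dims, self.depths = tuple(dims), tuple(depths)
        self.stem = ConvBN(rng, 3, stem_ch, 3, 2, act="relu6")
        stages = []
        prev = stem_ch
        for dim, depth in zip(dims, depths):
            layers = [ConvBN(rng, prev, dim, 3, 2, act="relu6")]
            layers += [StarBlock(rng, dim, mlp_ratio, dw_kernel)
                       for _ in range(depth)]
            stages.append(Sequential(layers))
            prev = dim
        self.stages = ModuleList(stages)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(
                f"input size {h}x{w} must be a multiple of 32 (no padding)")
        x = self.stem(x)
        outs = []
        for stage in self.stages:
            x = stage(x)
            outs.append(x)
        # stages 2..4 correspond to strides 8, 16, 32
        return {"P3": outs[1], "P4": outs[2], "P5": outs[3]}


class CSPBackbone(Module):
    """YOLOv8n-style cross-stage-partial backbone (the comparison baseline)."""

    def __init__(self, rng, width=(16, 32, 64, 128, 256), depths=(1, 2, 2, 1)):
        super().__init__()
        from .neck import C2f  # local import to avoid a cycle
        w0, w1, w2, w3, w4 = width
        self.stem = ConvBN(rng, 3, w0, 3, 2)
        self.down1 = ConvBN(rng, w0, w1, 3, 2)
        self.c2f1 = C2f(rng, w1, w1, depths[0], shortcut=True)
        self.down2 = ConvBN(rng, w1, w2, 3, 2)
        self.c2f2 = C2f(rng, w2, w2, depths[1], shortcut=True)
        self.down3 = ConvBN(rng, w2, w3, 3, 2)
        self.c2f3 = C2f(rng, w3, w3, depths[2], shortcut=True)
        self.down4 = ConvBN(rng, w3, w4, 3, 2)
        self.c2f4 = C2f(rng, w4, w4, depths[3], shortcut=True)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(
                f"input size {h}x{w} must be a multiple of 32 (no padding)")
        x = self.stem(x)
        x = self.c2f1(self.down1(x))
        p3 = self.c2f2(self.down2(x))
        p4 = self.c2f3(self.down3(p3))
        p5 = self.c2f4(self.down4(p4))
        return {"P3": p3, "P4": p4, "P5": p5}
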