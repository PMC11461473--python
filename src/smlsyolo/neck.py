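"""Feature-pyramid fusion: C2f / C2f-Star blocks, SPPF, and multi-head
self-attention applied to the deepest backbone map.

The top-down / bottom-up layout follows the YOLOv8 PAN convention; in the
lightweight variant every fusion block is a C2f-Star (inner bottlenecks
replaced by star-operation blocks) and the stride-32 map is refined by MHSA
right after spatial-pyramid pooling, where the token grid is smallest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autograd as A
from .nn.modules import Conv2d, Identity, Module, ModuleList, Parameter, Sequential
from .layers import ConvBN
from .star_backbone import StarBlock


class Bottleneck(Module):
    """Standard C2f inner block: two 3x3 convs with optional residual."""

    def __init__(self, rng, ch: int, shortcut: bool = True):
        super().__init__()
        self.cv1 = ConvBN(rng, ch, ch, 3)
        self.cv2 = ConvBN(rng, ch, ch, 3)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return A.add(x, y) if self.shortcut else y


@dataclass
class C2fStarConfig:
    in_channels: int
    out_channels: int
    n_blocks: int = 1

    def __post_init__(self):
        if self.out_channels % 2:
            raise ValueError("out_channels must be even (split into halves)")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    @property
    def hidden(self) -> int:
        return self.out_channels // 2


class C2f(Module):
    """Split-transform-concatenate fusion block.

    A 1x1 conv maps to ``out_channels`` which is split into two halves; one
    half runs through a chain of inner blocks whose every intermediate output
    is retained; the ``(2 + n) * hidden`` concatenated channels are fused by
    a final 1x1 conv.  ``inner='star'`` gives the C2f-Star variant.
    """

    def __init__(self, rng, c1: int, c2: int, n: int = 1,
                 shortcut: bool = False, inner: str = "bottleneck"):
        super().__init__()
        cfg = C2fStarConfig(c1, c2, n)
        h = cfg.hidden
        self.hidden = h
        self.cv1 = ConvBN(rng, c1, c2, 1)
        self.cv2 = ConvBN(rng, (2 + n) * h, c2, 1)
        if inner == "star":
            blocks = [StarBlock(rng, h) for _ in range(n)]
        elif inner == "bottleneck":
            blocks = [Bottleneck(rng, h, shortcut) for _ in range(n)]
        else:  # identity inner blocks, used in equivalence tests
            blocks = [Identity() for _ in range(n)]
        self.blocks = ModuleList(blocks)

    def forward(self, x):
        y = self.cv1(x)
        a = A.narrow(y, 1, 0, self.hidden)
        b = A.narrow(y, 1, self.hidden, self.hidden)
        outs = [a, b]
        for blk in self.blocks:
            outs.append(blk(outs[-1]))
        return self.cv2(A.concat(outs, axis=1))


def C2fStar(rng, c1: int, c2: int, n: int = 1) -> C2f:
    return C2f(rng, c1, c2, n, inner="star")


class SPPF(Module):
    """Spatial-pyramid pooling (fast): three chained 5x5 max-pools."""

    def __init__(self, rng, c1: int, c2: int, k: int = 5):
        super().__init__()
        h = c1 // 2
        self.cv1 = ConvBN(rng, c1, h, 1)
        self.cv2 = ConvBN(rng, 4 * h, c2, 1)
        self.k = k

    def forward(self, x):
        x = self.cv1(x)
        p1 = A.maxpool2d(x, self.k, 1, self.k // 2)
        p2 = A.maxpool2d(p1, self.k, 1, self.k // 2)
        p3 = A.maxpool2d(p2, self.k, 1, self.k // 2)
        return self.cv2(A.concat([x, p1, p2, p3], axis=1))


@dataclass
class MHSAConfig:
    embed_dim: int
    n_heads: int = 4
    pos_enc: bool = True

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}")


class MHSA(Module):
    """Multi-head self-attention over the flattened spatial grid.

    Queries/keys/values come from learned 1x1 projections; each head applies
    scaled dot-product attention ``softmax(Q K^T / sqrt(d_head)) V``; heads
    are concatenated, linearly projected and added back to the input.  The
    learned 2-D positional encoding is factorised into a per-row and a
    per-column embedding (their broadcast sum covers the grid); at a grid
    size other than the configured one it is linearly resampled.
    """

    def __init__(self, rng, embed_dim: int, n_heads: int = 4,
                 pos_enc: bool = True, grid: tuple[int, int] = (20, 20),
                 residual: bool = True):
        super().__init__()
        self.cfg = MHSAConfig(embed_dim, n_heads, pos_enc)
        self.wq = Conv2d(rng, embed_dim, embed_dim, 1, bias=False)
        self.wk = Conv2d(rng, embed_dim, embed_dim, 1, bias=False)
        self.wv = Conv2d(rng, embed_dim, embed_dim, 1, bias=False)
        self.wo = Conv2d(rng, embed_dim, embed_dim, 1, bias=True)
        self.residual = residual
        if pos_enc:
            self.pos_h = Parameter(
                (0.02 * rng.standard_normal((1, embed_dim, grid[0], 1))).astype(np.float32))
            self.pos_w = Parameter(
                (0.02 * rng.standard_normal((1, embed_dim, 1, grid[1]))).astype(np.float32))
        self.last_attention: np.ndarray | None = None

    def _encoded(self, x):
        if not self.cfg.pos_enc:
            return x
        h, w = x.shape[2], x.shape[3]
        ph, pw = self.pos_h, self.pos_w
        if ph.shape[2] != h or pw.shape[3] != w:
            # resample the stored encodings to the observed grid
            def resample(arr, n, axis):
                src = np.linspace(0.0, 1.0, arr.shape[axis])
                dst = np.linspace(0.0, 1.0, n)
                moved = np.moveaxis(arr, axis, -1)
                out = np.stack([np.interp(dst, src, row) for row in
                                moved.reshape(-1, arr.shape[axis])])
                return np.moveaxis(
                    out.reshape(moved.shape[:-1] + (n,)), -1, axis)
            ph = A.Tensor(resample(self.pos_h.data, h, 2).astype(np.float32))
            pw = A.Tensor(resample(self.pos_w.data, w, 3).astype(np.float32))
        return A.add(x, A.add(ph, pw))

    def forward(self, x):
        if x.shape[1] != self.cfg.embed_dim:
            raise ValueError(
                f"MHSA expects {self.cfg.embed_dim} channels, got {x.shape[1]}")
        n, c, h, w = x.shape
        heads, dh = self.cfg.n_heads, c // self.cfg.n_heads
        xe = self._encoded(x)
        q, k, v = self.wq(xe), self.wk(xe), self.wv(xe)

        def to_tokens(t):
            t = A.reshape(t, (n, heads, dh, h * w))
            return A.transpose(t, (0, 1, 3, 2))  # (n, heads, T, dh)

        q, k, v = to_tokens(q), to_tokens(k), to_tokens(v)
        attn = A.softmax(
            A.mul(A.matmul(q, A.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh)),
            axis=-1)
        self.last_attention = attn.data
        out = A.matmul(attn, v)                       # (n, heads, T, dh)
        out = A.reshape(A.transpose(out, (0, 1, 3, 2)), (n, c, h, w))
        out = self.wo(out)
        return A.add(x, out) if self.residual else out


class Neck(Module):
    """SPPF (+ optional MHSA) then top-down / bottom-up pyramid fusion."""

    def __init__(self, rng, ch: tuple[int, int, int],
                 out_ch: tuple[int, int, int], inner: str = "star",
                 n_blocks: int = 1, use_mhsa: bool = True, mhsa_heads: int = 4,
                 grid: tuple[int, int] = (20, 20), pos_enc: bool = True):
        super().__init__()
        c3, c4, c5 = ch
        n3, n4, n5 = out_ch
        self.ch = tuple(ch)
        self.sppf = SPPF(rng, c5, c5)
        self.attn = MHSA(rng, c5, mhsa_heads, pos_enc=pos_enc, grid=grid) \
            if use_mhsa else Identity()
        kw = dict(inner=inner)
        self.td1 = C2f(rng, c5 + c4, n4, n_blocks, **kw)
        self.td2 = C2f(rng, n4 + c3, n3, n_blocks, **kw)
        self.down1 = ConvBN(rng, n3, n3, 3, 2)
        self.bu1 = C2f(rng, n3 + n4, n4, n_blocks, **kw)
        self.down2 = ConvBN(rng, n4, n4, 3, 2)
        self.bu2 = C2f(rng, n4 + c5, n5, n_blocks, **kw)

    def forward(self, p3, p4, p5):
        if not (p3.shape[2] == 2 * p4.shape[2] == 4 * p5.shape[2]):
            raise ValueError("pyramid strides must be 8/16/32 (2x spatial steps)")
        p5 = self.attn(self.sppf(p5))
        t4 = self.td1(A.concat([A.upsample_nearest2x(p5), p4], axis=1))
        n3 = self.td2(A.concat([A.upsample_nearest2x(t4), p3], axis=1))
        n4 = self.bu1(A.concat([self.down1(n3), t4], axis=1))
        n5 = self.bu2(A.concat([self.down2(n4), p5], axis=1))
        return n3, n4, n5
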