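"""Common convolutional building blocks (conv + norm + activation)."""

from __future__ import annotations

from .nn import autograd as A
from .nn.modules import BatchNorm2d, Conv2d, GroupNorm, Module

_ACTS = {
    "silu": A.silu,
    "relu6": A.relu6,
    None: lambda x: x,
    "none": lambda x: x,
}


class ConvBN(Module):
    """Convolution (no bias) + batch normalisation + activation."""

    def __init__(self, rng, c1: int, c2: int, k: int = 1, s: int = 1,
                 groups: int = 1, act: str | None = "silu"):
        super().__init__()
        self.conv = Conv2d(rng, c1, c2, k, s, groups=groups, bias=False)
        self.bn = BatchNorm2d(c2)
        self._act = _ACTS[act]

    def forward(self, x):
        return self._act(self.bn(self.conv(x)))


class ConvGN(Module):
    """Convolution (no bias) + group normalisation + activation.

    Group normalisation makes the output independent of batch size, which
    keeps small-batch behaviour identical to large-batch behaviour.
    """

    def __init__(self, rng, c1: int, c2: int, k: int = 1, s: int = 1,
                 groups_norm: int = 16, act: str | None = "silu"):
        super().__init__()
        self.conv = Conv2d(rng, c1, c2, k, s, bias=False)
        self.gn = GroupNorm(groups_norm, c2)
        self._act = _ACTS[act]

    def forward(self, x):
        return self._act(self.gn(self.conv(x)))
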