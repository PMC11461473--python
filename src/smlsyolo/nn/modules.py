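"""Layer/module abstractions on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from . import autograd as A
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Composable layer with named parameters and train/eval modes."""

    def __init__(self) -> None:
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield (prefix + k, p)
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for k, b in self._buffers.items():
            yield (prefix + k, b)
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix + k + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def num_params(self) -> int:
        """Trainable scalar count (normalisation affine included,
        running statistics excluded)."""
        return sum(p.data.size for p in self.parameters() if p.requires_grad)

    # state (de)serialisation -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        for k, b in self.named_buffers():
            state["buffer:" + k] = b.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for k, v in state.items():
            if k.startswith("buffer:"):
                continue
            params[k].data[...] = v
        # buffers are stored by reference on their owning modules
        for name, m in self._walk(""):
            for bk in list(m._buffers):
                full = "buffer:" + name + bk
                if full in state:
                    m._buffers[bk][...] = state[full]

    def _walk(self, prefix):
        yield prefix, self
        for k, m in self._modules.items():
            yield from m._walk(prefix + k + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        idx = len(self._list)
        self._list.append(m)
        self._modules[str(idx)] = m
        object.__setattr__(self, str(idx), m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = float(np.sqrt(6.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int = 1,
                 stride: int = 1, pad: int | None = None, groups: int = 1,
                 bias: bool = True):
        super().__init__()
        if pad is None:
            pad = kernel // 2
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad, self.groups = kernel, stride, pad, groups
        fan_in = in_ch // groups * kernel * kernel
        self.weight = Parameter(
            _kaiming(rng, (out_ch, in_ch // groups, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x):
        return A.conv2d(x, self.weight, self.bias, stride=self.stride,
                        pad=self.pad, groups=self.groups)


class BatchNorm2d(Module):
    """Batch-statistics normalisation; frozen-statistics mode in eval()."""

    def __init__(self, ch: int, momentum: float = 0.03, eps: float = 1e-3):
        super().__init__()
        self.gamma = Parameter(np.ones(ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(ch, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(ch, dtype=np.float32))
        self.register_buffer("running_var", np.ones(ch, dtype=np.float32))
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return A.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training,
                            momentum=self.momentum, eps=self.eps)


class GroupNorm(Module):
    def __init__(self, groups: int, ch: int, eps: float = 1e-5):
        super().__init__()
        self.groups = min(groups, ch)
        while ch % self.groups:
            self.groups -= 1
        self.gamma = Parameter(np.ones(ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(ch, dtype=np.float32))
        self.eps = eps

    def forward(self, x):
        return A.group_norm(x, self.gamma, self.beta, self.groups, eps=self.eps)


class SGD:
    """SGD with momentum and (coupled) weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
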