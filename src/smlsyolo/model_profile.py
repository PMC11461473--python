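"""Parameter and FLOP profiling of assembled models.

FLOPs are accumulated analytically during a forward pass under the
2 x multiply-accumulate convention: a convolution contributes
``2 * k^2 * C_in * C_out * H_out * W_out / groups``, a linear map
``2 * in * out`` per position, and each attention head ``2 * T^2 * d`` for
Q K^T and again for the attention-weighted sum.  Normalisation, activations,
pooling and resampling are not counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import FlopCounter, Tensor
from .nn.modules import Module
from .model import ModelConfig, SegmentationModel, build_model


def count_params(model: Module) -> int:
    """Trainable scalars (normalisation scale/shift included, running
    statistics excluded)."""
    return model.num_params()


def count_gflops(model: Module, image_size: int | None = None,
                 batch: int = 1) -> float:
    if image_size is None:
        image_size = getattr(getattr(model, "cfg", None), "image_size", 640)
    if image_size % 32:
        raise ValueError("image_size must be a multiple of 32")
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((batch, 3, image_size, image_size), dtype=np.float32))
    with FlopCounter() as fc:
        model(x)
    if was_training:
        model.train()
    return fc.total / 1e9


@dataclass
class ProfileReport:
    variant: str
    image_size: int
    total_params: int
    head_params: int
    gflops: float

    @property
    def head_fraction(self) -> float:
        return 100.0 * self.head_params / self.total_params

    @property
    def total_params_m(self) -> float:
        return round(self.total_params / 1e6, 1)

    @property
    def head_params_m(self) -> float:
        return round(self.head_params / 1e6, 2)

    def breakdown(self, model: SegmentationModel) -> dict[str, int]:
        return {name: m.num_params()
                for name, m in (("backbone", model.backbone),
                                ("neck", model.neck), ("head", model.head))}

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "image_size": self.image_size,
            "total_params": self.total_params,
            "total_params_m": self.total_params_m,
            "head_params": self.head_params,
            "head_params_m": self.head_params_m,
            "head_fraction_pct": round(self.head_fraction, 1),
            "gflops": round(self.gflops, 1),
        }


def profile_model(cfg: ModelConfig, seed: int = 0,
                  image_size: int | None = None) -> ProfileReport:
    model = build_model(cfg, seed=seed)
    size = image_size or cfg.image_size
    return ProfileReport(
        variant=cfg.variant,
        image_size=size,
        total_params=count_params(model),
        head_params=count_params(model.head),
        gflops=count_gflops(model, size),
    )
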