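"""Batch prediction and model evaluation on labelled samples."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor
from .data import ImageSample, polygon_to_mask
from .metrics import MetricReport, evaluate
from .postprocess import PredictionInstance, decode_predictions
from .training import prepare_targets


@dataclass
class GtInstance:
    """Ground truth in pixel space at the evaluation resolution."""
    class_id: int
    box: tuple
    mask: np.ndarray


def predict_samples(model, samples: list[ImageSample],
                    image_size: int | None = None, conf: float = 0.25,
                    iou: float = 0.7, batch: int = 4
                    ) -> list[list[PredictionInstance]]:
    if image_size is None:
        image_size = model.cfg.image_size
    was_training = model.training
    model.eval()
    preds: list[list[PredictionInstance]] = []
    for b0 in range(0, len(samples), batch):
        x, _ = prepare_targets(samples[b0:b0 + batch], image_size)
        head_out = model(Tensor(x))
        preds.extend(decode_predictions(head_out, image_size, conf=conf,
                                        iou_nms=iou))
    if was_training:
        model.train()
    return preds


def ground_truths_px(samples: list[ImageSample], image_size: int
                     ) -> list[list[GtInstance]]:
    gts = []
    for s in samples:
        items = []
        for a in s.instances:
            x1, y1, x2, y2 = a.box
            items.append(GtInstance(
                a.class_id,
                (x1 * image_size, y1 * image_size,
                 x2 * image_size, y2 * image_size),
                polygon_to_mask(a.polygon, image_size, image_size)))
        gts.append(items)
    return gts


def evaluate_model(model, samples: list[ImageSample],
                   image_size: int | None = None, conf: float = 0.001,
                   iou_nms: float = 0.7, times=None,
                   plot_dir=None) -> MetricReport:
    """Low-confidence prediction + mAP@0.5 evaluation (box and mask)."""
    if image_size is None:
        image_size = model.cfg.image_size
    preds = predict_samples(model, samples, image_size, conf=conf, iou=iou_nms)
    gts = ground_truths_px(samples, image_size)
    classes = sorted({g.class_id for per in gts for g in per} | {0})
    return evaluate(preds, gts, classes, times=times, plot_dir=plot_dir)
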