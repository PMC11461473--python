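"""Decoding raw head outputs into scored instances.

Box regression is distribution-focal: each side's logits over ``reg_max``
bins are softmaxed and reduced to their expected bin value, giving a
distance from the cell's anchor point in stride units; the per-level Scale
scalar multiplies these distances before conversion to pixels.  Masks are
assembled YOLACT-style: sigmoid of the coefficient-weighted prototype sum,
bilinearly upsampled, thresholded strictly above 0.5 and cropped to the box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PredictionInstance:
    box: tuple  # (x1, y1, x2, y2) pixels
    score: float
    class_id: int
    mask: np.ndarray | None = None  # bool raster at input resolution
    coeffs: np.ndarray | None = None


def _np(x):
    if isinstance(x, np.ndarray):
        return x
    return x.data if hasattr(x, "data") else np.asarray(x)


def anchor_points(h: int, w: int, stride: int) -> np.ndarray:
    """(h*w, 2) pixel coordinates of cell centres."""
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64) + 0.5
    return np.column_stack([xs.ravel(), ys.ravel()]) * stride


def decode_boxes(reg_logits, stride: int, scale: float = 1.0,
                 reg_max: int = 16) -> np.ndarray:
    """(N, 4*reg_max, H, W) logits -> (N, H*W, 4) pixel boxes."""
    r = _np(reg_logits)
    scale = float(_np(scale))
    n, c, h, w = r.shape
    assert c == 4 * reg_max
    r = r.reshape(n, 4, reg_max, h * w)
    z = r - r.max(axis=2, keepdims=True)
    e = np.exp(z)
    prob = e / e.sum(axis=2, keepdims=True)
    dist = (prob * np.arange(reg_max).reshape(1, 1, reg_max, 1)).sum(axis=2)
    dist = dist * scale * stride                       # (n, 4, h*w) pixels
    pts = anchor_points(h, w, stride)                  # (h*w, 2)
    x1 = pts[None, :, 0] - dist[:, 0]
    y1 = pts[None, :, 1] - dist[:, 1]
    x2 = pts[None, :, 0] + dist[:, 2]
    y2 = pts[None, :, 1] + dist[:, 3]
    return np.stack([x1, y1, x2, y2], axis=-1)


def nms(instances: list[PredictionInstance], iou_threshold: float = 0.7,
        score_threshold: float = 0.25) -> list[PredictionInstance]:
    """Greedy class-aware suppression, deterministic ordering."""
    if not (0 <= iou_threshold <= 1 and 0 <= score_threshold <= 1):
        raise ValueError("thresholds must be in [0, 1]")
    from .metrics import box_iou
    cands = [p for p in instances if p.score >= score_threshold]
    cands.sort(key=lambda p: (-p.score, p.box))
    kept: list[PredictionInstance] = []
    for p in cands:
        if any(k.class_id == p.class_id and box_iou(k.box, p.box) > iou_threshold
               for k in kept):
            continue
        kept.append(p)
    return kept


def bilinear_resize(arr: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resampling with align_corners=False convention."""
    in_h, in_w = arr.shape[-2:]
    ys = (np.arange(out_h) + 0.5) * in_h / out_h - 0.5
    xs = (np.arange(out_w) + 0.5) * in_w / out_w - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, in_h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, in_w - 1)
    y1 = np.clip(y0 + 1, 0, in_h - 1)
    x1 = np.clip(x0 + 1, 0, in_w - 1)
    wy = np.clip(ys - y0, 0, 1)
    wx = np.clip(xs - x0, 0, 1)
    top = arr[..., y0[:, None], x0[None, :]] * (1 - wx) + \
        arr[..., y0[:, None], x1[None, :]] * wx
    bot = arr[..., y1[:, None], x0[None, :]] * (1 - wx) + \
        arr[..., y1[:, None], x1[None, :]] * wx
    return top + (bot - top) * wy[:, None]


def assemble_mask(prototypes, coeffs, box, out_shape) -> np.ndarray:
    """sigmoid(sum_k coeff_k * proto_k) -> upsample -> strict >0.5 -> crop."""
    protos = _np(prototypes)
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.shape[0] != protos.shape[0]:
        raise ValueError(
            f"coefficient count {coeffs.shape[0]} != prototype count {protos.shape[0]}")
    logits = np.tensordot(coeffs, protos, axes=(0, 0))
    from .nn.autograd import _stable_sigmoid
    prob = _stable_sigmoid(bilinear_resize(logits, *out_shape))
    mask = prob > 0.5
    x1, y1, x2, y2 = box
    h, w = out_shape
    crop = np.zeros_like(mask)
    xa, ya = max(int(np.floor(x1)), 0), max(int(np.floor(y1)), 0)
    xb, yb = min(int(np.ceil(x2)), w), min(int(np.ceil(y2)), h)
    if xb > xa and yb > ya:
        crop[ya:yb, xa:xb] = mask[ya:yb, xa:xb]
    return crop


def decode_predictions(head_out, image_size: int, conf: float = 0.25,
                       iou_nms: float = 0.7, max_det: int = 100
                       ) -> list[list[PredictionInstance]]:
    """HeadOutput -> per-image list of final instances."""
    reg_max = head_out.reg_max
    n = _np(head_out.reg[0]).shape[0]
    per_image: list[list[PredictionInstance]] = [[] for _ in range(n)]
    boxes_all, scores_all, cls_all, coef_all = [], [], [], []
    for lvl, stride in enumerate(head_out.strides):
        scale = float(_np(head_out.scales[lvl]))
        boxes = decode_boxes(head_out.reg[lvl], stride, scale, reg_max)
        cls = _np(head_out.cls[lvl])
        nc = cls.shape[1]
        hw = cls.shape[2] * cls.shape[3]
        from .nn.autograd import _stable_sigmoid
        scores = _stable_sigmoid(cls.reshape(n, nc, hw))
        coefs = _np(head_out.coef[lvl]).reshape(n, -1, hw)
        boxes_all.append(boxes)
        scores_all.append(scores)
        coef_all.append(coefs)
    protos = _np(head_out.protos)
    for i in range(n):
        cands = []
        for boxes, scores, coefs in zip(boxes_all, scores_all, coef_all):
            best_c = scores[i].argmax(axis=0)
            best_s = scores[i].max(axis=0)
            keep = np.nonzero(best_s >= conf)[0]
            for a in keep:
                cands.append(PredictionInstance(
                    box=tuple(np.clip(boxes[i, a],
                                      [0, 0, 0, 0],
                                      [image_size] * 4)),
                    score=float(best_s[a]), class_id=int(best_c[a]),
                    coeffs=coefs[i, :, a]))
        kept = nms(cands, iou_nms, conf)[:max_det]
        for p in kept:
            p.mask = assemble_mask(protos[i], p.coeffs, p.box,
                                   (image_size, image_size))
        per_image[i] = [p for p in kept]
    return per_image
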