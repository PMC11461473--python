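"""Detection / segmentation evaluation: confusion counting at IoU 0.5,
precision, recall, F1, all-point-interpolated average precision, mAP@0.5,
pixel IoU and FPS.

Conventions (documented and tested):
  * a prediction matches a ground truth only if IoU is strictly > the
    threshold (default 0.5);
  * matching is greedy in descending score, one-to-one within a class;
  * P = 0 when tp + fp = 0, R = 0 when tp + fn = 0, F1 = 0 when P + R = 0;
  * AP is the exact area under the monotone (upper-envelope) P-R staircase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other):
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn)


def box_iou(a, b) -> float:
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter) / float(union) if union else 0.0


def pixel_iou(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """TP / (TP + FP + FN) over pixels."""
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(
            f"mask shapes differ: {pred_mask.shape} vs {gt_mask.shape}")
    return mask_iou(pred_mask.astype(bool), gt_mask.astype(bool))


def match_instances(predictions, ground_truths, iou_threshold: float = 0.5,
                    kind: str = "box"):
    """Greedy score-descending one-to-one matching within one image.

    ``predictions`` carry .score, .class_id and .box / .mask;
    ``ground_truths`` carry .class_id and .box / a mask raster.
    Returns (ConfusionCounts, per-prediction TP flags in score order,
    scores in that order).
    """
    order = sorted(range(len(predictions)),
                   key=lambda i: (-predictions[i].score, i))
    matched = [False] * len(ground_truths)
    flags, scores = [], []
    tp = 0
    for i in order:
        p = predictions[i]
        best_iou, best_j = iou_threshold, -1
        for j, g in enumerate(ground_truths):
            if matched[j] or g.class_id != p.class_id:
                continue
            if kind == "box":
                iou = box_iou(p.box, _gt_box(g))
            else:
                iou = mask_iou(p.mask, _gt_mask(g, p.mask.shape))
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0:
            matched[best_j] = True
            tp += 1
            flags.append(True)
        else:
            flags.append(False)
        scores.append(p.score)
    fp = len(predictions) - tp
    fn = len(ground_truths) - tp
    return ConfusionCounts(tp, fp, fn), flags, scores


def _gt_box(g):
    box = g.box
    return box


def _gt_mask(g, shape):
    if hasattr(g, "mask") and not callable(getattr(g, "mask", None)):
        return g.mask
    return g.mask(shape[0], shape[1])


def precision_recall_f1(counts: ConfusionCounts):
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def f1_score(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r else 0.0


def pr_staircase(flags, scores, n_ground_truth: int):
    """Recall/precision staircase points sorted by descending score."""
    order = np.argsort(-np.asarray(scores, dtype=np.float64), kind="stable")
    flags = np.asarray(flags, dtype=np.float64)[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(1.0 - flags)
    recall = tp_cum / max(n_ground_truth, 1)
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    return recall, precision


def average_precision(flags, scores, n_ground_truth: int) -> float:
    """Exact area under the monotone precision envelope over recall."""
    if n_ground_truth == 0:
        return 0.0
    if len(flags) == 0:
        return 0.0
    recall, precision = pr_staircase(flags, scores, n_ground_truth)
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[1.0], precision, [0.0]])
    # monotone non-increasing envelope
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.nonzero(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def map50(per_class_aps) -> float:
    aps = list(per_class_aps)
    if not aps:
        raise ValueError("need at least one class AP")
    return float(np.mean(aps))


def fps(per_image_seconds) -> float:
    times = np.asarray(list(per_image_seconds), dtype=np.float64)
    if len(times) == 0 or (times <= 0).any():
        raise ValueError("durations must be positive")
    return float(1.0 / times.mean())


def pr_curve(flags, scores, n_ground_truth: int, plot_path=None):
    """Staircase points used by ``average_precision``; optionally writes a
    plot.  The area under the returned curve equals the AP value."""
    if len(flags) == 0 or n_ground_truth == 0:
        points = []
    else:
        recall, precision = pr_staircase(flags, scores, n_ground_truth)
        points = list(zip(recall.tolist(), precision.tolist()))
    ap = average_precision(flags, scores, n_ground_truth)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 4))
        if points:
            r = [0.0] + [pt[0] for pt in points]
            p = [1.0] + [pt[1] for pt in points]
            ax.step(r, p, where="post")
        ax.set_xlabel("Recall")
        ax.set_ylabel("Precision")
        ax.set_xlim(0, 1.05)
        ax.set_ylim(0, 1.05)
        ax.set_title(f"P-R curve (AP={ap:.3f})")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=100)
        plt.close(fig)
    return points, ap


@dataclass
class MetricReport:
    """Per-class and aggregate metrics for box and mask tasks."""

    classes: list = field(default_factory=list)
    box_p: float = 0.0
    box_r: float = 0.0
    box_f1: float = 0.0
    box_map50: float = 0.0
    mask_p: float = 0.0
    mask_r: float = 0.0
    mask_f1: float = 0.0
    mask_map50: float = 0.0
    pixel_iou: float = 0.0
    fps: float | None = None

    def to_dict(self) -> dict:
        pct = lambda v: round(100.0 * v, 1)
        d = {
            "box": {"P": pct(self.box_p), "R": pct(self.box_r),
                    "F1": pct(self.box_f1), "F1_int": round(100 * self.box_f1),
                    "mAP50": pct(self.box_map50)},
            "mask": {"P": pct(self.mask_p), "R": pct(self.mask_r),
                     "F1": pct(self.mask_f1), "F1_int": round(100 * self.mask_f1),
                     "mAP50": pct(self.mask_map50)},
            "pixel_iou": pct(self.pixel_iou),
        }
        if self.fps is not None:
            d["fps"] = round(self.fps, 1)
        return d


def evaluate(predictions_per_image, ground_truths_per_image, classes,
             iou_threshold: float = 0.5, times=None,
             plot_dir=None) -> MetricReport:
    """Aggregate matching across images into a MetricReport.

    ``predictions_per_image``: list over images of PredictionInstance lists;
    ``ground_truths_per_image``: list over images of InstanceAnnotation lists.
    """
    report = MetricReport(classes=list(classes))
    results = {}
    for kind in ("box", "mask"):
        per_class_ap = []
        total = ConfusionCounts()
        all_flags_scores = {c: ([], [], 0) for c in classes}
        for preds, gts in zip(predictions_per_image, ground_truths_per_image):
            for c in classes:
                pc = [p for p in preds if p.class_id == c]
                gc = [g for g in gts if g.class_id == c]
                counts, flags, scores = match_instances(
                    pc, gc, iou_threshold, kind)
                total = total + counts
                f, s, n = all_flags_scores[c]
                all_flags_scores[c] = (f + flags, s + scores, n + len(gc))
        for c in classes:
            f, s, n = all_flags_scores[c]
            if plot_dir is not None:
                from pathlib import Path
                _, ap = pr_curve(f, s, n,
                                 Path(plot_dir) / f"pr_{kind}_class{c}.png")
            else:
                ap = average_precision(f, s, n)
            per_class_ap.append(ap)
        p, r, f1 = precision_recall_f1(total)
        results[kind] = (p, r, f1, map50(per_class_ap))
    report.box_p, report.box_r, report.box_f1, report.box_map50 = results["box"]
    report.mask_p, report.mask_r, report.mask_f1, report.mask_map50 = results["mask"]
    # dataset-level pixel IoU: union of instance masks per image
    inter = union_p = union_g = 0
    for preds, gts in zip(predictions_per_image, ground_truths_per_image):
        if not preds and not gts:
            continue
        shape = None
        if preds:
            shape = preds[0].mask.shape
        pm = np.zeros(shape, dtype=bool) if shape else None
        for p in preds:
            pm |= p.mask.astype(bool)
        if pm is None and gts:
            continue
        gm = np.zeros_like(pm)
        for g in gts:
            gm |= _gt_mask(g, pm.shape).astype(bool)
        inter += np.logical_and(pm, gm).sum()
        union_p += np.logical_and(pm, ~gm).sum()
        union_g += np.logical_and(~pm, gm).sum()
    denom = inter + union_p + union_g
    report.pixel_iou = float(inter) / denom if denom else 0.0
    if times:
        report.fps = fps(times)
    return report
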