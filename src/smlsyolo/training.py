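"""Desk-scale training: task-aligned target assignment, the composite
box/class/mask objective, and a reproducible SGD loop.

The objective follows the YOLOv8-seg family: CIoU + distribution-focal
regression on assigned cells, binary cross-entropy classification over all
cells, and per-instance mask binary cross-entropy at prototype resolution,
cropped to the ground-truth box.  Assignment is a simplified task-aligned
scheme: candidate cells are those whose anchor point falls inside a ground
truth box, scored by ``cls^alpha * IoU^beta`` (alpha=0.5, beta=6), top-k
(k=10) per ground truth; a cell claimed by several ground truths goes to
the higher alignment, ties broken by IoU then lowest cell index.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .nn import autograd as A
from .nn.autograd import Tensor
from .nn.modules import SGD
from .data import ImageSample, polygon_to_mask
from .model import ModelConfig, SegmentationModel, build_model
from .postprocess import anchor_points, decode_boxes

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 16
    lr0: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    image_size: int = 640
    workers: int = 8
    mosaic_prob: float = 1.0
    mosaic_close_frac: float = 0.1   # mosaic disabled over the final fraction
    seed: int = 0
    # desk-scale overrides
    max_steps: int | None = None
    lr_final_frac: float = 0.01
    loss_weights: tuple = (7.5, 0.5, 1.0, 1.5)  # box, cls, mask, dfl
    assign_alpha: float = 0.5
    assign_beta: float = 6.0
    assign_topk: int = 10

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.image_size) <= 0 or self.lr0 <= 0:
            raise ValueError("epochs, batch_size, image_size, lr0 must be positive")

    def to_dict(self):
        d = asdict(self)
        d["loss_weights"] = list(self.loss_weights)
        return d


@dataclass
class GroundTruth:
    """Per-image targets in pixel space at the training resolution."""
    classes: np.ndarray      # (G,)
    boxes: np.ndarray        # (G, 4) pixels
    masks: np.ndarray        # (G, Hp, Wp) float {0,1} at prototype stride 4


@dataclass
class AssignmentResult:
    anchor_idx: list         # per image: (P,) flat anchor indices
    gt_idx: list             # per image: (P,) ground-truth indices
    anchors: np.ndarray      # (A, 2) pixel anchor points
    strides: np.ndarray      # (A,)
    level_of: np.ndarray     # (A,) level index


def prepare_targets(samples: list[ImageSample], image_size: int
                    ) -> tuple[np.ndarray, list[GroundTruth]]:
    """Resize images to the training resolution and rasterise targets."""
    from PIL import Image
    hp = image_size // 4
    xs, gts = [], []
    for s in samples:
        img = s.image
        if img.shape[0] != image_size or img.shape[1] != image_size:
            img = np.asarray(Image.fromarray(img).resize(
                (image_size, image_size), Image.BILINEAR))
        xs.append(img.transpose(2, 0, 1).astype(np.float32) / 255.0)
        classes, boxes, masks = [], [], []
        for a in s.instances:
            x1, y1, x2, y2 = a.box
            classes.append(a.class_id)
            boxes.append([x1 * image_size, y1 * image_size,
                          x2 * image_size, y2 * image_size])
            masks.append(polygon_to_mask(a.polygon, hp, hp).astype(np.float32))
        gts.append(GroundTruth(
            classes=np.asarray(classes, dtype=np.int64),
            boxes=np.asarray(boxes, dtype=np.float64).reshape(-1, 4),
            masks=np.asarray(masks, dtype=np.float32).reshape(-1, hp, hp)))
    return np.stack(xs), gts


def _flat_scores_boxes(head_out, image_size: int):
    """Detached per-cell class probabilities and decoded boxes, flattened
    across levels."""
    scores, boxes, anchors, strides, level_of = [], [], [], [], []
    for lvl, stride in enumerate(head_out.strides):
        cls = head_out.cls[lvl].data
        n, nc, h, w = cls.shape
        from .nn.autograd import _stable_sigmoid
        scores.append(_stable_sigmoid(cls.reshape(n, nc, h * w)))
        boxes.append(decode_boxes(head_out.reg[lvl], stride,
                                  head_out.scales[lvl], head_out.reg_max))
        anchors.append(anchor_points(h, w, stride))
        strides.append(np.full(h * w, stride))
        level_of.append(np.full(h * w, lvl))
    return (np.concatenate(scores, axis=2), np.concatenate(boxes, axis=1),
            np.concatenate(anchors), np.concatenate(strides),
            np.concatenate(level_of))


def _iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """(A, 4) x (G, 4) -> (A, G) box IoU."""
    ax1, ay1, ax2, ay2 = [boxes_a[:, i:i + 1] for i in range(4)]
    bx1, by1, bx2, by2 = [boxes_b[None, :, i] for i in range(4)]
    iw = np.clip(np.minimum(ax2, bx2) - np.maximum(ax1, bx1), 0, None)
    ih = np.clip(np.minimum(ay2, by2) - np.maximum(ay1, by1), 0, None)
    inter = iw * ih
    area_a = np.clip((ax2 - ax1) * (ay2 - ay1), 0, None)
    area_b = np.clip((bx2 - bx1) * (by2 - by1), 0, None)
    union = area_a + area_b - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def assign_targets(head_out, gts: list[GroundTruth], image_size: int,
                   alpha: float = 0.5, beta: float = 6.0, topk: int = 10
                   ) -> AssignmentResult:
    scores, boxes, anchors, strides, level_of = _flat_scores_boxes(
        head_out, image_size)
    n_img = scores.shape[0]
    anchor_idx, gt_idx = [], []
    for i in range(n_img):
        gt = gts[i]
        g = len(gt.classes)
        if g == 0:
            anchor_idx.append(np.zeros(0, dtype=np.int64))
            gt_idx.append(np.zeros(0, dtype=np.int64))
            continue
        inside = ((anchors[:, 0:1] > gt.boxes[None, :, 0])
                  & (anchors[:, 0:1] < gt.boxes[None, :, 2])
                  & (anchors[:, 1:2] > gt.boxes[None, :, 1])
                  & (anchors[:, 1:2] < gt.boxes[None, :, 3]))
        iou = _iou_matrix(boxes[i], gt.boxes)
        cls_score = scores[i, gt.classes, :].T      # (A, G)
        align = (cls_score ** alpha) * (iou ** beta)
        align = np.where(inside, align, -1.0)
        claim: dict[int, tuple] = {}
        for j in range(g):
            cand = np.nonzero(align[:, j] >= 0)[0]
            if len(cand) == 0:
                # fall back to the nearest anchor so tiny targets still train
                centre = 0.5 * (gt.boxes[j, :2] + gt.boxes[j, 2:])
                cand = np.array([np.argmin(
                    np.hypot(anchors[:, 0] - centre[0],
                             anchors[:, 1] - centre[1]))])
            order = cand[np.lexsort((cand, -iou[cand, j], -align[cand, j]))]
            for a in order[:topk]:
                key = (align[a, j], iou[a, j], -int(a))
                if a not in claim or key > claim[a][0]:
                    claim[a] = (key, j)
        if claim:
            aidx = np.array(sorted(claim), dtype=np.int64)
            gidx = np.array([claim[a][1] for a in sorted(claim)], dtype=np.int64)
        else:  # pragma: no cover
            aidx = np.zeros(0, dtype=np.int64)
            gidx = np.zeros(0, dtype=np.int64)
        anchor_idx.append(aidx)
        gt_idx.append(gidx)
    return AssignmentResult(anchor_idx, gt_idx, anchors, strides, level_of)


@dataclass
class LossBreakdown:
    box: float
    cls: float
    mask: float
    dfl: float
    total: object  # Tensor (graph root) or float

    @property
    def total_value(self) -> float:
        t = self.total
        return float(t.data) if hasattr(t, "data") else float(t)


def _ciou(pred: Tensor, gt: np.ndarray) -> Tensor:
    """Complete IoU between (P, 4) predicted boxes and constant GT boxes."""
    px1, py1 = A.narrow(pred, 1, 0, 1), A.narrow(pred, 1, 1, 1)
    px2, py2 = A.narrow(pred, 1, 2, 1), A.narrow(pred, 1, 3, 1)
    gx1, gy1, gx2, gy2 = [gt[:, i:i + 1] for i in range(4)]
    iw = A.clamp(A.add(A.minimum(px2, gx2), -A.maximum(px1, gx1)), 0.0, None)
    ih = A.clamp(A.add(A.minimum(py2, gy2), -A.maximum(py1, gy1)), 0.0, None)
    inter = A.mul(iw, ih)
    pw, ph = A.add(px2, -px1), A.add(py2, -py1)
    area_p = A.mul(pw, ph)
    area_g = (gx2 - gx1) * (gy2 - gy1)
    union = A.add(A.add(area_p, area_g), A.mul(inter, -1.0))
    iou = A.mul(inter, A.power(A.add(union, 1e-9), -1.0))
    # centre distance over enclosing-box diagonal
    cxp, cyp = A.mul(A.add(px1, px2), 0.5), A.mul(A.add(py1, py2), 0.5)
    cxg, cyg = 0.5 * (gx1 + gx2), 0.5 * (gy1 + gy2)
    rho2 = A.add(A.power(A.add(cxp, -cxg), 2.0), A.power(A.add(cyp, -cyg), 2.0))
    ew = A.add(A.maximum(px2, gx2), -A.minimum(px1, gx1))
    eh = A.add(A.maximum(py2, gy2), -A.minimum(py1, gy1))
    c2 = A.add(A.add(A.power(ew, 2.0), A.power(eh, 2.0)), 1e-9)
    # aspect-ratio consistency
    gw, gh = gx2 - gx1, gy2 - gy1
    v = A.mul(A.power(A.add(A.atan(A.mul(pw, A.power(A.add(ph, 1e-9), -1.0))),
                            -np.arctan(gw / (gh + 1e-9))), 2.0),
              4.0 / math.pi ** 2)
    alpha = Tensor(v.data / (1.0 - iou.data + v.data + 1e-9))
    return A.add(iou, A.mul(A.add(A.mul(rho2, A.power(c2, -1.0)),
                                  A.mul(v, alpha)), -1.0))


def compute_loss(head_out, assignment: AssignmentResult,
                 gts: list[GroundTruth], cfg: TrainConfig) -> LossBreakdown:
    for t in head_out.reg + head_out.cls + head_out.coef + [head_out.protos]:
        if not np.isfinite(t.data).all():
            raise FloatingPointError("non-finite values in head output")
    n_img = head_out.cls[0].shape[0]
    nc = head_out.cls[0].shape[1]
    reg_max = head_out.reg_max
    nm = head_out.coef[0].shape[1]
    w_box, w_cls, w_mask, w_dfl = cfg.loss_weights

    # flatten per-level maps to (N*A, C) rows, concatenated in level order
    def flat(maps, ch):
        rows = []
        for m in maps:
            n, c, h, w = m.shape
            rows.append(A.reshape(A.transpose(A.reshape(m, (n, c, h * w)),
                                              (0, 2, 1)), (n * h * w, c)))
        return rows

    cls_rows = flat(head_out.cls, nc)
    reg_rows = flat(head_out.reg, 4 * reg_max)
    coef_rows = flat(head_out.coef, nm)
    cells_per_level = [r.shape[0] // n_img for r in cls_rows]
    a_total = sum(cells_per_level)
    level_start = np.cumsum([0] + cells_per_level[:-1])

    def global_rows(level_local_rows):
        # rows are ordered level-major then image-major; build one tensor
        return A.concat(level_local_rows, axis=0)

    cls_all = global_rows(cls_rows)
    reg_all = global_rows(reg_rows)
    coef_all = global_rows(coef_rows)

    def row_index(img: int, flat_anchor: np.ndarray) -> np.ndarray:
        lvl = assignment.level_of[flat_anchor]
        local = flat_anchor - level_start[lvl]
        base = np.concatenate([[0], np.cumsum(
            [n_img * c for c in cells_per_level])])[:-1]
        return base[lvl] + img * np.asarray(cells_per_level)[lvl] + local

    # classification targets over every cell
    target = np.zeros((sum(n_img * c for c in cells_per_level), nc),
                      dtype=np.float32)
    pos_rows, pos_gt_img, pos_gt_idx = [], [], []
    for i in range(n_img):
        aidx, gidx = assignment.anchor_idx[i], assignment.gt_idx[i]
        if len(aidx) == 0:
            continue
        rows = row_index(i, aidx)
        target[rows, gts[i].classes[gidx]] = 1.0
        pos_rows.append(rows)
        pos_gt_img.append(np.full(len(rows), i))
        pos_gt_idx.append(gidx)
    n_pos = sum(len(r) for r in pos_rows)
    cls_loss = A.mul(A.tsum(A.bce_with_logits(cls_all, target)),
                     1.0 / max(n_pos, 1))

    if n_pos == 0:
        total = A.mul(cls_loss, w_cls)
        return LossBreakdown(0.0, cls_loss.item(), 0.0, 0.0, total)

    rows = np.concatenate(pos_rows)
    img_of = np.concatenate(pos_gt_img)
    g_of = np.concatenate(pos_gt_idx)
    aidx_all = np.concatenate([assignment.anchor_idx[i] for i in range(n_img)
                               if len(assignment.anchor_idx[i])])
    strides_pos = assignment.strides[aidx_all].astype(np.float32)
    anchors_pos = assignment.anchors[aidx_all].astype(np.float32)
    lvl_pos = assignment.level_of[aidx_all]
    gt_boxes = np.stack([gts[i].boxes[j] for i, j in zip(img_of, g_of)]
                        ).astype(np.float32)

    # --- box: decode positives differentiably, CIoU loss ---
    reg_pos = A.gather_rows(reg_all, rows)                  # (P, 4*reg_max)
    prob = A.softmax(A.reshape(reg_pos, (n_pos, 4, reg_max)), axis=2)
    bins = np.arange(reg_max, dtype=np.float32).reshape(1, 1, reg_max)
    dist_units = A.tsum(A.mul(prob, bins), axis=2)          # (P, 4) stride units
    scale_rows = A.concat(
        [A.reshape(head_out.scales[int(l)], (1, 1)) for l in lvl_pos], axis=0)
    dist_px = A.mul(A.mul(dist_units, scale_rows), strides_pos[:, None])
    ax, ay = anchors_pos[:, 0:1], anchors_pos[:, 1:2]
    boxes_pos = A.concat([
        A.add(A.mul(A.narrow(dist_px, 1, 0, 1), -1.0), ax),
        A.add(A.mul(A.narrow(dist_px, 1, 1, 1), -1.0), ay),
        A.add(A.narrow(dist_px, 1, 2, 1), ax),
        A.add(A.narrow(dist_px, 1, 3, 1), ay)], axis=1)
    ciou = _ciou(boxes_pos, gt_boxes)
    box_loss = A.tmean(A.add(1.0, A.mul(ciou, -1.0)))

    # --- distribution-focal loss on the two adjacent bins ---
    scale_det = scale_rows.data.reshape(-1, 1)
    t_units = np.stack([
        (anchors_pos[:, 0] - gt_boxes[:, 0]),
        (anchors_pos[:, 1] - gt_boxes[:, 1]),
        (gt_boxes[:, 2] - anchors_pos[:, 0]),
        (gt_boxes[:, 3] - anchors_pos[:, 1])], axis=1) / strides_pos[:, None]
    t_units = np.clip(t_units / np.maximum(scale_det, 1e-6), 0, reg_max - 1.01)
    lo = np.floor(t_units)
    wl, wr = 1.0 + lo - t_units, t_units - lo
    onehot = np.zeros((n_pos, 4, reg_max), dtype=np.float32)
    idx = np.indices(lo.shape)
    onehot[idx[0], idx[1], lo.astype(int)] = wl
    onehot[idx[0], idx[1], np.minimum(lo.astype(int) + 1, reg_max - 1)] += wr
    logp = A.log_softmax(A.reshape(reg_pos, (n_pos, 4, reg_max)), axis=2)
    dfl_loss = A.mul(A.tsum(A.mul(logp, -onehot)), 1.0 / (n_pos * 4))

    # --- mask: coefficient-assembled masks vs GT at prototype resolution ---
    protos = head_out.protos
    n, nm_, hp, wp = protos.shape
    protos_rows = A.reshape(protos, (n, nm_ * hp * wp))
    protos_pos = A.reshape(A.gather_rows(protos_rows, img_of, few_unique=True),
                           (n_pos, nm_, hp * wp))
    coef_pos = A.reshape(A.gather_rows(coef_all, rows), (n_pos, 1, nm_))
    mask_logits = A.reshape(A.matmul(coef_pos, protos_pos), (n_pos, hp * wp))
    mask_t = np.stack([gts[i].masks[j] for i, j in zip(img_of, g_of)]
                      ).reshape(n_pos, hp * wp)
    # crop: only pixels inside the GT box contribute, normalised by box area
    crop = np.zeros((n_pos, hp, wp), dtype=np.float32)
    gb = np.clip(np.round(gt_boxes / 4.0), 0, hp).astype(int)
    for p in range(n_pos):
        x1, y1, x2, y2 = gb[p]
        crop[p, y1:max(y2, y1 + 1), x1:max(x2, x1 + 1)] = 1.0
    crop = crop.reshape(n_pos, hp * wp)
    area = np.maximum(crop.sum(axis=1), 1.0)
    bce = A.mul(A.bce_with_logits(mask_logits, mask_t), crop)
    mask_loss = A.tmean(A.mul(A.tsum(bce, axis=1), 1.0 / area))

    total = A.add(A.add(A.mul(box_loss, w_box), A.mul(cls_loss, w_cls)),
                  A.add(A.mul(mask_loss, w_mask), A.mul(dfl_loss, w_dfl)))
    if not np.isfinite(total.data):
        raise FloatingPointError("non-finite training loss")
    return LossBreakdown(box_loss.item(), cls_loss.item(), mask_loss.item(),
                         dfl_loss.item(), total)


# ---------------------------------------------------------------------------
# training loop


def save_checkpoint(model: SegmentationModel, train_cfg: TrainConfig,
                    path, seed: int) -> None:
    path = Path(path)
    np.savez(path, **model.state_dict())
    meta = {"model": model.cfg.to_dict(), "train": train_cfg.to_dict(),
            "seed": seed}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def load_checkpoint(path):
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    model = build_model(ModelConfig.from_dict(meta["model"]),
                        seed=meta["seed"])
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
        model.load_state_dict(dict(z.items()))
    return model, meta


def train(model: SegmentationModel, samples: list[ImageSample],
          cfg: TrainConfig, out_dir=None, log_every: int = 10):
    """Reproducible SGD training; returns the per-step total-loss history."""
    if not samples:
        raise ValueError("dataset must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    params = list(model.parameters())
    opt = SGD(params, cfg.lr0, cfg.momentum, cfg.weight_decay)
    n = len(samples)
    steps_per_epoch = max(1, math.ceil(n / cfg.batch_size))
    total_steps = cfg.max_steps if cfg.max_steps is not None \
        else cfg.epochs * steps_per_epoch
    history = []
    model.train()
    from .data import mosaic_augment
    step = 0
    t0 = time.time()
    while step < total_steps:
        order = rng.permutation(n)
        for b0 in range(0, n, cfg.batch_size):
            if step >= total_steps:
                break
            batch = [samples[i] for i in order[b0:b0 + cfg.batch_size]]
            frac = step / max(total_steps, 1)
            use_mosaic = (cfg.mosaic_prob > 0
                          and frac < 1.0 - cfg.mosaic_close_frac
                          and rng.uniform() < cfg.mosaic_prob)
            if use_mosaic and len(samples) >= 4:
                batch = [mosaic_augment(
                    [samples[i] for i in rng.integers(0, n, 4)],
                    cfg.image_size, seed=int(rng.integers(2 ** 31)))
                    for _ in batch]
            x, gts = prepare_targets(batch, cfg.image_size)
            lr = cfg.lr0 * (1.0 - (1.0 - cfg.lr_final_frac) * frac)
            opt.lr = lr
            head_out = model(Tensor(x))
            assignment = assign_targets(head_out, gts, cfg.image_size,
                                        cfg.assign_alpha, cfg.assign_beta,
                                        cfg.assign_topk)
            loss = compute_loss(head_out, assignment, gts, cfg)
            opt.zero_grad()
            loss.total.backward()
            opt.step()
            history.append(loss.total_value)
            if log_every and step % log_every == 0:
                log.info("step %d/%d lr %.5f box %.3f cls %.3f mask %.3f "
                         "dfl %.3f total %.3f (%.1fs)", step, total_steps, lr,
                         loss.box, loss.cls, loss.mask, loss.dfl,
                         loss.total_value, time.time() - t0)
            step += 1
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, cfg, out / "checkpoint.npz", cfg.seed)
        (out / "loss_log.yaml").write_text(yaml.safe_dump(
            {"total_loss": [float(v) for v in history]}))
    return history
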