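"""Target assignment, loss terms, and the reproducible training loop."""

import numpy as np
import pytest

from smlsyolo.data import SynthConfig, generate_synthetic_samples
from smlsyolo.model import build_model, tiny_config
from smlsyolo.nn import Tensor
from smlsyolo.nn import autograd as A
from smlsyolo.training import (AssignmentResult, GroundTruth, TrainConfig,
                               assign_targets, compute_loss, load_checkpoint,
                               prepare_targets, save_checkpoint, train)


@pytest.fixture(scope="module")
def small_model():
    return build_model(tiny_config(image_size=64), seed=0)


def _gt(boxes, classes=None, size=64):
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    g = len(boxes)
    masks = np.zeros((g, size // 4, size // 4), dtype=np.float32)
    for i, (x1, y1, x2, y2) in enumerate(boxes / 4):
        masks[i, int(y1):max(int(y2), int(y1) + 1),
              int(x1):max(int(x2), int(x1) + 1)] = 1.0
    return GroundTruth(
        classes=np.asarray(classes if classes is not None else [0] * g,
                           dtype=np.int64),
        boxes=boxes, masks=masks)


class TestAssignment:
    def test_empty_ground_truth_all_background(self, small_model, rng):
        x = Tensor(rng.uniform(size=(1, 3, 64, 64)).astype(np.float32))
        out = small_model.eval()(x)
        res = assign_targets(out, [_gt(np.zeros((0, 4)))], 64)
        assert len(res.anchor_idx[0]) == 0

    def test_single_cell_box_assigned(self, small_model, rng):
        x = Tensor(rng.uniform(size=(1, 3, 64, 64)).astype(np.float32))
        out = small_model.eval()(x)
        # a box covering exactly one stride-8 cell centred at (12, 12)
        res = assign_targets(out, [_gt([[8.5, 8.5, 15.5, 15.5]])], 64)
        assert len(res.anchor_idx[0]) >= 1
        a = res.anchor_idx[0][0]
        assert res.strides[a] == 8
        assert tuple(res.anchors[a]) == (12.0, 12.0)

    def test_conflicting_cell_goes_to_higher_alignment(self, small_model, rng):
        """Two overlapping ground truths: brute-force both candidate
        alignment scores and check the winner."""
        x = Tensor(rng.uniform(size=(1, 3, 64, 64)).astype(np.float32))
        out = small_model.eval()(x)
        gt = _gt([[4, 4, 28, 28], [8, 8, 24, 24]])
        res = assign_targets(out, [gt], 64)
        from smlsyolo.training import _flat_scores_boxes, _iou_matrix
        scores, boxes, anchors, strides, _ = _flat_scores_boxes(out, 64)
        iou = _iou_matrix(boxes[0], gt.boxes)
        align = (scores[0, 0, :, None].repeat(2, 1) ** 0.5) * iou ** 6
        for a, j in zip(res.anchor_idx[0], res.gt_idx[0]):
            other = 1 - j
            inside_other = (gt.boxes[other, 0] < anchors[a, 0]
                            < gt.boxes[other, 2]
                            and gt.boxes[other, 1] < anchors[a, 1]
                            < gt.boxes[other, 3])
            if inside_other:
                assert (align[a, j], iou[a, j]) >= (align[a, other],
                                                    iou[a, other])


class TestLoss:
    def _forward(self, small_model, rng, gts):
        x = Tensor(rng.uniform(size=(1, 3, 64, 64)).astype(np.float32))
        out = small_model(x)
        res = assign_targets(out, gts, 64)
        return out, res

    def test_no_instances_box_mask_zero(self, small_model, rng):
        small_model.eval()
        out, res = self._forward(small_model, rng, [_gt(np.zeros((0, 4)))])
        loss = compute_loss(out, res, [_gt(np.zeros((0, 4)))],
                            TrainConfig(image_size=64))
        assert loss.box == 0.0 and loss.mask == 0.0 and loss.dfl == 0.0
        assert loss.cls > 0.0
        assert loss.total_value >= 0.0

    def test_finite_on_random_batches(self, small_model, rng):
        small_model.eval()
        cfg = TrainConfig(image_size=64)
        for _ in range(10):
            g = int(rng.integers(0, 4))
            raw = rng.uniform(4, 60, size=(g, 4))
            boxes = np.stack([raw[:, :2].min(1), raw[:, 2:].min(1),
                              raw[:, :2].max(1) + 4, raw[:, 2:].max(1) + 4],
                             axis=1) if g else np.zeros((0, 4))
            gts = [_gt(boxes)]
            out, res = self._forward(small_model, rng, gts)
            loss = compute_loss(out, res, gts, cfg)
            assert np.isfinite(loss.total_value)
            assert loss.total_value >= 0.0

    def test_dfl_uniform_equals_adjacent_bin_cross_entropy(self):
        """A uniform regression distribution decodes to (reg_max-1)/2 and
        its distribution-focal loss against integer target t equals the
        cross-entropy of the two adjacent bins, evaluated directly."""
        reg_max = 16
        logits = np.zeros((1, 4, reg_max), dtype=np.float32)
        logp = A.log_softmax(Tensor(logits), axis=2)
        # uniform distribution: every bin has probability 1/reg_max
        t = 6.0
        wl, wr = 1.0, 0.0  # integer target: all weight on bin floor(t)
        expected = -(wl * np.log(1 / reg_max) + wr * np.log(1 / reg_max))
        onehot = np.zeros_like(logits)
        onehot[0, :, int(t)] = wl
        loss = float((A.mul(logp, -onehot)).sum().data) / 4
        assert loss == pytest.approx(expected, rel=1e-6)
        # fractional target t=6.3 splits weight 0.7/0.3 across bins 6 and 7
        t, wl, wr = 6.3, 0.7, 0.3
        onehot = np.zeros_like(logits)
        onehot[0, :, 6] = wl
        onehot[0, :, 7] = wr
        loss = float((A.mul(logp, -onehot)).sum().data) / 4
        brute = -(wl * np.log(1 / reg_max) + wr * np.log(1 / reg_max))
        assert loss == pytest.approx(brute, rel=1e-6)

    def test_gradient_reaches_every_branch(self, rng):
        """One backward pass on a synthetic batch puts gradients on the
        backbone, the attention block, the shared head stack, every Scale,
        the prototype path and the coefficient head (no dead wiring)."""
        model = build_model(tiny_config(image_size=64), seed=0)
        model.train()
        x = Tensor(rng.uniform(size=(2, 3, 64, 64)).astype(np.float32))
        out = model(x)
        # instances sized to populate all three pyramid levels
        gts = [_gt([[4, 4, 16, 16], [8, 8, 40, 40]]),
               _gt([[2, 2, 62, 62]])]
        res = assign_targets(out, gts, 64)
        # guarantee at least one positive on every level
        for lvl in range(3):
            if not any((res.level_of[res.anchor_idx[i]] == lvl).any()
                       for i in range(2)):
                sel = np.nonzero(res.level_of == lvl)[0][0]
                res.anchor_idx[1] = np.append(res.anchor_idx[1], sel)
                res.gt_idx[1] = np.append(res.gt_idx[1], 0)
        loss = compute_loss(out, res, gts, TrainConfig(image_size=64))
        loss.total.backward()
        missing = [name for name, p in model.named_parameters()
                   if p.grad is None or not np.any(p.grad)]
        assert missing == []


class TestTrainLoop:
    def test_loss_descends_and_is_deterministic(self, tmp_path):
        samples = generate_synthetic_samples(
            SynthConfig(n_images=4, image_size=64, seed=1))
        cfg = TrainConfig(image_size=64, batch_size=4, max_steps=12,
                          mosaic_prob=0.0, seed=3)
        histories = []
        for _ in range(2):
            model = build_model(tiny_config(image_size=64), seed=0)
            histories.append(train(model, samples, cfg, log_every=0))
        assert histories[0] == histories[1]  # bit-identical trajectories
        assert np.mean(histories[0][-3:]) < histories[0][0]

    def test_checkpoint_round_trip_and_lr(self, tmp_path):
        samples = generate_synthetic_samples(
            SynthConfig(n_images=2, image_size=64, seed=2))
        model = build_model(tiny_config(image_size=64), seed=0)
        cfg = TrainConfig(image_size=64, batch_size=2, max_steps=2,
                          mosaic_prob=0.0, seed=0)
        train(model, samples, cfg, out_dir=tmp_path, log_every=0)
        restored, meta = load_checkpoint(tmp_path / "checkpoint.npz")
        assert meta["train"]["lr0"] == 0.01
        pa = dict(model.named_parameters())
        pb = dict(restored.named_parameters())
        assert all(np.array_equal(pa[k].data, pb[k].data) for k in pa)

    def test_empty_dataset_rejected(self):
        model = build_model(tiny_config(image_size=64), seed=0)
        with pytest.raises(ValueError):
            train(model, [], TrainConfig(image_size=64))

    def test_mosaic_probability_zero_passthrough(self):
        """With mosaic probability 0 the loop consumes samples unchanged
        (covered by determinism of prepare_targets on the raw samples)."""
        samples = generate_synthetic_samples(
            SynthConfig(n_images=2, image_size=64, seed=5))
        x, gts = prepare_targets(samples, 64)
        assert x.shape == (2, 3, 64, 64)
        assert all(len(g.classes) == len(s.instances)
                   for g, s in zip(gts, samples))
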