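# smlsyolo

Lightweight single-stage **instance segmentation of retinal atrophy
lesions** in pathological-myopia fundus photographs, implemented entirely
on numpy (a small built-in reverse-mode autodiff engine; no GPU, no
deep-learning framework).

Pathological myopia produces patchy retinal atrophy — including
peripapillary atrophy around the optic disc — that appears in colour
fundus photographs as bright irregular patches.  Screening at scale wants
a segmenter that is both accurate and very small.  This package
reimplements such a network and everything needed to exercise it end to
end: the model family, dataset tooling for YOLO-segmentation polygon
labels, a synthetic fundus generator (the clinical dataset is not
redistributable), desk-scale CPU training, and the standard detection /
segmentation metrics.

## The model

The lightweight variant (`smls`) modifies a YOLOv8-style segmenter in
four places:

* **Star-operation backbone** — four stages of residual blocks built
  around `act(f1(x)) ⊙ f2(x)`: the element-wise product of two learned
  linear projections, which injects pairwise feature interactions (an
  implicit high-dimensional feature space) into a narrow network.
* **C2f-Star neck** — the split-transform-concatenate fusion blocks of the
  PAN neck keep their topology but their inner bottlenecks become star
  blocks.
* **MHSA** — multi-head self-attention (`softmax(QKᵀ/√d)V` per head over
  flattened tokens, learned factorised 2-D positional encoding) applied to
  the stride-32 map right after spatial-pyramid pooling.
* **Segment_LS head** — per-level 1×1 projections feed one stack of two
  3×3 conv + GroupNorm layers whose weights are **shared across all three
  pyramid levels**; shared 1×1 convs emit box-distribution logits
  (`4·reg_max` bins, decoded by softmax expectation), class logits and
  mask coefficients; a learnable scalar **Scale** per level rescales the
  decoded distances; instance masks are YOLACT-style coefficient-weighted
  prototype combinations.

The comparison baseline (`yolov8n_seg`) is a faithful YOLOv8n-seg with
unshared per-level head branches.  With the calibrated default
configuration the profiler reproduces the published complexity figures:
1.7 M total / 0.25 M head parameters and 8.2 GFLOPs at 640×640 for the
lightweight model, against 3.26 M / 1.00 M (30.7 % of the network) for
the baseline — a 75.5 % head-parameter reduction.

Evaluation implements precision `P = TP/(TP+FP)`, recall
`R = TP/(TP+FN)`, `F1 = 2PR/(P+R)`, all-point-interpolated
`AP = ∫ P dR` at an IoU > 0.5 match criterion (box IoU or mask pixel
IoU), `mAP@0.5` as the class mean, pixel `IoU = TP/(TP+FP+FN)` and FPS.

## Worked example

Profile both variants (this is real output):

```bash
$ smlsyolo profile --variant smls
{
  "variant": "smls",
  "image_size": 640,
  "total_params": 1696780,
  "total_params_m": 1.7,
  "head_params": 245500,
  "head_params_m": 0.25,
  "head_fraction_pct": 14.5,
  "gflops": 8.2,
  "total_params_m2": 1.7
}
$ smlsyolo profile --variant yolov8n_seg
{
  "variant": "yolov8n_seg",
  "image_size": 640,
  "total_params": 3262752,
  "total_params_m": 3.3,
  "head_params": 1003216,
  "head_params_m": 1.0,
  "head_fraction_pct": 30.7,
  "gflops": 11.2,
  "total_params_m2": 3.26
}
```

Reading: the lightweight model has 1,696,780 trainable parameters (prints
as 1.7 M), of which 245,500 (0.25 M, 14.5 %) sit in the shared-conv
segmentation head, and one 640×640 forward pass costs 8.2 GFLOPs under
the 2×multiply-accumulate convention.  The baseline head alone holds
1.00 M of 3.26 M parameters (30.7 %), so the head redesign removes
75.5 % of the head.  (The baseline's GFLOP figure is discussed in
`docs/methods.md` — published numbers for that model depend on profiler
conventions.)

Generate data, train the desk-scale variant, evaluate:

```bash
smlsyolo synth --out data/synth --n 8 --imgsz 256 --seed 0
smlsyolo train data/synth --out runs/demo --tiny --imgsz 256 \
         --batch 8 --steps 450 --mosaic 0 --seed 0
smlsyolo eval data/synth --checkpoint runs/demo/checkpoint.npz --out runs/demo_eval
```

The eval report (`runs/demo_eval/metrics.json`) contains per-task
precision/recall/F1/mAP@0.5 in percent plus P-R curve images; on this
8-image training set the mask mAP@0.5 reaches 1.0 at seed 0 (the desk-scale
overfit check asserted by the test suite).  The dataset commands
reproduce the documented procedures exactly: a 9:1 split of 795 ids gives
716 / 79, and six-fold augmentation (original + histogram equalisation,
grayscale, horizontal flip, linear colour, right-angle rotation, vertical
flip) turns 716 → 5,012 and 79 → 553.

## Layout

```
src/smlsyolo/
  nn/              numpy autodiff engine + layers (conv, BN/GN, SGD)
  star_backbone.py star operation, StarBlock, StarNet, CSP baseline
  neck.py          C2f / C2f-Star, SPPF, MHSA, PAN fusion
  segment_ls_head.py  shared-conv GN head, Scale, prototypes, baseline head
  model.py         configs + assembly      model_profile.py  params/GFLOPs
  data.py          labels, split, augmentation, mosaic, synthetic fundus
  training.py      assignment, losses, SGD loop
  postprocess.py   DFL decode, NMS, mask assembly
  metrics.py       P/R/F1, AP, mAP@0.5, pixel IoU, FPS, P-R curves
  inference.py     batch predict + evaluate    cli.py  command line
configs/           frozen model configurations
docs/methods.md    model, conventions, calibration, limitations
```
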