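# Methods

This package reimplements a lightweight single-stage instance-segmentation
network for patchy retinal atrophy in pathological-myopia fundus
photographs, together with the dataset procedures and evaluation metrics
needed to exercise it end to end on CPU.  Everything runs on a small
reverse-mode autodiff engine written on numpy; no deep-learning framework
is required.

## The model

**SMLS-YOLO variant (`variant: smls`).**  A YOLOv8-style detector/segmenter
with four substitutions:

1. *Star-operation backbone.*  The backbone is a StarNet-style stack: a
   stride-2 stem then four stages of (stride-2 conv, N StarBlocks).  A
   StarBlock computes `x + dw2(BN(g(act(f1(y)) * f2(y))))` with
   `y = BN(dw1(x))`, where `f1, f2` are 1x1 expansions to `mlp_ratio * dim`
   channels, `g` projects back, `dw*` are 7x7 depthwise convs, and the
   activation is a ramp capped at 6 (ReLU6).  The element-wise product of
   two linear projections ("star operation") injects pairwise feature
   interactions — an implicit high-dimensional feature map — at the cost of
   a single extra point-wise conv.  Stage outputs 2-4 form the
   stride-8/16/32 pyramid.
2. *C2f-Star fusion.*  The neck keeps the YOLOv8 PAN layout (SPPF on the
   stride-32 map, top-down then bottom-up fusion) but every C2f block's
   inner bottlenecks are replaced by StarBlocks.  A C2f block maps to
   `out_channels` by 1x1 conv, splits into halves, chains the inner blocks
   on one half retaining every intermediate, and fuses the
   `(2 + n) * out/2` concatenated channels by a final 1x1 conv.
3. *Multi-head self-attention after the backbone.*  MHSA runs on the
   stride-32 map directly after SPPF — the cheapest placement given the
   quadratic token cost (20 x 20 tokens at 640 input).  Per head:
   `softmax(Q K^T / sqrt(d_head)) V` over flattened tokens with learned 1x1
   Q/K/V projections, concatenated heads, a learned output projection, and
   a residual connection.  The learned 2-D positional encoding is
   factorised into per-row plus per-column embeddings (their broadcast sum
   spans the grid); at other grid sizes it is linearly resampled.
4. *Shared-convolution segmentation head (Segment_LS).*  Each pyramid
   level is projected by an unshared 1x1 conv + GroupNorm to a common
   width, then one stack of two 3x3 conv + GroupNorm layers — weights
   shared across all three levels — feeds three shared 1x1 output convs:
   box-regression logits (`4 * reg_max` distribution bins), class logits,
   and mask coefficients.  GroupNorm (16 groups) makes the head exactly
   batch-size independent, which the tests assert (batch-1 forward equals
   the matching slice of a batch-8 forward).  One learnable scalar Scale
   per level, initialised to 1, multiplies the *decoded* regression
   distances so the shared weights can serve three strides.  Instance
   masks keep the YOLACT mechanism: a separate prototype path
   (conv -> 2x upsample -> conv -> 1x1) off the stride-8 map emits `nm`
   stride-4 prototype maps, and an instance's mask is
   `sigmoid(sum_k coeff_k * proto_k)` upsampled, thresholded strictly
   above 0.5, and cropped to its box.

**Baseline (`variant: yolov8n_seg`).**  The comparison model is a faithful
YOLOv8n-seg: CSP backbone (widths 16/32/64/128/256, C2f depths 1/2/2/1),
SPPF + PAN neck with plain C2f blocks, and the decoupled head with
*unshared* per-level regression/classification/mask-coefficient branches
plus the same prototype mechanism (batch-norm variant, nearest-neighbour
prototype upsample).  The regression and classification hidden widths are
tied to the level-3 channel count (64); the mask branch width is
`max(ch3/4, nm)`.  Profiling defaults to the stock 80-class configuration.
With these choices the counted parameters are 3,262,752 total and
1,003,216 in the head (30.7%) — matching the published baseline figures
digit for digit — while task training uses `nc = 1`.

## Complexity accounting

`count_params` sums trainable scalars (normalisation scale/shift included,
running statistics excluded).  `count_gflops` accumulates analytically
during a forward pass under the 2 x multiply-accumulate convention:
convolutions contribute `2 k^2 C_in C_out H_out W_out / groups`, linear
maps `2 · in · out` per position, and each attention head `2 T^2 d` for
`Q K^T` plus the same for the weighted sum.  Normalisation, activations,
pooling and resampling are not counted.  A test validates the conv formula
against an instrumented naive convolution on random single layers.

**Calibration.**  The published description fixes the block designs but not
the widths/depths, so the default configuration was selected once by a
grid search (`scripts/calibrate.py`) over the StarNet-S1-style family —
backbone dims/depths, neck channels, head width, prototype width — for the
configuration whose totals round to the published 1.7 M parameters, 0.25 M
head parameters and 8.2 GFLOPs at 640 x 640.  The frozen result (dims
24/48/96/192, depths 1/2/2/1, stem 24, neck channels 32/64/96, head width
104, prototype width 32) ships in `configs/smls.yaml`; it yields 1,696,780
total / 245,500 head parameters (14.5% head share, 75.5% smaller than the
baseline head) and 8.16 GFLOPs.  Under the same conv-only 2 x MAC
convention the baseline counts 11.2 GFLOPs; published GFLOP figures for
that model vary with profiler details (e.g. whether the prototype upsample
is a transposed convolution and how the classification hidden width scales
with class count), and we report what our counter computes rather than
tuning the counter to a printed value.

## Dataset procedures

* **Split.**  Deterministic shuffled 9:1 split; the train share is rounded
  *up* (795 -> 716/79, matching `ceil(0.9 * 795) = 716`).
* **Six-fold augmentation.**  Each image yields the original plus six
  variants: histogram equalisation, grayscale (luminance replicated to
  three channels so input shape is unchanged), horizontal flip, per-channel
  linear colour map `y = a x + b` with `a ~ U(0.8, 1.2)`,
  `b ~ U(-20, 20)` (clipped to [0, 255]), a right-angle rotation drawn from
  {90°, 180°, 270°} (keeps polygons exactly representable), and vertical
  flip — so 716 -> 5,012 and 79 -> 553.  Geometric transforms move every
  polygon vertex by the same map; photometric transforms leave polygons
  untouched.  Instances whose clipped polygon collapses to zero area are
  dropped with a warning.
* **Mosaic.**  Four images are resized into the four quadrants around a
  centre point drawn from the middle half of the canvas; polygons follow
  the same affine maps.  Mosaic runs with configurable probability during
  training and is disabled over the final 10% of the budget.
* **Coordinates.**  Normalised to [0, 1], origin top-left; a pixel belongs
  to a polygon mask iff its centre is inside (even-odd rule).  One
  rasteriser implements this everywhere.

## The synthetic generator

Real fundus data (582 annotated lesion images, 213 normal, 400 test) is
not redistributable, so a generator emulates its geometry: a dark
surround, a circular retinal field with radial falloff and reddish hue, an
off-centre bright optic-disc ellipse, a few dark vessels, and 1-3 bright
irregular atrophic patches placed near the disc (peripapillary pattern).
Lesions are perturbed ellipses — radius modulated by sinusoids of
frequency 2/3/5 with amplitudes up to 0.14 — giving irregular but exactly
polygonizable shapes.  Vertex coordinates are rounded to 6 decimals
*before* the internal raster is drawn, so re-rasterising an emitted label
file reproduces the generator's lesion mask pixel for pixel.  Identical
configs (including seed) produce byte-identical datasets.

What it does not emulate: real lesion texture and colour statistics,
annotation noise, camera vignetting and focus variation, or the
class imbalance of clinical data.  Tests that pass on synthetic data
demonstrate that the pipeline is mechanically and numerically correct, not
that the model reaches any particular accuracy on real fundus photographs.
With two classes enabled, lesions adjacent to the disc are labelled
class 1 (peripapillary) and the rest class 0.  A lesion-free fraction is
supported and defaults to 0.

## Training

Target assignment is a simplified task-aligned scheme: candidate cells are
those whose anchor point (cell centre) lies inside a ground-truth box,
scored by `cls^0.5 · IoU^6`; the top 10 per ground truth become positives;
a doubly-claimed cell goes to the higher alignment, ties broken by IoU
then lower cell index; a ground truth too small to contain any anchor
point falls back to its nearest anchor.  The loss is the YOLOv8-seg
family objective with weights box:cls:mask:dfl = 7.5:0.5:1.0:1.5 —
complete-IoU on decoded boxes, two-adjacent-bin distribution-focal loss on
the `reg_max = 16` distance bins, binary cross-entropy classification over
all cells (normalised by positive count), and per-instance mask BCE at
prototype resolution (stride 4), restricted to the ground-truth box and
normalised by its area.  Optimisation is SGD with momentum 0.937 and
weight decay 5e-4 at initial learning rate 0.01 (the published recipe),
decaying linearly to 1% of the initial value; the published budget is 300
epochs at batch 16 and 640 x 640 on GPU.

**Desk scale.**  CPU demonstrations and tests use a reduced variant
(`configs/smls_tiny.yaml`: dims 16/32/64/128, depths 1/1/1/1, neck
32/64/128, head width 32, 16 prototypes) trained for 450 steps at batch 8
on 8 synthetic 256 x 256 images — sizes chosen so the full
train -> predict -> evaluate loop stays in a few CPU-minutes.  That run
overfits its training set to mask mAP@0.5 near 1 and more than halves the
total loss; fixed-seed reruns are bit-identical because every source of
randomness flows from one numpy generator.

## Evaluation

Matching is greedy in descending score, one-to-one per class and image; a
prediction matches only if IoU is *strictly* greater than 0.5 (box IoU for
the box task, pixel IoU of binary masks for the mask task).  AP is the
exact area under the monotone (upper-envelope) precision-recall staircase
— all-point interpolation — and mAP@0.5 is the unweighted class mean.
Conventions: P = 0 when TP+FP = 0, R = 0 when TP+FN = 0, F1 = 0 when
P+R = 0; an AP with zero ground truths is reported as 0.  Reports print
percentages to one decimal and F1 additionally integer-rounded.  FPS is
`1 / mean(per-image seconds)` and is informational only (hardware
dependent).  Prediction uses confidence 0.25 / NMS IoU 0.7; evaluation
uses confidence 0.001 as is standard for mAP.

## Numerical choices and edge cases

* Mask binarisation is strictly `> 0.5`; the all-zero-coefficient case
  (`sigmoid(0) = 0.5`) is therefore background.
* Scale scalars multiply decoded distances (not raw logits): uniformly
  scaling distribution logits would leave the softmax expectation
  unchanged, so distance scaling is the only reading under which the
  scalar actually adapts the regression range per level.
* BatchNorm uses eps 1e-3 / momentum 0.03 (YOLO convention); GroupNorm
  uses 16 groups or fewer if the channel count requires.  Biases are
  disabled on convs followed by a normalisation layer, which keeps
  parameter counts reproducible.
* Regression output bias starts at 1.0 and class bias at -4.6 (prior
  probability ~1%), stabilising early training.
* Model weights draw from one PCG64 generator per build seed; two builds
  from the same config and seed are identical.
* Inputs whose side is not a multiple of 32 are rejected, never padded.
* Drop-path/stochastic depth is omitted (determinism preferred; the block
  design does not require it).

## Known limitations

* The engine is CPU/numpy; the full 640-input model trains far too slowly
  for real-data experiments — by design, the package demonstrates
  correctness at desk scale, and the published real-data accuracy tables
  are out of scope.
* The pixel-IoU aggregate at evaluation confidence 0.001 unions every
  low-confidence mask and is therefore pessimistic; use prediction
  confidence for qualitative mask quality.
* The baseline GFLOP figure depends on profiler conventions as discussed
  above.
* `fps` measures this numpy implementation, not the published GPU
  deployment, and is excluded from any comparison.
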