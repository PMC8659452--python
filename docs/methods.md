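# Methods

This note documents the models, conventions and design choices behind
`bloomdet`, in the order the pipeline uses them.

## Problem setting

The task is two-class object detection — `flower` (open citrus blossom) and
`bud` (unopened flower bud) — aimed at per-image counting, the raw statistic
behind flowering-intensity estimates.  The models are the YOLOv4 family:
one-stage anchor-based detectors whose heads predict, per grid cell and
anchor, a box offset/scale, an objectness score and per-class scores.  The
package's emphasis is on the *lightweight* variants obtained by replacing
ordinary 3×3 convolutions with depthwise-separable pairs and swapping the
backbone for MobileNetV3, and on making every step of that pipeline
verifiable by construction.

## Architecture graphs and parameter accounting

Architectures are declarative DAGs of typed layer nodes; the accountant and
the NumPy runtime consume the same graph, which is what makes the central
cross-check (analytic ledger = allocated arrays, exactly) meaningful.

Counting conventions (trainable parameters only):

- conv: `Hk·Wk·(Di/groups)·Do` weights, `+Do` if biased.  Convs followed by
  batch norm carry no bias; the only biased convs are the 1×1 head
  predictors and the squeeze-excite layers.
- batch norm: 2 per channel (scale, shift); running statistics are buffers.
- dense: `Di·Do + Do`.
- pooling / activations / upsampling / concat / residual add / channel
  slice / SE gating: 0.

These conventions reproduce the standard 80-class YOLOv4 at 64,363,101
parameters and the 80-class YOLOv4-tiny at 6,056,606 — the known reference
totals for those architectures — which validates the backbone and neck
layer inventories independently of this package's 2-class configurations.

### The four ablation configurations

The package builds five variants; four of them form the ablation whose
parameter totals the acceptance script reports.  The exact configuration of
each was recovered so that the analytic count lands on the published total
for that ablation row *exactly*, and the recovered configurations are part
of the package's contract:

1. **`yolov4`, 2 classes — 63,943,071.**  Standard CSPDarknet53 (Mish) +
   SPP (5/9/13 stride-1 max-pools) + PANet + three heads, `3·(5+2)=21`
   output channels per head predictor.  Fully pinned by the standard
   architecture; no freedom.

2. **`yolov4_dw`, 2 classes — 35,690,655.**  Every 3×3 conv in the
   SPP/PANet/head-stem fusion network becomes depthwise 3×3 + BN +
   activation followed by pointwise 1×1 + BN + activation (predictors
   untouched, backbone untouched), **and** the two 1×1 channel reducers
   feeding the top-down upsample path (512→256, 256→128) are likewise built
   as depthwise-separable blocks — the convention of common lightweight
   ports of this architecture family.  Without the reducer convention the
   total is 35,682,207, short by exactly the 8,448 parameters those two
   blocks add.  The rewrite is exposed as
   `dw_separable_transform(graph, scope, upsample_reducers=...)`.

3. **`yolov4_tiny`, 20 classes — 5,918,006.**  The published tiny row
   corresponds to the *stock* two-head CSPDarknet53-tiny model with
   20-class (Pascal VOC) heads — the configuration of the VOC-pretrained
   weights used for transfer learning — not to a 2-class depthwise rewrite.
   The identity is arithmetic: the stock 2-class tiny counts 5,876,426, and
   widening both 1×1 predictors from 21 to 75 channels adds
   `(75−21)·(513+257) = 41,580`.  A parity argument shows no three-head
   configuration can produce this (even) total, since each biased 21- or
   75-channel predictor contributes an odd count and everything else is
   even.  The spec'd 2-class depthwise tiny also exists in the package as
   `yolov4_tiny_dw` (4,051,274 parameters) and is the smoke-training model.

4. **`improved`, 2 classes — 11,309,039.**  MobileNetV3-Large backbone in
   the torchvision convention — SE blocks on the expansion channels with
   squeeze width `make_divisible(exp/4, 8)` and biased 1×1 SE layers, no
   expansion conv in the first bneck — tapped at strides 8/16/32
   (40/112/160 channels, before the final 960-channel conv), feeding the
   depthwise-separable neck of (2) but with plain 1×1 upsample reducers and
   1×1 lateral adapters.  This decomposition (backbone 2,816,432 + neck
   8,492,607) was the unique exact match in a joint search over SE
   conventions × tap choices × reducer conventions.

The per-variant reducer convention (depthwise in `yolov4_dw`/
`yolov4_tiny_dw`, plain 1×1 in `improved`) reflects that the two
lightweight reworks were evidently built at different times or from
different templates; the builder exposes it as a flag rather than hiding
it.

### FLOPs

Multiply-adds use `Ho·Wo·(Di/g)·Do·Hk·Wk` with output spatial dimensions
propagated symbolically through strides.  For the depthwise pair the cost
is `Ho·Wo·Di·9 + Ho·Wo·Di·Do`, whose ratio to the ordinary conv tends to
`1/Do + 1/(Hk·Wk)` — the standard closed form for the depthwise-separable
saving (at 3×3, about 1/9 for wide layers).

## Anchor clustering

Lloyd k-means on (w, h) pairs under `d = 1 − IoU` with corner-aligned IoU,
k-means++ seeding under the same distance, per-dimension **median** centroid
update (the robust choice common in anchor tools; mean is a config switch),
ties to the lowest anchor index, empty clusters re-seeded from the farthest
box.  Boxes are rescaled to network-input coordinates (608×608 by default)
before clustering, so anchors are stated at input scale.  `avg_iou_curve`
takes the best of `restarts` runs per k (default 10), which makes the curve
nondecreasing in k up to restart noise.  The elbow rule maximizes the
discrete slope *decrease* `s_{k-1} − s_k`: on a concave quality curve "the
largest slope" alone would always pick the smallest k, whereas the knee is
where adding one more anchor stops paying.  Ties resolve to the smaller k
(simpler model).  The shipped default anchor set for 608-px input is
23×22, 42×39, 64×62, 104×84, 165×141 (k = 5).

## Augmentation

- **Cutout**: one axis-aligned square, default side 100 px, filled with 0
  on all channels, center uniform over the image and clipped at borders
  (the original formulation).  Ground-truth boxes are never altered or
  dropped — the augmentation's purpose is precisely to teach the detector
  that occluded flowers are still flowers.
- **Mosaic**: a random split point in [0.3, 0.7]² partitions the canvas
  into four regions; each input is color-jittered (purely multiplicative
  channel gains, so black stays black), nearest-resized into its region,
  and its boxes are scaled, clipped to the region and dropped below 20% of
  their scaled area (a threshold this package fixes; no standard value
  exists).
- **Plans**: ordered op lists over {flip, mirror, crop, translate, rotate,
  brightness, noise, cutout}.  "Random flipping" in this literature can
  mean axis flips or arbitrary rotation; both are provided as separate ops
  (rotate is right-angle, which keeps boxes axis-aligned and exact) and
  plans choose.  Geometric ops map box corners through the same point
  transform as the pixels; photometric ops never touch boxes.
- **Balancing**: images containing the minority class receive
  `expansion_factor` times the augmented copies of other images, with
  provenance-tagged ids.

## Synthetic scenes

The generator emulates the features of orchard imagery that matter to this
pipeline: bright multi-lobed flower blobs (five-petal rosettes with a
yellow center) vs. small compact pale buds on green clutter; variable
density; partial occlusion by leaf-colored ellipses (up to ~50% of a blob,
drawn *after* annotation so boxes keep the full extent); multiplicative
luminosity.  Boxes are tight by construction (computed from the rendered
mask).  Density presets — sparse ≤ 10, medium 11–30, dense > 30 boxes per
image — are this package's quantitative convention for the few/middle/
intensive evaluation strata, which are usually described only
qualitatively.  The `EASY_SCENE` preset (160×160, two flowers and two buds
per image, 40–56 px flowers, 26–36 px buds, well separated on a plain
background) defines the regime for smoke-scale training: large enough
objects for a tiny model to learn from ~40 images in a few hundred
iterations.

What the generator does *not* emulate: real petal texture and specularity,
perspective, motion blur, realistic class imbalance, or inter-tree
variation.
Passing tests on synthetic scenes therefore demonstrate the correctness and
trainability of the pipeline, not field accuracy.

## Runtime and training

The runtime executes graphs in NumPy (NCHW, float32): im2col + BLAS matmul
convolutions, windowed depthwise convs, train-mode batch norm, the full
activation set (leaky ReLU 0.1, Mish, h-swish, h-sigmoid, ReLU/ReLU6), 2×2
max-pool, stride-1 SPP pools, nearest upsampling, channel slice/concat,
residual add, SE gating.  Backward passes are hand-derived and checked
against float64 central differences per op.

Training (smoke scale) follows the YOLOv4 loss structure:

- **Assignment**: each ground-truth box is matched to its best
  width-height-IoU anchor, plus any anchor with IoU > 0.3 (multi-anchor
  matching), at the grid cell containing the box center on the anchor's
  scale.  Unassigned anchors with IoU > 0.5 to some box are excluded from
  the objectness penalty (ignore region).
- **Loss**: `λ_box (1 − CIoU)` on positives (λ_box = 3), BCE objectness
  with weight 1 on positives and 0.5 on negatives, BCE class scores on
  positives.  CIoU gradients w.r.t. the decoded box come from central
  finite differences (exact to O(h²), h = 0.01 px; positives are few) and
  chain analytically through the sigmoid/exp decode.
- **Optimizer**: Adam (0.9/0.999) under the cosine-annealed schedule
  `lr(t) = lr₀·(1 + cos(πt/T))/2`.  Predictor objectness biases start at
  −4 so the overwhelmingly negative cells are cheap from the first step.
- **Full-scale defaults** in `TrainConfig` (608 px, batch 32, 75k
  iterations, lr 1e-3, Mosaic on) state the reference protocol; smoke runs
  use 160 px, batch 4, ≤300 iterations, Mosaic off — sizes chosen so a
  single-CPU run finishes in minutes while still reaching mAP@0.5 ≈ 0.9 on
  held-out easy scenes.

Transfer learning is available as a weight-file hook
(`TrainConfig.pretrained_weights`); no pretrained weights ship with the
package.

## Evaluation

VOC protocol: detections ranked by confidence; greedy match to the
highest-IoU unmatched same-class ground truth at IoU ≥ 0.5 (the `mAP@0.5`
operating point); AP integrates the monotone all-point precision envelope
(the 11-point VOC-2007 variant is a switch); mAP is the plain mean over
classes; F1 uses the final P/R point of the ranked list.  Precision at zero
recall is reported as 1 by convention (display only — AP is unaffected on
nonempty match sets).  Density stratification partitions by ground-truth
box count with the thresholds above; because matching is per-image,
stratum TP/FP/FN tallies pool exactly to the whole-set tallies.

The flower share `n_flower/(n_flower+n_bud)` reported by the counter is a
convention of this package (a proxy for flowering rate); it is labeled as
such in output and undefined when nothing is detected.

## Numerical and degenerate-input choices

- Split rounding: floor each bucket, remainders to train then val.
- k > n boxes, non-positive box dimensions, malformed annotation files,
  ≠ 4 mosaic inputs, unknown variants → explicit errors; empty id lists
  and empty scenes are valid and produce empty outputs.
- Box containers are half-open `[x_min, x_max)`, origin top-left; VOC XML
  1-based inclusive coordinates are converted on read/write, making VOC and
  YOLO round-trips exact to 0.5 px.
- All randomness flows from explicit integer seeds (NumPy `default_rng`);
  scene and dataset generation are bit-deterministic across runs.

## Known limitations

- The runtime is single-threaded NumPy: fine for the smoke scale and for
  parameter/shape oracles, not for full-scale training (75k iterations at
  608 px are out of reach by design).
- Backward passes for the stride-1 SPP pools are not implemented (the SPP
  variants are not smoke-trained); training covers the tiny depthwise
  variant end to end.
- Mosaic jitter approximates color-gamut shifts with channel gains rather
  than a true HSV rotation.
- mAP/F1 on the synthetic scenes say nothing quantitative about accuracy
  on real orchard photographs.
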