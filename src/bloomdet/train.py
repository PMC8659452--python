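"""Smoke-scale detector training on the NumPy runtime.

The loss follows the YOLOv4 reference formulation: a CIoU term on matched
boxes, binary cross-entropy on objectness (with an ignore region for
unmatched predictions that still overlap ground truth well), and binary
cross-entropy on class scores.  Each ground-truth box is assigned to the
anchor (over all scales) with the best width-height IoU, at the grid cell
containing the box center.

CIoU derivatives with respect to the decoded box are obtained by central
finite differences (4 coordinates per matched box, exact to O(h^2)) and
chained analytically through the sigmoid/exponential decode — matched boxes
are few, so this costs nothing compared to the convolutions.

Optimization is Adam with the cosine-annealed learning-rate schedule from
:class:`~bloomdet.detector.TrainConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .anchors import AnchorSet, iou_wh
from .architecture.graph import ArchitectureGraph
from .boxes import LabeledImage
from .detector import TrainConfig, split_anchors
from .runtime import RuntimeModel, build_runtime_model


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def ciou(box_a, box_b) -> float:
    """Complete IoU between (cx, cy, w, h) boxes."""
    ax0, ay0 = box_a[0] - box_a[2] / 2, box_a[1] - box_a[3] / 2
    ax1, ay1 = box_a[0] + box_a[2] / 2, box_a[1] + box_a[3] / 2
    bx0, by0 = box_b[0] - box_b[2] / 2, box_b[1] - box_b[3] / 2
    bx1, by1 = box_b[0] + box_b[2] / 2, box_b[1] + box_b[3] / 2
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = box_a[2] * box_a[3] + box_b[2] * box_b[3] - inter
    iou = inter / union if union > 0 else 0.0
    # center distance over enclosing diagonal
    cw = max(ax1, bx1) - min(ax0, bx0)
    ch = max(ay1, by1) - min(ay0, by0)
    c2 = cw * cw + ch * ch + 1e-9
    rho2 = (box_a[0] - box_b[0]) ** 2 + (box_a[1] - box_b[1]) ** 2
    v = (4 / np.pi**2) * (np.arctan(box_b[2] / box_b[3]) - np.arctan(box_a[2] / box_a[3])) ** 2
    alpha = v / (1 - iou + v + 1e-9)
    return iou - rho2 / c2 - alpha * v


def _ciou_grad(pred, gt, h=1e-2):
    """Central-difference gradient of CIoU w.r.t. the predicted box."""
    g = np.zeros(4)
    for i in range(4):
        p_hi = pred.copy()
        p_lo = pred.copy()
        p_hi[i] += h
        p_lo[i] -= h
        if i >= 2:  # keep sizes positive
            p_lo[i] = max(p_lo[i], 1e-3)
        g[i] = (ciou(p_hi, gt) - ciou(p_lo, gt)) / (p_hi[i] - p_lo[i])
    return g


@dataclass
class TrainResult:
    model: RuntimeModel
    loss_history: list[float]
    lr_history: list[float]
    anchors_per_scale: list[list[tuple[float, float]]]

    def smoothed_loss(self, window: int = 10) -> list[float]:
        out = []
        for i in range(len(self.loss_history)):
            lo = max(0, i - window + 1)
            out.append(float(np.mean(self.loss_history[lo : i + 1])))
        return out


class _Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: {n: np.zeros_like(a) for n, a in p.items()} for k, p in params.items()}
        self.v = {k: {n: np.zeros_like(a) for n, a in p.items()} for k, p in params.items()}
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for k, pg in grads.items():
            for n, g in pg.items():
                g = g.astype(np.float32)
                m = self.m[k][n]
                v = self.v[k][n]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                params[k][n] -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def _prepare_batch(images: Sequence[LabeledImage], size: int) -> np.ndarray:
    """Resize (nearest) and normalize to an NCHW float32 batch."""
    batch = np.empty((len(images), 3, size, size), dtype=np.float32)
    for i, img in enumerate(images):
        px = img.pixels
        ys = (np.arange(size) * img.height / size).astype(int).clip(0, img.height - 1)
        xs = (np.arange(size) * img.width / size).astype(int).clip(0, img.width - 1)
        resized = px[np.ix_(ys, xs)].astype(np.float32) / 255.0
        batch[i] = resized.transpose(2, 0, 1)
    return batch


def _scale_boxes(img: LabeledImage, size: int):
    fx, fy = size / img.width, size / img.height
    return [
        ((b.x_min + b.x_max) / 2 * fx, (b.y_min + b.y_max) / 2 * fy,
         b.width * fx, b.height * fy, b.class_name)
        for b in img.boxes
    ]


def yolo_loss_and_grads(
    head_outputs: list[np.ndarray],
    batch_images: Sequence[LabeledImage],
    anchors_per_scale: list[list[tuple[float, float]]],
    input_size: int,
    class_names: Sequence[str],
    lambda_box: float = 3.0,
    lambda_obj: float = 1.0,
    lambda_noobj: float = 0.5,
    lambda_cls: float = 1.0,
    ignore_iou: float = 0.5,
):
    """Loss value and per-head gradients for one batch.

    Head tensors are (N, S, S, A*(5+C)).  Returns (loss, [grad per head]).
    """
    n_cls = len(class_names)
    n_img = len(batch_images)
    flat_anchors = [a for scale in anchors_per_scale for a in scale]
    scale_of = []
    for si, scale in enumerate(anchors_per_scale):
        scale_of += [(si, ai) for ai in range(len(scale))]

    grads = [np.zeros_like(h) for h in head_outputs]
    views = [
        h.reshape(h.shape[0], h.shape[1], h.shape[2], len(anchors_per_scale[i]), 5 + n_cls)
        for i, h in enumerate(head_outputs)
    ]
    gviews = [
        g.reshape(v.shape) for g, v in zip(grads, views)
    ]

    total_loss = 0.0
    n_pos = 0
    # objectness targets: start all-negative, mark positives/ignores per image
    obj_target = [np.zeros(v.shape[:4], dtype=np.float32) for v in views]
    obj_mask = [np.ones(v.shape[:4], dtype=np.float32) for v in views]

    pos_entries = []  # (scale, img, y, x, anchor, gt_box(cx,cy,w,h), class_idx)
    match_iou = 0.3  # anchors above this also become positives (multi-anchor match)
    for bi, img in enumerate(batch_images):
        for (cx, cy, w, h, cls) in _scale_boxes(img, input_size):
            ious = [iou_wh((w, h), a) for a in flat_anchors]
            best = int(np.argmax(ious))
            ci = class_names.index(cls)
            for j, ij in enumerate(ious):
                si, ai = scale_of[j]
                s = views[si].shape[1]
                stride = input_size / s
                gx = min(int(cx / stride), s - 1)
                gy = min(int(cy / stride), s - 1)
                if j == best or ij > match_iou:
                    if obj_target[si][bi, gy, gx, ai] == 0.0:
                        pos_entries.append((si, bi, gy, gx, ai, (cx, cy, w, h), ci))
                        obj_target[si][bi, gy, gx, ai] = 1.0
                        obj_mask[si][bi, gy, gx, ai] = 1.0
                elif ij > ignore_iou and obj_target[si][bi, gy, gx, ai] == 0.0:
                    # prior overlaps well but is not assigned: no objectness penalty
                    obj_mask[si][bi, gy, gx, ai] = 0.0

    # objectness BCE over all cells
    for si, v in enumerate(views):
        logits = v[..., 4]
        p = _sigmoid(logits)
        t = obj_target[si]
        m = obj_mask[si]
        w = np.where(t > 0, lambda_obj, lambda_noobj) * m
        eps = 1e-9
        total_loss += float(np.sum(w * -(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps))))
        gviews[si][..., 4] += w * (p - t)

    # box + class terms on positives
    for (si, bi, gy, gx, ai, gt, ci) in pos_entries:
        n_pos += 1
        v = views[si][bi, gy, gx, ai]
        gv = gviews[si][bi, gy, gx, ai]
        s = views[si].shape[1]
        stride = input_size / s
        aw, ah = anchors_per_scale[si][ai]
        sx, sy = _sigmoid(v[0]), _sigmoid(v[1])
        bw = aw * np.exp(np.clip(v[2], -20, 20))
        bh = ah * np.exp(np.clip(v[3], -20, 20))
        pred = np.array([(gx + sx) * stride, (gy + sy) * stride, bw, bh])
        gt_arr = np.array(gt)
        c = ciou(pred, gt_arr)
        total_loss += lambda_box * (1.0 - float(c))
        dci = -_ciou_grad(pred, gt_arr) * lambda_box  # d(1-ciou)/dpred
        gv[0] += dci[0] * stride * sx * (1 - sx)
        gv[1] += dci[1] * stride * sy * (1 - sy)
        gv[2] += dci[2] * bw
        gv[3] += dci[3] * bh
        # class BCE
        cl = _sigmoid(v[5:])
        t = np.zeros(n_cls)
        t[ci] = 1.0
        eps = 1e-9
        total_loss += lambda_cls * float(
            np.sum(-(t * np.log(cl + eps) + (1 - t) * np.log(1 - cl + eps)))
        )
        gv[5:] += lambda_cls * (cl - t)

    norm = max(n_img, 1)
    return total_loss / norm, [g / norm for g in grads]


def train(
    graph: ArchitectureGraph,
    images: Sequence[LabeledImage],
    config: TrainConfig,
    anchors: Optional[AnchorSet] = None,
    class_names: Sequence[str] = ("flower", "bud"),
    seed: Optional[int] = None,
) -> TrainResult:
    """Train a runtime model built from ``graph`` on labeled images.

    ``anchors`` defaults to a k-means fit on the training boxes themselves
    (2 heads -> 6 anchors, 3 heads -> 9, three per head).  Deterministic for
    a fixed config seed.
    """
    from .anchors import kmeans_anchors

    if not images:
        raise ValueError("no training images")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_heads = len(graph.head_names)
    if anchors is None:
        wh = [
            (b.width * config.input_size / img.width,
             b.height * config.input_size / img.height)
            for img in images for b in img.boxes
        ]
        k = graph.anchors_per_head * n_heads
        anchors = kmeans_anchors(wh, k=min(k, len(wh)), seed=seed)
    anchor_groups = split_anchors(anchors, n_heads)

    model = build_runtime_model(graph, seed=seed)
    if config.pretrained_weights:
        import pickle

        with open(config.pretrained_weights, "rb") as fh:
            model.load_state_dict(pickle.load(fh))
    opt = _Adam(model.params)

    loss_history: list[float] = []
    lr_history: list[float] = []
    idx = np.arange(len(images))
    for it in range(config.iterations):
        lr = config.lr_at(it)
        take = rng.choice(idx, size=min(config.batch_size, len(images)), replace=False)
        batch_imgs = [images[i] for i in take]
        x = _prepare_batch(batch_imgs, config.input_size)
        heads = model.forward(x, train=True)
        loss, head_grads = yolo_loss_and_grads(
            heads, batch_imgs, anchor_groups, config.input_size, class_names
        )
        pgrads = model.backward(head_grads)
        opt.step(model.params, pgrads, lr)
        loss_history.append(float(loss))
        lr_history.append(float(lr))
    return TrainResult(
        model=model,
        loss_history=loss_history,
        lr_history=lr_history,
        anchors_per_scale=anchor_groups,
    )


def detect(
    model: RuntimeModel,
    images: Sequence[LabeledImage],
    anchors_per_scale: list[list[tuple[float, float]]],
    input_size: int,
    conf_threshold: float = 0.5,
    nms_iou: float = 0.45,
    class_names: Sequence[str] = ("flower", "bud"),
):
    """Run inference and return post-NMS detections in original image coords."""
    from .boxes import BoundingBox, Detection
    from .detector import decode_predictions, nms

    all_dets = []
    for img in images:
        x = _prepare_batch([img], input_size)
        heads = model.predict(x)
        dets = decode_predictions(
            [h[0] for h in heads], anchors_per_scale, input_size,
            conf_threshold=conf_threshold, class_names=class_names,
            image_id=img.image_id,
        )
        fx, fy = img.width / input_size, img.height / input_size
        rescaled = []
        for d in dets:
            b = d.box
            nb = BoundingBox(b.x_min * fx, b.y_min * fy, b.x_max * fx, b.y_max * fy,
                             b.class_name, b.confidence)
            rescaled.append(Detection(box=nb, image_id=d.image_id))
        all_dets.extend(nms(rescaled, iou_threshold=nms_iou))
    return all_dets
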