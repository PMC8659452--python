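"""Prediction decoding, non-maximum suppression, and flower/bud counting.

A YOLO head tensor of shape (S, S, A*(5+C)) encodes, per grid cell and
anchor: tx, ty (sigmoid -> center offset within the cell), tw, th
(exponential anchor scaling), an objectness logit and C class logits.  The
decoded confidence is sigmoid(objectness) * sigmoid(class score).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .anchors import AnchorSet
from .boxes import BoundingBox, Detection, DEFAULT_CLASSES


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol configuration.

    Defaults mirror the full-scale protocol (608px input, batches of 32,
    75,000 iterations, initial learning rate 1e-3 with cosine annealing,
    Mosaic enabled); smoke-scale runs override them.
    """

    input_size: int = 608
    batch_size: int = 32
    iterations: int = 75_000
    initial_lr: float = 1e-3
    lr_schedule: str = "cosine_annealing"
    mosaic: bool = True
    seed: int = 0
    pretrained_weights: Optional[str] = None

    def __post_init__(self):
        if min(self.input_size, self.batch_size, self.iterations) <= 0:
            raise ValueError("input_size, batch_size and iterations must be positive")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.lr_schedule != "cosine_annealing":
            raise ValueError(f"unrecognized lr schedule {self.lr_schedule!r}")

    def lr_at(self, iteration: int) -> float:
        """Cosine-annealed learning rate, from initial_lr down to ~0."""
        t = min(max(iteration, 0), self.iterations) / self.iterations
        return self.initial_lr * 0.5 * (1.0 + float(np.cos(np.pi * t)))


@dataclass
class CountReport:
    """Per-image flower/bud counts.

    ``flower_share`` = n_flower / (n_flower + n_bud) is this package's
    operationalization of a flowering-rate statistic; it is a convention of
    the artifact, reported as None when no objects are detected.
    """

    n_flower: int
    n_bud: int

    @property
    def flower_share(self) -> Optional[float]:
        total = self.n_flower + self.n_bud
        return self.n_flower / total if total else None


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def split_anchors(anchors: AnchorSet, n_heads: int) -> list[list[tuple[float, float]]]:
    """Distribute anchors over heads, smallest anchors to the finest scale.

    The anchor list (ascending area) is divided into ``n_heads`` contiguous
    groups; earlier heads (larger feature maps, finer stride) receive the
    smaller anchors.  Remainders go to the coarsest head.
    """
    per = len(anchors.anchors) // n_heads
    if per == 0:
        raise ValueError(f"{len(anchors.anchors)} anchors cannot cover {n_heads} heads")
    groups = [list(anchors.anchors[i * per:(i + 1) * per]) for i in range(n_heads)]
    groups[-1].extend(anchors.anchors[n_heads * per:])
    return groups


def decode_predictions(
    head_outputs: Sequence[np.ndarray],
    anchors_per_scale: Sequence[Sequence[tuple[float, float]]],
    input_size: int,
    conf_threshold: float = 0.5,
    class_names: Sequence[str] = DEFAULT_CLASSES,
    image_id: str = "",
) -> list[Detection]:
    """Decode raw head tensors into thresholded detections.

    ``head_outputs[i]`` has shape (S_i, S_i, A_i*(5+C)) with logits;
    ``anchors_per_scale[i]`` lists that head's A_i anchors in input-image
    pixels.  Box centers are ``(cell + sigmoid(t)) * stride``; sizes are
    ``anchor * exp(t)``; confidence is objectness times class probability.
    """
    if len(head_outputs) != len(anchors_per_scale):
        raise ValueError(
            f"{len(head_outputs)} heads but {len(anchors_per_scale)} anchor groups"
        )
    n_classes = len(class_names)
    dets: list[Detection] = []
    for out, head_anchors in zip(head_outputs, anchors_per_scale):
        s = out.shape[0]
        a = len(head_anchors)
        if out.shape != (s, s, a * (5 + n_classes)):
            raise ValueError(
                f"head shape {out.shape} incompatible with {a} anchors, "
                f"{n_classes} classes"
            )
        stride = input_size / s
        grid = out.reshape(s, s, a, 5 + n_classes)
        obj = _sigmoid(grid[..., 4])
        cls_prob = _sigmoid(grid[..., 5:])
        conf_all = obj[..., None] * cls_prob  # (s, s, a, C)
        ys, xs, aa, cc = np.nonzero(conf_all >= conf_threshold)
        for y, x, ai, ci in zip(ys, xs, aa, cc):
            tx, ty, tw, th = grid[y, x, ai, :4]
            cx = (x + float(_sigmoid(np.array(tx)))) * stride
            cy = (y + float(_sigmoid(np.array(ty)))) * stride
            aw, ah = head_anchors[ai]
            bw = aw * float(np.exp(np.clip(tw, -20, 20)))
            bh = ah * float(np.exp(np.clip(th, -20, 20)))
            box = BoundingBox(
                x_min=cx - bw / 2, y_min=cy - bh / 2,
                x_max=cx + bw / 2, y_max=cy + bh / 2,
                class_name=class_names[ci],
                confidence=min(1.0, float(conf_all[y, x, ai, ci])),
            )
            clipped = box.clipped(input_size, input_size)
            if clipped is not None:
                dets.append(Detection(box=clipped, image_id=image_id))
    return dets


def nms(detections: Sequence[Detection], iou_threshold: float = 0.45) -> list[Detection]:
    """Per-class greedy non-maximum suppression.

    Within each (image, class) group, keep the highest-confidence detection
    and suppress any remaining detection overlapping it with corner IoU
    above the threshold.  Output order is confidence-descending with box
    coordinates as a deterministic tie-break.
    """
    groups: dict[tuple[str, str], list[Detection]] = {}
    for d in detections:
        groups.setdefault((d.image_id, d.class_name), []).append(d)
    survivors: list[Detection] = []
    for group in groups.values():
        ranked = sorted(
            group,
            key=lambda d: (-d.confidence, d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max),
        )
        kept: list[Detection] = []
        for d in ranked:
            if all(d.box.iou(k.box) <= iou_threshold for k in kept):
                kept.append(d)
        survivors.extend(kept)
    survivors.sort(
        key=lambda d: (-d.confidence, d.image_id, d.box.x_min, d.box.y_min,
                       d.box.x_max, d.box.y_max)
    )
    return survivors


def count_flowers(detections: Sequence[Detection]) -> dict[str, CountReport]:
    """Per-image flower/bud counts from (post-NMS) detections."""
    out: dict[str, CountReport] = {}
    per_image: dict[str, dict[str, int]] = {}
    for d in detections:
        per_image.setdefault(d.image_id, {"flower": 0, "bud": 0})
        if d.class_name in per_image[d.image_id]:
            per_image[d.image_id][d.class_name] += 1
    for img_id, counts in sorted(per_image.items()):
        out[img_id] = CountReport(n_flower=counts["flower"], n_bud=counts["bud"])
    return out
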