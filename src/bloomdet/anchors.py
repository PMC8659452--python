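"""Anchor-box k-means under IoU distance, Avg-IoU curves and elbow selection.

Anchor priors are chosen by clustering the width-height pairs of ground-truth
boxes with Lloyd's algorithm under the distance d = 1 - IoU(box, anchor),
where IoU is computed between corner-aligned rectangles (position ignored).
The quality score is Avg IoU: the mean over boxes of the best IoU to any
anchor.  k is selected at the elbow of the Avg-IoU-vs-k curve, the point
where the discrete slope drops most sharply.

The default anchor set shipped with the package is the five-anchor
configuration for 608x608 input obtained on the citrus flower/bud task:
23x22, 42x39, 64x62, 104x84, 165x141.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: five-anchor set at 608x608 input for the citrus flower/bud task
DEFAULT_ANCHORS_608 = ((23, 22), (42, 39), (64, 62), (104, 84), (165, 141))


@dataclass(frozen=True)
class AnchorSet:
    """k width-height anchor priors at a stated input resolution."""

    anchors: tuple[tuple[float, float], ...]
    avg_iou: float
    input_size: int

    def __post_init__(self):
        areas = [w * h for w, h in self.anchors]
        if any(a2 < a1 for a1, a2 in zip(areas, areas[1:])):
            raise ValueError("anchors must be sorted ascending by area")
        if not (0.0 <= self.avg_iou <= 1.0):
            raise ValueError("avg_iou outside [0,1]")

    @property
    def k(self) -> int:
        return len(self.anchors)

    def darknet_string(self) -> str:
        """Comma-separated ``w,h`` pairs, nearest-integer, darknet style."""
        return ", ".join(f"{int(round(w))},{int(round(h))}" for w, h in self.anchors)


@dataclass(frozen=True)
class AvgIouCurve:
    """Avg IoU as a function of k over a contiguous k range."""

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self):
        ks = [k for k, _ in self.entries]
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("k values must be strictly increasing")

    @property
    def ks(self) -> list[int]:
        return [k for k, _ in self.entries]

    @property
    def avg_ious(self) -> list[float]:
        return [v for _, v in self.entries]


def iou_wh(a: tuple[float, float], b: tuple[float, float]) -> float:
    """IoU of two corner-aligned rectangles given as (w, h) pairs."""
    if min(a) <= 0 or min(b) <= 0:
        raise ValueError("box dimensions must be positive")
    inter = min(a[0], b[0]) * min(a[1], b[1])
    return inter / (a[0] * a[1] + b[0] * b[1] - inter)


def _iou_matrix(boxes: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """(n, k) IoU between every box and every anchor (corner-aligned)."""
    iw = np.minimum(boxes[:, None, 0], anchors[None, :, 0])
    ih = np.minimum(boxes[:, None, 1], anchors[None, :, 1])
    inter = iw * ih
    union = (boxes[:, 0] * boxes[:, 1])[:, None] + (anchors[:, 0] * anchors[:, 1])[None, :] - inter
    return inter / union


def _avg_iou(boxes: np.ndarray, anchors: np.ndarray) -> float:
    return float(_iou_matrix(boxes, anchors).max(axis=1).mean())


def _kmeans_pp_init(boxes: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under d = 1 - IoU."""
    n = len(boxes)
    centers = [boxes[rng.integers(n)]]
    while len(centers) < k:
        d = 1.0 - _iou_matrix(boxes, np.array(centers)).max(axis=1)
        total = d.sum()
        if total <= 0:  # all boxes coincide with a center
            centers.append(boxes[rng.integers(n)])
            continue
        centers.append(boxes[rng.choice(n, p=d / total)])
    return np.array(centers, dtype=float)


def kmeans_anchors(
    boxes: Sequence[tuple[float, float]],
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    centroid: str = "median",
) -> AnchorSet:
    """Lloyd k-means on (w, h) pairs with IoU distance.

    Assignment ties break toward the lowest anchor index; centroids update as
    the per-dimension median (or mean) of their cluster; an emptied cluster is
    re-seeded from the box farthest from every centroid.
    """
    arr = np.asarray(boxes, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("boxes must be (n, 2) width-height pairs")
    if np.any(arr <= 0):
        raise ValueError("box dimensions must be positive")
    n = len(arr)
    if k > n:
        raise ValueError(f"k={k} exceeds population size {n}")
    if centroid not in ("median", "mean"):
        raise ValueError("centroid must be 'median' or 'mean'")
    reduce_fn = np.median if centroid == "median" else np.mean

    rng = np.random.default_rng(seed)
    centers = _kmeans_pp_init(arr, k, rng)
    prev_obj = -np.inf
    for _ in range(max_iter):
        iou = _iou_matrix(arr, centers)
        assign = iou.argmax(axis=1)  # argmax takes the lowest index on ties
        for j in range(k):
            members = arr[assign == j]
            if len(members) == 0:
                farthest = (1.0 - iou.max(axis=1)).argmax()
                centers[j] = arr[farthest]
            else:
                centers[j] = reduce_fn(members, axis=0)
        obj = _avg_iou(arr, centers)
        if obj - prev_obj < tol:
            break
        prev_obj = obj

    order = np.argsort(centers[:, 0] * centers[:, 1], kind="stable")
    centers = centers[order]
    return AnchorSet(
        anchors=tuple((float(w), float(h)) for w, h in centers),
        avg_iou=_avg_iou(arr, centers),
        input_size=0,
    )


def avg_iou_curve(
    boxes: Sequence[tuple[float, float]],
    k_min: int = 2,
    k_max: int = 10,
    restarts: int = 10,
    seed: int = 0,
) -> AvgIouCurve:
    """Best-of-restarts Avg IoU for each k in [k_min, k_max]."""
    if not (1 <= k_min <= k_max):
        raise ValueError("need k_max >= k_min >= 1")
    entries = []
    for k in range(k_min, k_max + 1):
        best = -1.0
        for r in range(restarts):
            result = kmeans_anchors(boxes, k, seed=seed * 1000 + k * 37 + r)
            best = max(best, result.avg_iou)
        entries.append((k, best))
    return AvgIouCurve(entries=tuple(entries))


def select_k_elbow(curve: AvgIouCurve) -> int:
    """k at the sharpest slope decrease of the Avg-IoU curve.

    On a concave quality curve the forward slope s_k = q(k+1) - q(k) shrinks
    with k; the elbow is the k maximizing s_{k-1} - s_k, i.e. where adding one
    more anchor stops paying.  Ties resolve to the smaller k.
    """
    if len(curve.entries) < 3:
        raise ValueError("elbow selection needs at least 3 curve points")
    ks = curve.ks
    qs = curve.avg_ious
    slopes = [(qs[i + 1] - qs[i]) / (ks[i + 1] - ks[i]) for i in range(len(ks) - 1)]
    drops = [slopes[i] - slopes[i + 1] for i in range(len(slopes) - 1)]
    max_drop = max(drops)
    # ties (within float tolerance) resolve to the smaller k
    best = next(i for i, d in enumerate(drops) if d >= max_drop - 1e-9)
    return ks[best + 1]


def scale_anchors(anchors: AnchorSet, target_size: int, source_size: int | None = None) -> AnchorSet:
    """Rescale anchors linearly to a new input resolution (nearest-integer px)."""
    if target_size <= 0:
        raise ValueError("target size must be positive")
    src = source_size if source_size is not None else anchors.input_size
    if src <= 0:
        raise ValueError("source input size unknown; pass source_size")
    factor = target_size / src
    scaled = tuple(
        (float(round(w * factor)), float(round(h * factor))) for w, h in anchors.anchors
    )
    return AnchorSet(anchors=scaled, avg_iou=anchors.avg_iou, input_size=target_size)
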