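"""Core annotation containers: boxes, labeled images, dataset splits, detections.

Coordinates are continuous pixels in the image frame with the origin at the
top-left corner; boxes are half-open rectangles [x_min, x_max) x [y_min, y_max)
so that width = x_max - x_min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: the label set of the flowering-phenology task
DEFAULT_CLASSES = ("flower", "bud")


@dataclass(frozen=True)
class BoundingBox:
    """One rectangular annotation or detection.

    ``confidence`` is None for ground truth and a fraction in [0, 1] for
    detector output.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_name: str
    confidence: Optional[float] = None

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box: ({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0,1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def clipped(self, width: float, height: float) -> Optional["BoundingBox"]:
        """Clip to [0,width]x[0,height]; None if nothing remains."""
        x0, y0 = max(self.x_min, 0.0), max(self.y_min, 0.0)
        x1, y1 = min(self.x_max, width), min(self.y_max, height)
        if x1 <= x0 or y1 <= y0:
            return None
        return replace(self, x_min=x0, y_min=y0, x_max=x1, y_max=y1)

    def iou(self, other: "BoundingBox") -> float:
        """Corner-coordinate intersection-over-union."""
        ix = max(0.0, min(self.x_max, other.x_max) - max(self.x_min, other.x_min))
        iy = max(0.0, min(self.y_max, other.y_max) - max(self.y_min, other.y_min))
        inter = ix * iy
        union = self.area + other.area - inter
        return inter / union if union > 0 else 0.0

    def shifted(self, dx: float, dy: float) -> "BoundingBox":
        return replace(
            self,
            x_min=self.x_min + dx,
            y_min=self.y_min + dy,
            x_max=self.x_max + dx,
            y_max=self.y_max + dy,
        )


@dataclass
class LabeledImage:
    """An image with its ground-truth boxes."""

    image_id: str
    width: int
    height: int
    pixels: Optional[np.ndarray]  # H x W x 3 uint8, None when annotation-only
    boxes: list[BoundingBox] = field(default_factory=list)

    def __post_init__(self):
        if self.pixels is not None:
            h, w = self.pixels.shape[:2]
            if (h, w) != (self.height, self.width):
                raise ValueError(
                    f"pixel array {h}x{w} disagrees with size {self.height}x{self.width}"
                )

    def clip_boxes(self) -> None:
        clipped = []
        for b in self.boxes:
            cb = b.clipped(self.width, self.height)
            if cb is not None:
                clipped.append(cb)
        self.boxes = clipped

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for b in self.boxes:
            out[b.class_name] = out.get(b.class_name, 0) + 1
        return out


@dataclass(frozen=True)
class Detection:
    """A detector output box bound to a source image."""

    box: BoundingBox
    image_id: str

    def __post_init__(self):
        if self.box.confidence is None:
            raise ValueError("a Detection requires a confidence score")

    @property
    def class_name(self) -> str:
        return self.box.class_name

    @property
    def confidence(self) -> float:
        return self.box.confidence  # type: ignore[return-value]


@dataclass
class DatasetSplit:
    """Disjoint, exhaustive train/val/test partition of image ids."""

    train: list[str]
    val: list[str]
    test: list[str]
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self):
        all_ids = self.train + self.val + self.test
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split buckets overlap")

    @property
    def n_total(self) -> int:
        return len(self.train) + len(self.val) + len(self.test)

    def bucket_of(self, image_id: str) -> str:
        for name in ("train", "val", "test"):
            if image_id in getattr(self, name):
                return name
        raise KeyError(image_id)


def boxes_as_array(boxes: Sequence[BoundingBox]) -> np.ndarray:
    """(n, 4) float array of corner coordinates."""
    if not boxes:
        return np.zeros((0, 4))
    return np.array([[b.x_min, b.y_min, b.x_max, b.y_max] for b in boxes], dtype=float)
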