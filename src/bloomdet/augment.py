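"""Data enhancement: Cutout occlusion, Mosaic composition, geometric and
photometric transforms, and minority-class balancing.

Cutout zeroes a square region (default 100x100) at a uniformly random center
to emulate foliage occlusion; ground-truth boxes are left untouched — an
occluded flower is still annotated, which is exactly the phenomenon the
augmentation teaches the detector to survive.  Mosaic composites four
jittered images into one canvas around a random split point, fusing
background context from different scenes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .boxes import BoundingBox, LabeledImage


@dataclass(frozen=True)
class CutoutConfig:
    size: int = 100
    fill_value: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("cutout size must be >= 1")
        if not (0 <= self.fill_value <= 255):
            raise ValueError("fill value must be an intensity in [0,255]")


_KNOWN_OPS = ("flip", "mirror", "crop", "translate", "rotate", "brightness", "noise", "cutout")


@dataclass(frozen=True)
class AugmentPlan:
    """Ordered augmentation recipe.

    ``ops`` is an ordered subset of {flip, mirror, crop, translate, rotate,
    brightness, noise, cutout}; ``params`` holds per-op parameter ranges.
    ``flip`` is a vertical axis flip, ``mirror`` horizontal; ``rotate`` is a
    right-angle rotation (the arbitrary-angle variant of "random flipping" is
    exposed as its own op so plans can choose).
    """

    ops: tuple[str, ...] = ("mirror", "brightness", "noise")
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for op in self.ops:
            if op not in _KNOWN_OPS:
                raise ValueError(f"unknown augmentation op {op!r}")


def cutout(image: LabeledImage, config: CutoutConfig) -> LabeledImage:
    """Zero one axis-aligned square; boxes pass through unchanged.

    The square's center is uniform over the image and the square is clipped
    at the borders, following the original Cutout formulation; a region
    larger than the image simply covers it entirely.
    """
    rng = np.random.default_rng(config.seed)
    h, w = image.height, image.width
    cy = rng.integers(0, h)
    cx = rng.integers(0, w)
    half = config.size // 2
    y0, y1 = max(0, cy - half), min(h, cy - half + config.size)
    x0, x1 = max(0, cx - half), min(w, cx - half + config.size)
    pixels = image.pixels.copy()
    pixels[y0:y1, x0:x1, :] = config.fill_value
    return LabeledImage(
        image_id=image.image_id,
        width=w,
        height=h,
        pixels=pixels,
        boxes=list(image.boxes),
    )


def _transform_boxes_affine(
    boxes: Sequence[BoundingBox],
    fn,
    out_w: float,
    out_h: float,
    min_area_frac: float = 0.0,
) -> list[BoundingBox]:
    """Map box corners through a point transform, clip, drop tiny remnants."""
    out = []
    for b in boxes:
        corners = [fn(x, y) for x, y in ((b.x_min, b.y_min), (b.x_max, b.y_min),
                                         (b.x_min, b.y_max), (b.x_max, b.y_max))]
        xs = [c[0] for c in corners]
        ys = [c[1] for c in corners]
        nb = BoundingBox(min(xs), min(ys), max(xs), max(ys), b.class_name, b.confidence)
        clipped = nb.clipped(out_w, out_h)
        if clipped is None:
            continue
        if min_area_frac > 0 and clipped.area < min_area_frac * b.area:
            continue
        out.append(clipped)
    return out


def _apply_geometric(image: LabeledImage, op: str, rng: np.random.Generator,
                     params: dict) -> LabeledImage:
    h, w = image.height, image.width
    px = image.pixels
    if op == "mirror":  # horizontal flip
        new_px = px[:, ::-1, :].copy()
        fn = lambda x, y: (w - x, y)
        boxes = _transform_boxes_affine(image.boxes, fn, w, h)
    elif op == "flip":  # vertical flip
        new_px = px[::-1, :, :].copy()
        fn = lambda x, y: (x, h - y)
        boxes = _transform_boxes_affine(image.boxes, fn, w, h)
    elif op == "rotate":  # right-angle rotation, k in {1,2,3} quarter turns
        k = int(rng.integers(1, 4))
        new_px = np.rot90(px, k=k, axes=(0, 1)).copy()
        if k == 1:  # 90 deg counterclockwise: (x,y) -> (y, w-x), canvas h x w -> w x h
            fn = lambda x, y: (y, w - x)
            ow, oh = h, w
        elif k == 2:
            fn = lambda x, y: (w - x, h - y)
            ow, oh = w, h
        else:
            fn = lambda x, y: (h - y, x)
            ow, oh = h, w
        boxes = _transform_boxes_affine(image.boxes, fn, ow, oh)
        return LabeledImage(image.image_id, ow, oh, new_px, boxes)
    elif op == "translate":
        rng_range = params.get("translate", (-0.2, 0.2))
        dx = float(rng.uniform(*rng_range)) * w if "dx" not in params else params["dx"]
        dy = float(rng.uniform(*rng_range)) * h if "dy" not in params else params["dy"]
        dx_i, dy_i = int(round(dx)), int(round(dy))
        new_px = np.zeros_like(px)
        src_y0, src_y1 = max(0, -dy_i), min(h, h - dy_i)
        src_x0, src_x1 = max(0, -dx_i), min(w, w - dx_i)
        dst_y0, dst_x0 = max(0, dy_i), max(0, dx_i)
        new_px[dst_y0:dst_y0 + (src_y1 - src_y0), dst_x0:dst_x0 + (src_x1 - src_x0)] = \
            px[src_y0:src_y1, src_x0:src_x1]
        fn = lambda x, y: (x + dx_i, y + dy_i)
        boxes = _transform_boxes_affine(image.boxes, fn, w, h)
    elif op == "crop":
        frac = params.get("crop_frac", (0.6, 0.95))
        cw = int(w * rng.uniform(*frac))
        ch = int(h * rng.uniform(*frac))
        x0 = int(rng.integers(0, w - cw + 1))
        y0 = int(rng.integers(0, h - ch + 1))
        new_px = px[y0:y0 + ch, x0:x0 + cw].copy()
        fn = lambda x, y: (x - x0, y - y0)
        boxes = _transform_boxes_affine(image.boxes, fn, cw, ch, min_area_frac=0.2)
        if new_px.size == 0:
            raise ValueError("crop produced an empty image")
        return LabeledImage(image.image_id, cw, ch, new_px, boxes)
    else:  # pragma: no cover
        raise ValueError(op)
    return LabeledImage(image.image_id, w, h, new_px, boxes)


def _apply_photometric(image: LabeledImage, op: str, rng: np.random.Generator,
                       params: dict) -> LabeledImage:
    px = image.pixels.astype(np.float64)
    if op == "brightness":
        lo, hi = params.get("brightness", (0.6, 1.4))
        scale = params.get("brightness_scale", float(rng.uniform(lo, hi)))
        px = px * scale
    elif op == "noise":
        amp = params.get("noise_amp", 8.0)
        if amp > 0:
            px = px + rng.normal(0.0, amp, px.shape)
    else:  # pragma: no cover
        raise ValueError(op)
    out = np.clip(px, 0, 255).astype(np.uint8)
    return LabeledImage(image.image_id, image.width, image.height, out, list(image.boxes))


def apply_plan(image: LabeledImage, plan: AugmentPlan) -> LabeledImage:
    """Apply the plan's ops in declared order.

    Geometric ops transform pixels and boxes consistently; photometric ops
    leave boxes untouched.
    """
    rng = np.random.default_rng(plan.seed)
    out = image
    for op in plan.ops:
        if op in ("mirror", "flip", "rotate", "translate", "crop"):
            out = _apply_geometric(out, op, rng, plan.params)
        elif op in ("brightness", "noise"):
            out = _apply_photometric(out, op, rng, plan.params)
        elif op == "cutout":
            cfg = CutoutConfig(
                size=plan.params.get("cutout_size", 100),
                fill_value=plan.params.get("cutout_fill", 0),
                seed=int(rng.integers(2**31)),
            )
            out = cutout(out, cfg)
        if out.pixels.size == 0:
            raise ValueError(f"op {op!r} produced an empty image")
    return out


def mosaic(images: Sequence[LabeledImage], out_size: int, seed: int = 0,
           drop_area_frac: float = 0.2) -> LabeledImage:
    """Compose exactly four images into one canvas around a random split point.

    Each input is photometrically jittered and scaled to its quadrant; boxes
    are transformed, clipped to their quadrant, and dropped when the clipped
    area falls below ``drop_area_frac`` of the original.
    """
    if len(images) != 4:
        raise ValueError(f"mosaic requires exactly 4 images, got {len(images)}")
    rng = np.random.default_rng(seed)
    sx = int(out_size * rng.uniform(0.3, 0.7))
    sy = int(out_size * rng.uniform(0.3, 0.7))
    regions = [  # (x0, y0, x1, y1) quadrants
        (0, 0, sx, sy),
        (sx, 0, out_size, sy),
        (0, sy, sx, out_size),
        (sx, sy, out_size, out_size),
    ]
    canvas = np.zeros((out_size, out_size, 3), dtype=np.uint8)
    boxes: list[BoundingBox] = []
    for img, (x0, y0, x1, y1) in zip(images, regions):
        rw, rh = x1 - x0, y1 - y0
        if rw <= 0 or rh <= 0:
            continue
        jit = _hsv_jitter(img.pixels, rng)
        patch = _resize_nearest(jit, rh, rw)
        canvas[y0:y1, x0:x1] = patch
        fx = rw / img.width
        fy = rh / img.height
        for b in img.boxes:
            nb = BoundingBox(
                b.x_min * fx + x0, b.y_min * fy + y0,
                b.x_max * fx + x0, b.y_max * fy + y0,
                b.class_name, b.confidence,
            )
            scaled_area = nb.area
            clipped = nb.clipped(x1, y1)
            if clipped is None:
                continue
            cb = BoundingBox(
                max(clipped.x_min, x0), max(clipped.y_min, y0),
                clipped.x_max, clipped.y_max, b.class_name, b.confidence,
            ) if clipped.x_min < x0 or clipped.y_min < y0 else clipped
            if cb.area >= drop_area_frac * scaled_area:
                boxes.append(cb)
    return LabeledImage(
        image_id=f"mosaic_{seed}", width=out_size, height=out_size,
        pixels=canvas, boxes=boxes,
    )


def _resize_nearest(px: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = px.shape[:2]
    ys = (np.arange(out_h) * h / out_h).astype(int).clip(0, h - 1)
    xs = (np.arange(out_w) * w / out_w).astype(int).clip(0, w - 1)
    return px[np.ix_(ys, xs)]


def _hsv_jitter(px: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mild color-gamut shift: per-channel gains plus a global value gain.

    Purely multiplicative, so a black canvas stays black.
    """
    gains = rng.uniform(0.85, 1.15, size=3) * rng.uniform(0.9, 1.1)
    out = px.astype(np.float64) * gains
    return np.clip(out, 0, 255).astype(np.uint8)


def balance_classes(
    dataset: Sequence[LabeledImage],
    minority: str,
    expansion_factor: int,
    plan: AugmentPlan,
    base_copies: int = 1,
) -> list[LabeledImage]:
    """Augment minority-class images ``expansion_factor`` x more than others.

    Returns the originals followed by augmented copies with provenance-tagged
    ids (``<id>/aug<k>``).  If the minority class appears nowhere, a warning
    is emitted and the originals are returned unchanged.
    """
    if expansion_factor < 1:
        raise ValueError("expansion factor must be >= 1")
    if not any(minority in img.class_counts() for img in dataset):
        import warnings

        warnings.warn(f"minority class {minority!r} absent from the dataset")
        return list(dataset)
    out = list(dataset)
    for img in dataset:
        copies = base_copies * (
            expansion_factor if minority in img.class_counts() else 1
        )
        for j in range(copies):
            stable = sum(ord(c) for c in img.image_id) % 10007  # process-independent
            aug = apply_plan(img, replace(plan, seed=plan.seed * 9973 + stable + j))
            aug = copy.copy(aug)
            aug.image_id = f"{img.image_id}/aug{j}"
            out.append(aug)
    return out
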