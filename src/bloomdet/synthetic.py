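"""Synthetic orchard scenes with known ground truth.

Real citrus-orchard imagery shows white five-petal flowers and small pale buds
against cluttered green foliage, at densities from a few isolated blossoms to
dense clusters, under varying luminosity and with frequent partial occlusion
by leaves.  This module emulates those conditions procedurally so that every
downstream component (anchor clustering, augmentation, training, evaluation)
is testable with exactly known box annotations:

* flowers render as rosettes of 5 white elliptical petals around a yellow
  center — bright, multi-lobed, the size of a typical near-field blossom;
* buds render as single small pale ellipses;
* the background is either a flat green or a cluttered texture of randomly
  placed darker/lighter leaf-colored ellipses;
* occlusion draws a leaf-colored ellipse over part of a blob; the annotation
  keeps the full extended box (an occluded flower is still a flower);
* ``luminosity`` scales all intensities multiplicatively to emulate dusk or
  overexposure-corrected frames.

Everything is integer-pixel deterministic for a fixed seed.

Density presets follow the package's convention for stratified evaluation:
sparse scenes have at most 10 boxes, medium 11-30, dense more than 30.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .annotation_io import split_dataset, write_split_manifests, write_voc_xml
from .boxes import BoundingBox, DatasetSplit, LabeledImage

# render palette (RGB)
_GREEN_BG = np.array([52, 86, 38], dtype=np.int16)
_LEAF_SHADES = np.array(
    [[34, 64, 26], [68, 108, 48], [46, 96, 40], [90, 126, 60]], dtype=np.int16
)
_PETAL = np.array([246, 246, 240], dtype=np.int16)
_CENTER = np.array([235, 200, 60], dtype=np.int16)
_BUD = np.array([225, 228, 205], dtype=np.int16)

#: boxes-per-image thresholds for the sparse / medium / dense strata
DENSITY_THRESHOLDS = (10, 30)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic orchard scene."""

    width: int = 608
    height: int = 608
    n_flowers: int = 8
    n_buds: int = 4
    flower_size_range: tuple[int, int] = (40, 110)
    bud_size_range: tuple[int, int] = (14, 34)
    occlusion_prob: float = 0.25
    background: str = "cluttered"  # {"simple", "cluttered"}
    luminosity: float = 1.0
    min_separation: float = 0.0  # minimum center distance as fraction of blob size
    seed: int = 0

    def __post_init__(self):
        if self.background not in ("simple", "cluttered"):
            raise ValueError(f"unknown background {self.background!r}")
        if not (0.0 < self.luminosity <= 1.5):
            raise ValueError("luminosity must lie in (0, 1.5]")
        for lo, hi in (self.flower_size_range, self.bud_size_range):
            if lo <= 0 or hi < lo:
                raise ValueError("size ranges must be positive and ordered")
        if min(self.n_flowers, self.n_buds) < 0:
            raise ValueError("counts must be >= 0")


#: well-separated large blossoms on a plain background — the regime a small
#: detector can learn from tens of images
EASY_SCENE = SceneConfig(
    width=160,
    height=160,
    n_flowers=2,
    n_buds=2,
    flower_size_range=(40, 56),
    bud_size_range=(26, 36),
    occlusion_prob=0.0,
    background="simple",
    min_separation=0.8,
)

DENSITY_PRESETS = {
    "sparse": SceneConfig(n_flowers=4, n_buds=2),
    "medium": SceneConfig(n_flowers=14, n_buds=6),
    "dense": SceneConfig(n_flowers=28, n_buds=10),
}


@dataclass(frozen=True)
class BoxPopulationSpec:
    """Clustered width-height population for anchor-clustering fixtures."""

    cluster_centers: tuple[tuple[float, float], ...] = ((23, 22), (64, 62), (165, 141))
    points_per_cluster: int = 100
    jitter_sd: float = 3.0
    seed: int = 0


class PlacementError(RuntimeError):
    """Raised when the requested object count cannot be placed."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(f"placed only {achieved} of {requested} objects")
        self.requested = requested
        self.achieved = achieved


def _disk_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float, theta: float = 0.0):
    """Boolean mask of a rotated filled ellipse on an h x w grid."""
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    xr = x * ct + y * st
    yr = -x * st + y * ct
    return (xr / rx) ** 2 + (yr / ry) ** 2 <= 1.0


def _paint(img: np.ndarray, mask: np.ndarray, color: np.ndarray) -> None:
    img[mask] = color


def _render_flower(img: np.ndarray, rng: np.random.Generator, cx: float, cy: float, size: float):
    """Five white petals around a yellow center; returns the tight pixel mask."""
    h, w = img.shape[:2]
    petal_r = size * 0.30
    ring = size / 2.0 - petal_r
    total = np.zeros((h, w), dtype=bool)
    phase = rng.uniform(0, 2 * np.pi)
    for i in range(5):
        ang = phase + i * 2 * np.pi / 5
        px = cx + ring * np.cos(ang)
        py = cy + ring * np.sin(ang)
        m = _disk_mask(h, w, py, px, petal_r, petal_r * rng.uniform(0.75, 1.0), ang)
        _paint(img, m, _PETAL)
        total |= m
    m = _disk_mask(h, w, cy, cx, size * 0.14, size * 0.14)
    _paint(img, m, _CENTER)
    total |= m
    return total


def _render_bud(img: np.ndarray, rng: np.random.Generator, cx: float, cy: float, size: float):
    h, w = img.shape[:2]
    theta = rng.uniform(0, np.pi)
    m = _disk_mask(h, w, cy, cx, size / 2.0, size / 2.0 * rng.uniform(0.6, 0.85), theta)
    _paint(img, m, _BUD)
    return m


def _mask_bbox(mask: np.ndarray) -> Optional[tuple[float, float, float, float]]:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return None
    # half-open box tightly enclosing the mask pixels
    return float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1)


def generate_scene(config: SceneConfig) -> LabeledImage:
    """Render one orchard scene; deterministic per seed.

    Every rendered flower/bud carries exactly one ground-truth box tightly
    enclosing its pixels before occlusion (occluded blobs stay annotated with
    their full extent).
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    img = np.empty((h, w, 3), dtype=np.int16)
    img[:] = _GREEN_BG
    if config.background == "cluttered":
        n_leaves = max(8, (h * w) // 6000)
        for _ in range(n_leaves):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            r = rng.uniform(0.02, 0.09) * min(h, w)
            shade = _LEAF_SHADES[rng.integers(len(_LEAF_SHADES))]
            m = _disk_mask(h, w, cy, cx, r, r * rng.uniform(0.4, 0.9), rng.uniform(0, np.pi))
            _paint(img, m, shade)

    boxes: list[BoundingBox] = []
    placed_centers: list[tuple[float, float, float]] = []  # (cx, cy, size)
    todo = [("flower", config.flower_size_range)] * config.n_flowers
    todo += [("bud", config.bud_size_range)] * config.n_buds
    occlusions: list[tuple[np.ndarray, float]] = []

    for cls, (lo, hi) in todo:
        size = float(rng.uniform(lo, hi))
        ok = False
        for _attempt in range(200):
            cx = rng.uniform(size / 2, w - size / 2) if w > size else w / 2
            cy = rng.uniform(size / 2, h - size / 2) if h > size else h / 2
            if config.min_separation > 0:
                min_d = config.min_separation * size
                if any(
                    np.hypot(cx - px, cy - py) < min_d * 0.5 + ps * config.min_separation * 0.5
                    for px, py, ps in placed_centers
                ):
                    continue
            ok = True
            break
        if not ok:
            raise PlacementError(len(todo), len(boxes))
        if cls == "flower":
            mask = _render_flower(img, rng, cx, cy, size)
        else:
            mask = _render_bud(img, rng, cx, cy, size)
        bbox = _mask_bbox(mask)
        if bbox is None:  # fully outside the frame; should not happen
            raise PlacementError(len(todo), len(boxes))
        boxes.append(BoundingBox(*bbox, class_name=cls))
        placed_centers.append((cx, cy, size))
        if rng.uniform() < config.occlusion_prob:
            occlusions.append((mask, size))

    # draw occluders after all blobs so boxes stay tight to pre-occlusion extent
    for mask, size in occlusions:
        ys, xs = np.nonzero(mask)
        cy = float(ys.mean())
        cx = float(xs.mean())
        off = size * 0.35
        ocy = cy + rng.uniform(-off, off)
        ocx = cx + rng.uniform(-off, off)
        r = size * rng.uniform(0.25, 0.5)  # covers up to ~50% of the blob
        shade = _LEAF_SHADES[rng.integers(len(_LEAF_SHADES))]
        m = _disk_mask(h, w, ocy, ocx, r, r * rng.uniform(0.5, 0.9), rng.uniform(0, np.pi))
        _paint(img, m, shade)

    pixels = np.clip(img.astype(np.float64) * config.luminosity, 0, 255).astype(np.uint8)
    return LabeledImage(
        image_id=f"scene_{config.seed:08d}",
        width=w,
        height=h,
        pixels=pixels,
        boxes=boxes,
    )


def generate_box_population(spec: BoxPopulationSpec) -> list[tuple[float, float]]:
    """Width-height pairs with Gaussian jitter around planted cluster centers.

    Dimensions are truncated at 1 px so every box stays valid.
    """
    rng = np.random.default_rng(spec.seed)
    pairs: list[tuple[float, float]] = []
    for cw, ch in spec.cluster_centers:
        ws = rng.normal(cw, spec.jitter_sd, spec.points_per_cluster)
        hs = rng.normal(ch, spec.jitter_sd, spec.points_per_cluster)
        for wv, hv in zip(ws, hs):
            pairs.append((max(1.0, float(wv)), max(1.0, float(hv))))
    return pairs


def generate_dataset(
    config: SceneConfig,
    n_images: int,
    out_dir: str | Path,
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
) -> DatasetSplit:
    """Write ``n_images`` PNG + VOC XML pairs and return a 7:2:1 split.

    Per-image seeds are derived from the master seed and recorded in a
    manifest for exact reproduction.
    """
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = []
    manifest = []
    for i in range(n_images):
        img_seed = (config.seed * 100003 + i) % (2**31)
        scene = generate_scene(replace(config, seed=img_seed))
        image_id = f"img_{i:05d}"
        scene.image_id = image_id
        Image.fromarray(scene.pixels).save(out / f"{image_id}.png")
        write_voc_xml(scene, out / f"{image_id}.xml")
        ids.append(image_id)
        manifest.append(f"{image_id}\t{img_seed}")
    (out / "seeds.tsv").write_text("\n".join(manifest) + "\n")
    split = split_dataset(ids, ratios=ratios, seed=config.seed)
    write_split_manifests(split, out)
    return split


def generate_scenes(config: SceneConfig, n_images: int) -> list[LabeledImage]:
    """In-memory variant of :func:`generate_dataset` (no file I/O)."""
    scenes = []
    for i in range(n_images):
        img_seed = (config.seed * 100003 + i) % (2**31)
        scene = generate_scene(replace(config, seed=img_seed))
        scene.image_id = f"img_{i:05d}"
        scenes.append(scene)
    return scenes
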