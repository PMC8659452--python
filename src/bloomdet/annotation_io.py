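"""Pascal VOC XML (LabelImg dialect) and YOLO-txt annotation I/O, dataset splits.

VOC XML files written by LabelImg carry 1-based inclusive pixel coordinates;
they are converted to 0-based half-open on read (so width = x_max - x_min) and
converted back on write.  YOLO txt lines are ``class_index cx cy w h`` with all
values normalized to [0, 1].
"""

from __future__ import annotations

import random
from pathlib import Path
from typing import Sequence

from lxml import etree

from .boxes import BoundingBox, DatasetSplit, LabeledImage


class AnnotationFormatError(ValueError):
    """Raised for structurally invalid annotation files."""


def read_voc_xml(path: str | Path, load_pixels: bool = False) -> LabeledImage:
    """Parse one LabelImg-style Pascal VOC XML file.

    Boxes are clipped to the image bounds; unknown class names pass through
    verbatim.  If ``load_pixels`` is true and the referenced image file exists
    next to the XML, its pixels are loaded.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise AnnotationFormatError(f"malformed VOC XML in {path}: {exc}") from exc
    root = tree.getroot()
    size = root.find("size")
    if size is None:
        raise AnnotationFormatError(f"{path}: missing <size> element")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))

    boxes: list[BoundingBox] = []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        bnd = obj.find("bndbox")
        if name is None or bnd is None:
            raise AnnotationFormatError(f"{path}: <object> missing name or bndbox")
        # LabelImg: 1-based inclusive -> 0-based half-open
        x_min = float(bnd.findtext("xmin")) - 1.0
        y_min = float(bnd.findtext("ymin")) - 1.0
        x_max = float(bnd.findtext("xmax"))
        y_max = float(bnd.findtext("ymax"))
        boxes.append(BoundingBox(x_min, y_min, x_max, y_max, name))

    pixels = None
    if load_pixels:
        img_file = root.findtext("filename")
        if img_file:
            img_path = path.parent / img_file
            if img_path.exists():
                import numpy as np
                from PIL import Image

                pixels = np.asarray(Image.open(img_path).convert("RGB"))

    image = LabeledImage(
        image_id=path.stem, width=width, height=height, pixels=pixels, boxes=boxes
    )
    image.clip_boxes()
    return image


def write_voc_xml(image: LabeledImage, path: str | Path) -> None:
    """Emit Pascal VOC XML readable by :func:`read_voc_xml` and by LabelImg."""
    path = Path(path)
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = path.parent.name
    etree.SubElement(root, "filename").text = f"{image.image_id}.png"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(image.width)
    etree.SubElement(size, "height").text = str(image.height)
    etree.SubElement(size, "depth").text = "3"
    etree.SubElement(root, "segmented").text = "0"
    for b in image.boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = b.class_name
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        # 0-based half-open -> 1-based inclusive integers
        etree.SubElement(bnd, "xmin").text = str(int(round(b.x_min)) + 1)
        etree.SubElement(bnd, "ymin").text = str(int(round(b.y_min)) + 1)
        etree.SubElement(bnd, "xmax").text = str(int(round(b.x_max)))
        etree.SubElement(bnd, "ymax").text = str(int(round(b.y_max)))
    path.write_bytes(etree.tostring(root, pretty_print=True))


def read_yolo_txt(
    path: str | Path,
    width: float,
    height: float,
    class_names: Sequence[str],
) -> list[BoundingBox]:
    """Read one YOLO txt file of normalized ``class cx cy w h`` lines."""
    boxes: list[BoundingBox] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise AnnotationFormatError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        idx = int(parts[0])
        cx, cy, w, h = (float(v) for v in parts[1:])
        for name, v in zip(("cx", "cy", "w", "h"), (cx, cy, w, h)):
            if not (0.0 <= v <= 1.0):
                raise AnnotationFormatError(f"{path}:{ln}: {name}={v} outside [0,1]")
        if not (0 <= idx < len(class_names)):
            raise IndexError(f"{path}:{ln}: class index {idx} outside label set")
        boxes.append(
            BoundingBox(
                x_min=(cx - w / 2.0) * width,
                y_min=(cy - h / 2.0) * height,
                x_max=(cx + w / 2.0) * width,
                y_max=(cy + h / 2.0) * height,
                class_name=class_names[idx],
            )
        )
    return boxes


def write_yolo_txt(
    boxes: Sequence[BoundingBox],
    path: str | Path,
    width: float,
    height: float,
    class_names: Sequence[str],
) -> None:
    """Write YOLO txt (inverse of :func:`read_yolo_txt`)."""
    lines = []
    for b in boxes:
        idx = list(class_names).index(b.class_name)
        cx = (b.x_min + b.x_max) / 2.0 / width
        cy = (b.y_min + b.y_max) / 2.0 / height
        w = b.width / width
        h = b.height / height
        lines.append(f"{idx} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def split_dataset(
    image_ids: Sequence[str],
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Deterministic shuffled train/val/test partition.

    Bucket sizes are floor(n * ratio) with remainders distributed to train
    first, then val, so the realized proportions are within one item of the
    requested ratios.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios {ratios} do not sum to 1")
    ids = list(image_ids)
    rng = random.Random(seed)
    rng.shuffle(ids)
    n = len(ids)
    n_train = int(n * ratios[0])
    n_val = int(n * ratios[1])
    n_test = int(n * ratios[2])
    remainder = n - n_train - n_val - n_test  # at most 2 for three buckets
    if remainder >= 1:
        n_train += 1
    if remainder == 2:
        n_val += 1
    return DatasetSplit(
        train=ids[:n_train],
        val=ids[n_train : n_train + n_val],
        test=ids[n_train + n_val :],
        ratios=ratios,
        seed=seed,
    )


def write_split_manifests(split: DatasetSplit, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("train", "val", "test"):
        (out / f"{name}.txt").write_text("\n".join(getattr(split, name)) + "\n")
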