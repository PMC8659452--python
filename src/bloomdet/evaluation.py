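"""VOC-style detection evaluation: precision, recall, AP, mAP, F1,
and density-stratified reporting.

Matching follows the standard VOC protocol: detections are processed in
descending confidence; each detection matches the highest-IoU unmatched
ground truth of the same class and image with IoU >= threshold (a true
positive), otherwise it is a false positive; unmatched ground truths are
false negatives.  AP integrates the monotone (all-point interpolated)
precision envelope over recall; mAP is the arithmetic mean of per-class APs;
F1 = 2PR/(P+R) = 2TP/(2TP+FP+FN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .boxes import BoundingBox, Detection, LabeledImage
from .synthetic import DENSITY_THRESHOLDS


@dataclass
class MatchResult:
    """TP/FP flags per ranked detection and the ground-truth tally."""

    tp_flags: list[bool]  # per detection, in descending-confidence order
    n_gt: int
    iou_threshold: float = 0.5

    @property
    def tp(self) -> int:
        return sum(self.tp_flags)

    @property
    def fp(self) -> int:
        return len(self.tp_flags) - self.tp

    @property
    def fn(self) -> int:
        return self.n_gt - self.tp


@dataclass
class PRCurve:
    """Cumulative precision/recall along the confidence-ranked detections."""

    precision: np.ndarray
    recall: np.ndarray
    n_gt: int

    @property
    def final_precision(self) -> float:
        return float(self.precision[-1]) if len(self.precision) else 1.0

    @property
    def final_recall(self) -> float:
        return float(self.recall[-1]) if len(self.recall) else 0.0


@dataclass
class EvalReport:
    """Per-class AP/PR plus aggregate mAP and F1."""

    per_class_ap: dict[str, float]
    per_class_f1: dict[str, float]
    per_class_pr: dict[str, PRCurve]
    mAP: float
    f1: float
    strata: dict[str, "EvalReport"] = field(default_factory=dict)


def _sort_by_confidence(dets: Sequence[Detection]) -> list[Detection]:
    # stable order: confidence desc, then box coordinates for reproducibility
    return sorted(
        dets,
        key=lambda d: (-d.confidence, d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max),
    )


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[tuple[str, BoundingBox]],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy VOC matching of one class's detections against ground truth.

    ``gts`` may be plain boxes (single-image evaluation) or (image_id, box)
    pairs.  Ties on IoU resolve to the lower ground-truth index.
    """
    norm_gts = [(None, g) if isinstance(g, BoundingBox) else g for g in gts]
    ranked = _sort_by_confidence(dets)
    matched = [False] * len(norm_gts)
    flags: list[bool] = []
    for det in ranked:
        best_iou = 0.0
        best_j = -1
        for j, (img_id, gt) in enumerate(norm_gts):
            if matched[j] or (img_id is not None and img_id != det.image_id):
                continue
            iou = det.box.iou(gt)
            if iou > best_iou:  # strict: ties keep the earlier candidate
                best_iou = iou
                best_j = j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    return MatchResult(tp_flags=flags, n_gt=len(gts), iou_threshold=iou_threshold)


def precision_recall(matches: MatchResult) -> PRCurve:
    """Cumulative P/R along the ranked detection list.

    With zero detections the curve is empty; precision at zero recall is
    reported as 1 by convention.
    """
    flags = np.asarray(matches.tp_flags, dtype=float)
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(1.0 - flags)
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    recall = tp_cum / matches.n_gt if matches.n_gt > 0 else np.zeros_like(tp_cum)
    return PRCurve(precision=precision, recall=recall, n_gt=matches.n_gt)


def average_precision(pr: PRCurve, method: str = "interp") -> float:
    """Area under the PR curve.

    ``interp`` (default) integrates the monotone all-point precision
    envelope; ``voc2007`` averages the envelope at the 11 recall points
    0, 0.1, ..., 1.0.
    """
    if pr.n_gt == 0:
        return 0.0
    if len(pr.precision) == 0:
        return 0.0
    mrec = np.concatenate([[0.0], pr.recall, [1.0]])
    mpre = np.concatenate([[1.0], pr.precision, [0.0]])
    # monotone envelope from the right
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    if method == "voc2007":
        pts = np.linspace(0, 1, 11)
        vals = [mpre[np.searchsorted(mrec, t, side="left")] if t <= mrec[-1] else 0.0
                for t in pts]
        return float(np.mean(vals))
    if method != "interp":
        raise ValueError(f"unknown AP method {method!r}")
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def mean_ap(aps: Sequence[float]) -> float:
    """Arithmetic mean of per-class APs."""
    if len(aps) == 0:
        raise ValueError("mean AP needs at least one class")
    return float(np.mean(aps))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate_detections(
    dets: Sequence[Detection],
    images: Sequence[LabeledImage],
    iou_threshold: float = 0.5,
    classes: Optional[Sequence[str]] = None,
    ap_method: str = "interp",
    strata_thresholds: Optional[tuple[int, int]] = None,
) -> EvalReport:
    """Full per-class evaluation of a detection set against labeled images.

    Classes default to those present in the ground truth.  When
    ``strata_thresholds`` is given, per-density sub-reports are computed over
    the few/middle/intensive image strata.
    """
    if classes is None:
        classes = sorted({b.class_name for img in images for b in img.boxes})
    per_ap: dict[str, float] = {}
    per_f1: dict[str, float] = {}
    per_pr: dict[str, PRCurve] = {}
    for cls in classes:
        cls_dets = [d for d in dets if d.class_name == cls]
        cls_gts = [(img.image_id, b) for img in images for b in img.boxes
                   if b.class_name == cls]
        m = match_detections(cls_dets, cls_gts, iou_threshold)
        pr = precision_recall(m)
        per_ap[cls] = average_precision(pr, method=ap_method)
        n_det = len(m.tp_flags)
        p = m.tp / n_det if n_det else 1.0
        r = m.tp / m.n_gt if m.n_gt else 0.0
        per_f1[cls] = f1_score(p, r)
        per_pr[cls] = pr

    report = EvalReport(
        per_class_ap=per_ap,
        per_class_f1=per_f1,
        per_class_pr=per_pr,
        mAP=mean_ap(list(per_ap.values())) if per_ap else 0.0,
        f1=float(np.mean(list(per_f1.values()))) if per_f1 else 0.0,
    )
    if strata_thresholds is not None:
        strata = stratify_by_density(images, strata_thresholds)
        for name, sub_imgs in strata.items():
            ids = {img.image_id for img in sub_imgs}
            sub_dets = [d for d in dets if d.image_id in ids]
            if sub_imgs:
                report.strata[name] = evaluate_detections(
                    sub_dets, sub_imgs, iou_threshold, classes, ap_method
                )
    return report


def stratify_by_density(
    images: Sequence[LabeledImage],
    thresholds: tuple[int, int] = DENSITY_THRESHOLDS,
) -> dict[str, list[LabeledImage]]:
    """Partition images into few/middle/intensive strata by box count.

    ``few``: <= t1 boxes; ``middle``: (t1, t2]; ``intensive``: > t2.
    """
    t1, t2 = thresholds
    if not t1 < t2:
        raise ValueError("thresholds must be increasing")
    out: dict[str, list[LabeledImage]] = {"few": [], "middle": [], "intensive": []}
    for img in images:
        n = len(img.boxes)
        if n <= t1:
            out["few"].append(img)
        elif n <= t2:
            out["middle"].append(img)
        else:
            out["intensive"].append(img)
    return out
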