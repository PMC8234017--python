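"""Object-detection scoring: IoU, greedy matching, precision-recall, interpolated AP and mAP.

A prediction counts as a true positive when its class label matches a
ground-truth box and their intersection-over-union

    IoU(B, G) = area(B & G) / area(B | G)

is at least the threshold t.  Detections below the confidence threshold
(strictly greater-than filter, default 0.5) are discarded; the rest are
processed in descending confidence and each is greedily matched to the
unmatched same-class ground truth with the highest IoU >= t — the
convention of the COCO evaluation literature.  Each ground truth matches
at most once; the leftovers are false negatives.

Average precision is the N-point interpolated area under the
precision-recall curve,

    AP = (1/N) * sum_i P_interp(R_i),   P_interp(R_i) = max_{R' >= R_i} P(R'),

with the 101-point recall grid {0.00, 0.01, ..., 1.00}.  mAP averages AP
over classes and over an IoU-threshold set: {0.5} for mAP[0.5] and the
ten thresholds 0.50, 0.55, ..., 0.95 for mAP[0.5:0.95].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "BoundingBox",
    "Detection",
    "GroundTruthBox",
    "MatchResult",
    "APResult",
    "iou",
    "match_detections",
    "interpolated_ap",
    "map_metric",
    "MAP_50_THRESHOLDS",
    "MAP_50_95_THRESHOLDS",
    "load_coco_ground_truth",
    "load_coco_detections",
    "write_coco_scene",
]

MAP_50_THRESHOLDS: Tuple[float, ...] = (0.5,)
MAP_50_95_THRESHOLDS: Tuple[float, ...] = tuple(0.5 + 0.05 * i for i in range(10))

DEFAULT_CONFIDENCE_THRESHOLD = 0.5


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with continuous corner coordinates."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "BoundingBox":
        """COCO corner-plus-size layout [x, y, w, h]."""
        return cls(x, y, x + w, y + h)

    @classmethod
    def from_center(cls, cx: float, cy: float, w: float, h: float) -> "BoundingBox":
        """YOLO center layout (cx, cy, w, h)."""
        return cls(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


@dataclass(frozen=True)
class GroundTruthBox:
    box: BoundingBox
    label: int = 0
    image_id: int = 0


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    confidence: float
    label: int = 0
    image_id: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    # per retained detection in descending confidence: (confidence, is_tp)
    flags: Tuple[Tuple[float, bool], ...] = ()
    n_ground_truth: int = 0


@dataclass(frozen=True)
class APResult:
    ap: float
    recalls: np.ndarray
    precisions: np.ndarray
    interpolated: np.ndarray  # P_interp on the recall grid


def iou(B: BoundingBox, G: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = min(B.xmax, G.xmax) - max(B.xmin, G.xmin)
    iy = min(B.ymax, G.ymax) - max(B.ymin, G.ymin)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (B.area + G.area - inter)


def _match_flags(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruthBox],
    t: float,
    conf_threshold: Optional[float],
) -> List[Tuple[float, bool]]:
    """Greedy confidence-ordered matching; returns (confidence, is_tp) per retained detection."""
    if conf_threshold is not None:
        dets = [d for d in dets if d.confidence > conf_threshold]
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    matched = [False] * len(gts)
    flags: List[Tuple[float, bool]] = []
    for i in order:
        d = dets[i]
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gts):
            if matched[j] or g.label != d.label or g.image_id != d.image_id:
                continue
            v = iou(d.box, g.box)
            if v >= t and v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0:
            matched[best_j] = True
            flags.append((d.confidence, True))
        else:
            flags.append((d.confidence, False))
    return flags


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruthBox],
    t: float = 0.5,
    conf_threshold: Optional[float] = DEFAULT_CONFIDENCE_THRESHOLD,
) -> MatchResult:
    """TP/FP/FN counts at IoU threshold t after confidence filtering.

    Pass ``conf_threshold=None`` to keep every detection (the AP path,
    which sweeps the confidence axis itself).
    """
    flags = _match_flags(dets, gts, t, conf_threshold)
    tp = sum(1 for _, ok in flags if ok)
    return MatchResult(
        tp=tp,
        fp=len(flags) - tp,
        fn=len(gts) - tp,
        flags=tuple(flags),
        n_ground_truth=len(gts),
    )


def interpolated_ap(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruthBox],
    t: float = 0.5,
    n_points: int = 101,
    conf_threshold: Optional[float] = None,
) -> APResult:
    """N-point interpolated average precision at one IoU threshold.

    Builds the cumulative precision-recall sequence from confidence-sorted
    detections, takes the running maximum from the right, and averages the
    interpolated precision over the uniform recall grid.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if not gts:
        raise ValueError("AP is undefined without ground-truth boxes")
    flags = _match_flags(dets, gts, t, conf_threshold)
    grid = np.linspace(0.0, 1.0, n_points)
    if not flags:
        return APResult(0.0, np.array([]), np.array([]), np.zeros(n_points))
    is_tp = np.array([ok for _, ok in flags], dtype=np.float64)
    tp_cum = np.cumsum(is_tp)
    fp_cum = np.cumsum(1.0 - is_tp)
    recalls = tp_cum / len(gts)
    precisions = tp_cum / (tp_cum + fp_cum)
    # P_interp(r) = max precision at recall >= r
    interp = np.empty(n_points)
    run_max = np.maximum.accumulate(precisions[::-1])[::-1]
    for i, r in enumerate(grid):
        idx = np.searchsorted(recalls, r, side="left")
        interp[i] = run_max[idx] if idx < len(recalls) else 0.0
    return APResult(float(interp.mean()), recalls, precisions, interp)


def map_metric(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruthBox],
    thresholds: Sequence[float] = MAP_50_THRESHOLDS,
    n_points: int = 101,
    conf_threshold: Optional[float] = None,
) -> float:
    """Mean AP over IoU thresholds and over the classes present in the ground truth."""
    if not thresholds:
        raise ValueError("threshold set must be non-empty")
    labels = sorted({g.label for g in gts})
    if not labels:
        raise ValueError("mAP is undefined without ground-truth boxes")
    aps = []
    for t in thresholds:
        for lab in labels:
            aps.append(
                interpolated_ap(
                    [d for d in dets if d.label == lab],
                    [g for g in gts if g.label == lab],
                    t,
                    n_points,
                    conf_threshold,
                ).ap
            )
    return float(np.mean(aps))


# -- COCO-style JSON I/O -----------------------------------------------------

def load_coco_ground_truth(path) -> List[GroundTruthBox]:
    """Read ground truths from COCO-layout JSON (annotations with bbox [x, y, w, h])."""
    with open(path) as fh:
        raw = json.load(fh)
    return [
        GroundTruthBox(
            box=BoundingBox.from_xywh(*ann["bbox"]),
            label=int(ann.get("category_id", 0)),
            image_id=int(ann.get("image_id", 0)),
        )
        for ann in raw["annotations"]
    ]


def load_coco_detections(path) -> List[Detection]:
    """Read detections from COCO results JSON (list of {image_id, bbox, score, category_id})."""
    with open(path) as fh:
        raw = json.load(fh)
    return [
        Detection(
            box=BoundingBox.from_xywh(*d["bbox"]),
            confidence=float(d["score"]),
            label=int(d.get("category_id", 0)),
            image_id=int(d.get("image_id", 0)),
        )
        for d in raw
    ]


def write_coco_scene(
    path,
    gts: Sequence[GroundTruthBox],
    image_sizes: Dict[int, Tuple[int, int]],
) -> None:
    """Write ground truths as COCO-layout JSON (images + annotations)."""
    doc = {
        "images": [
            {"id": i, "width": w, "height": h} for i, (w, h) in sorted(image_sizes.items())
        ],
        "annotations": [
            {
                "id": k,
                "image_id": g.image_id,
                "category_id": g.label,
                "bbox": [g.box.xmin, g.box.ymin, g.box.xmax - g.box.xmin, g.box.ymax - g.box.ymin],
                "area": g.box.area,
                "iscrowd": 0,
            }
            for k, g in enumerate(gts)
        ],
        "categories": [{"id": lab, "name": f"class-{lab}"} for lab in sorted({g.label for g in gts})],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
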