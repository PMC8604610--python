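"""Detection-quality evaluation: Hit:Miss:False scoring and ROC analysis.

Predictions are matched one-to-one to annotated ground-truth boxes by
centroid: a prediction is eligible for a box when its centroid lies inside
the box or within ``max_match_dist`` of the box centre, and pairs are
accepted greedily by increasing distance.  A match with the correct label is
a hit; an unmatched box is a miss; an unmatched prediction — or a matched
but mislabelled one — is a false.  H, M and F are percentages of the total
event count (hits + misses + falses), so they sum to 100 before rounding.

The ROC analysis treats the detector as a binary classifier over the
evaluation region of each test image.  Events (TP = matched detection,
FP = unmatched detection, FN = unmatched box) are counted in 20x20-pixel
cell units and TN fills the remainder of the region's cell budget
(floor(width * height / cell^2) cells per image, 301 for the 1720x70
trackway band).  TPR = TP/(TP+FN) and FPR = FP/(FP+TN) per threshold value;
the empirical curve joins consecutive thresholds with straight lines and the
AUC is the trapezoidal area after anchoring (0,0) and (1,1).  The optimal
threshold maximises Youden's J = TPR - FPR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .classify import PAW_LABELS, ClassifiedFootfall, PawLabel
from .config import DetectionThresholds
from .detect import PawCluster, detect_paws
from .frames import FrameImage

__all__ = [
    "GroundTruthBox",
    "GroundTruthFrame",
    "MatchCounts",
    "HMFScore",
    "ROCPoint",
    "EvalRegion",
    "ConfusionMatrix",
    "match_detections",
    "score_run",
    "hmf_score",
    "roc_sweep",
    "roc_from_scores",
    "auc",
    "optimal_threshold",
    "confusion_matrix",
]


@dataclass(frozen=True)
class GroundTruthBox:
    label: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


@dataclass(frozen=True)
class GroundTruthFrame:
    frame_index: int
    boxes: tuple[GroundTruthBox, ...] = ()


@dataclass(frozen=True)
class MatchCounts:
    hits: int = 0
    misses: int = 0
    falses: int = 0

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(
            self.hits + other.hits,
            self.misses + other.misses,
            self.falses + other.falses,
        )

    @property
    def total(self) -> int:
        return self.hits + self.misses + self.falses


@dataclass(frozen=True)
class HMFScore:
    hit_pct: float
    miss_pct: float
    false_pct: float


@dataclass(frozen=True)
class ROCPoint:
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    tpr: float  # nan when TP+FN = 0
    fpr: float


@dataclass(frozen=True)
class EvalRegion:
    """The analysed band of each test image, counted in square cells."""

    width: int = 1720
    height: int = 70
    cell: int = 20

    @property
    def total_cells(self) -> int:
        return (self.width * self.height) // (self.cell * self.cell)


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # [[TP, FN], [FP, TN]]
    rates: np.ndarray  # row-normalised


def _prediction_tuple(pred) -> tuple[float, float, Optional[str]]:
    if isinstance(pred, ClassifiedFootfall):
        x, y = pred.cluster.centroid
        return (x, y, pred.label.value)
    if isinstance(pred, PawCluster):
        x, y = pred.centroid
        return (x, y, None)
    x, y = pred[0], pred[1]
    label = pred[2] if len(pred) > 2 else None
    if isinstance(label, PawLabel):
        label = label.value
    return (float(x), float(y), label)


def match_detections(
    predictions: Sequence,
    boxes: Sequence[GroundTruthBox],
    max_match_dist: float = 20.0,
) -> MatchCounts:
    """One-to-one greedy matching of one frame's predictions to its boxes.

    Predictions may be ClassifiedFootfall, PawCluster, or (x, y[, label])
    tuples; a ``None`` label means label-agnostic scoring (any match is a
    hit).  A matched prediction with a wrong label consumes the box and
    counts as false — the box is not additionally a miss.
    """
    preds = [_prediction_tuple(p) for p in predictions]
    candidates = []
    for i, (x, y, _lab) in enumerate(preds):
        for j, box in enumerate(boxes):
            cx, cy = box.center
            d = math.hypot(x - cx, y - cy)
            if box.contains(x, y) or d <= max_match_dist:
                candidates.append((d, i, j))
    candidates.sort()
    used_pred: set[int] = set()
    used_box: set[int] = set()
    hits = falses = 0
    for d, i, j in candidates:
        if i in used_pred or j in used_box:
            continue
        used_pred.add(i)
        used_box.add(j)
        label = preds[i][2]
        if label is None or label == boxes[j].label:
            hits += 1
        else:
            falses += 1
    falses += len(preds) - len(used_pred)
    misses = len(boxes) - len(used_box)
    return MatchCounts(hits, misses, falses)


def score_run(
    predictions_by_frame: dict[int, Sequence],
    truth: Sequence[GroundTruthFrame],
    max_match_dist: float = 20.0,
) -> MatchCounts:
    """Aggregate per-frame matching over a whole run."""
    truth_by_frame = {t.frame_index: t for t in truth}
    total = MatchCounts()
    frames = set(predictions_by_frame) | set(truth_by_frame)
    for f in sorted(frames):
        preds = predictions_by_frame.get(f, ())
        boxes = truth_by_frame.get(f, GroundTruthFrame(f)).boxes
        total = total + match_detections(preds, boxes, max_match_dist)
    return total


def hmf_score(counts: MatchCounts) -> HMFScore:
    """Percentages of hits, misses and falses over all scored events."""
    if counts.total == 0:
        raise ValueError("H:M:F undefined with zero events")
    t = counts.total
    return HMFScore(
        hit_pct=100.0 * counts.hits / t,
        miss_pct=100.0 * counts.misses / t,
        false_pct=100.0 * counts.falses / t,
    )


_THRESHOLD_FIELDS = (
    "green_threshold",
    "proximity_threshold",
    "min_cluster_size",
    "max_cluster_size",
)


def roc_sweep(
    frames: Sequence[FrameImage],
    truth: Sequence[GroundTruthFrame],
    variable: str,
    grid: Sequence[float],
    base_thresholds: DetectionThresholds,
    band: tuple[int, int],
    region: Optional[EvalRegion] = None,
    max_match_dist: float = 20.0,
) -> list[ROCPoint]:
    """Empirical ROC for one detection threshold over a test set.

    ``variable`` names one of the four DetectionThresholds fields; detection
    runs from scratch at every grid value with the other thresholds fixed.
    """
    if variable not in _THRESHOLD_FIELDS:
        raise ValueError(f"variable must be one of {_THRESHOLD_FIELDS}")
    grid = sorted(grid)
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    if region is None:
        band_height = band[1] - band[0]
        region = EvalRegion(width=frames[0].width, height=band_height)
    truth_by_frame = {t.frame_index: t for t in truth}
    total_cells = region.total_cells * len(frames)
    points = []
    for value in grid:
        if variable in ("green_threshold", "min_cluster_size", "max_cluster_size"):
            value_cast: float | int = int(value)
        else:
            value_cast = float(value)
        thr = replace(base_thresholds, **{variable: value_cast})
        counts = MatchCounts()
        for frame in frames:
            preds = [(c.centroid[0], c.centroid[1], None) for c in detect_paws(frame, thr, band)]
            boxes = truth_by_frame.get(frame.frame_index, GroundTruthFrame(frame.frame_index)).boxes
            counts = counts + match_detections(preds, boxes, max_match_dist)
        tp, fn, fp = counts.hits, counts.misses, counts.falses
        tn = max(total_cells - tp - fp - fn, 0)
        tpr = tp / (tp + fn) if (tp + fn) > 0 else math.nan
        fpr = fp / (fp + tn) if (fp + tn) > 0 else math.nan
        points.append(ROCPoint(float(value), tp, fp, fn, tn, tpr, fpr))
    return points


def roc_from_scores(
    positive_scores: Sequence[float],
    negative_scores: Sequence[float],
    thresholds: Optional[Sequence[float]] = None,
) -> list[ROCPoint]:
    """ROC points for a generic scored classifier (score >= t -> positive).

    Used for control experiments (for example, a detector fed pure-noise
    scores, whose curve should hug the chance diagonal).
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if thresholds is None:
        thresholds = np.unique(np.concatenate([pos, neg]))
    points = []
    p, n = len(pos), len(neg)
    for t in sorted(thresholds):
        tp = int(np.sum(pos >= t))
        fp = int(np.sum(neg >= t))
        points.append(
            ROCPoint(
                float(t), tp, fp, p - tp, n - fp,
                tp / p if p else math.nan,
                fp / n if n else math.nan,
            )
        )
    return points


def auc(points: Sequence[ROCPoint]) -> float:
    """Trapezoidal area under the (FPR, TPR) polyline.

    Points are sorted by FPR (then TPR) and the endpoints (0,0) and (1,1)
    are anchored, matching straight-line interpolation between consecutive
    thresholds.
    """
    coords = sorted(
        (p.fpr, p.tpr) for p in points if not (math.isnan(p.fpr) or math.isnan(p.tpr))
    )
    if not coords:
        raise ValueError("AUC needs at least one finite ROC point")
    xs = [0.0] + [c[0] for c in coords] + [1.0]
    ys = [0.0] + [c[1] for c in coords] + [1.0]
    return float(np.trapezoid(ys, xs))


def optimal_threshold(points: Sequence[ROCPoint]) -> tuple[float, ROCPoint]:
    """The grid value maximising Youden's J = TPR - FPR.

    Ties break toward smaller FPR, then smaller threshold.
    """
    finite = [p for p in points if not (math.isnan(p.fpr) or math.isnan(p.tpr))]
    if not finite:
        raise ValueError("no finite ROC point to choose from")
    best = min(finite, key=lambda p: (-(p.tpr - p.fpr), p.fpr, p.threshold))
    return best.threshold, best


def confusion_matrix(point: ROCPoint) -> ConfusionMatrix:
    """2x2 counts [[TP, FN], [FP, TN]] plus row-normalised rates."""
    counts = np.array([[point.tp, point.fn], [point.fp, point.tn]], dtype=np.int64)
    sums = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(sums > 0, counts / sums, np.nan)
    return ConfusionMatrix(counts=counts, rates=rates)
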