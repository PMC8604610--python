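"""Paw classification: label clusters in four-cluster frames, then propagate.

Frames containing exactly four clusters are the anchor: with the mouse
running left to right, the two clusters with the larger x centroids are the
front paws and, within each front/rear pair, the cluster with the smaller y
centroid is the right paw.  Labels then spread recursively to unlabelled
clusters in nearby frames whose centroid lies within a distance threshold of
an already-labelled cluster, until no new assignment is possible.  Clusters
that remain unlabelled (noses, tails, noise that survived the size filter)
are marked Unclassified and excluded from downstream gait analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .config import ClassificationConfig
from .detect import PawCluster

__all__ = [
    "PawLabel",
    "PAW_LABELS",
    "DIAGONAL_PAIRS",
    "ClassifiedFootfall",
    "group_by_frame",
    "classify_four_paw_frames",
    "propagate_labels",
    "classify_paws",
]

logger = logging.getLogger(__name__)


class PawLabel(str, Enum):
    LEFT_FRONT = "Left-Front"
    RIGHT_FRONT = "Right-Front"
    LEFT_REAR = "Left-Rear"
    RIGHT_REAR = "Right-Rear"
    UNCLASSIFIED = "Unclassified"


PAW_LABELS: tuple[PawLabel, ...] = (
    PawLabel.LEFT_FRONT,
    PawLabel.RIGHT_FRONT,
    PawLabel.LEFT_REAR,
    PawLabel.RIGHT_REAR,
)

DIAGONAL_PAIRS: tuple[tuple[PawLabel, PawLabel], ...] = (
    (PawLabel.LEFT_FRONT, PawLabel.RIGHT_REAR),
    (PawLabel.RIGHT_FRONT, PawLabel.LEFT_REAR),
)


@dataclass(eq=False)
class ClassifiedFootfall:
    """A detected cluster with its paw label (possibly Unclassified)."""

    cluster: PawCluster
    label: PawLabel

    @property
    def excluded(self) -> bool:
        """Unclassified footfalls are kept for diagnostics but excluded
        from gait-parameter extraction."""
        return self.label is PawLabel.UNCLASSIFIED

    @property
    def frame_index(self) -> int:
        return self.cluster.frame_index


def group_by_frame(clusters: Iterable[PawCluster]) -> dict[int, list[PawCluster]]:
    out: dict[int, list[PawCluster]] = {}
    for c in clusters:
        out.setdefault(c.frame_index, []).append(c)
    return out


def _four_paw_order(
    clusters: Sequence[PawCluster], right_to_left: bool
) -> dict[int, PawLabel]:
    """Label exactly four clusters by the x/y rule.

    Ties (measure-zero on real data) break by the other coordinate, then by
    cluster size descending.
    """
    xs = [c.centroid[0] for c in clusters]
    ys = [c.centroid[1] for c in clusters]
    sizes = [c.size for c in clusters]
    sx = 1.0 if right_to_left else -1.0  # front = larger x for left-to-right runs
    front_first = sorted(range(4), key=lambda i: (sx * xs[i], ys[i], -sizes[i]))
    front, rear = front_first[:2], front_first[2:]
    labels: dict[int, PawLabel] = {}
    for pair, (right_lab, left_lab) in (
        (front, (PawLabel.RIGHT_FRONT, PawLabel.LEFT_FRONT)),
        (rear, (PawLabel.RIGHT_REAR, PawLabel.LEFT_REAR)),
    ):
        sy = -1.0 if right_to_left else 1.0  # right = smaller y for left-to-right runs
        right, left = sorted(pair, key=lambda i: (sy * ys[i], sx * xs[i], -sizes[i]))
        labels[right] = right_lab
        labels[left] = left_lab
    return labels


def classify_four_paw_frames(
    clusters_by_frame: Mapping[int, Sequence[PawCluster]],
    right_to_left: bool = False,
) -> dict[tuple[int, int], PawLabel]:
    """Label the clusters of every frame holding exactly four clusters.

    Returns a partial labelling keyed by (frame_index, cluster position).
    Frames with any other cluster count are left untouched.
    """
    labels: dict[tuple[int, int], PawLabel] = {}
    for frame, clusters in clusters_by_frame.items():
        if len(clusters) != 4:
            continue
        for i, lab in _four_paw_order(clusters, right_to_left).items():
            labels[(frame, i)] = lab
    return labels


def _dist(a: tuple[float, float], b: tuple[float, float]) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def propagate_labels(
    clusters_by_frame: Mapping[int, Sequence[PawCluster]],
    labels: Mapping[tuple[int, int], PawLabel],
    cfg: ClassificationConfig,
) -> dict[tuple[int, int], PawLabel]:
    """Spread labels to nearby unlabelled clusters until fixpoint.

    Each pass assigns to every unlabelled cluster the label of the nearest
    labelled cluster within ``frame_window`` frames and
    ``propagation_distance`` pixels, skipping labels already present in the
    cluster's own frame.  Conflicts (two clusters of one frame claiming one
    label in the same pass) resolve nearest-first — ties by earlier source
    frame, then centroid — with the loser deferred to a later pass; the
    resolution depends only on geometry, never on input ordering.  Clusters
    still unlabelled at fixpoint become Unclassified.
    """
    cfg.validate()
    labels = dict(labels)
    frames = sorted(clusters_by_frame)
    centroids = {
        (f, i): c.centroid
        for f in frames
        for i, c in enumerate(clusters_by_frame[f])
    }
    frame_labels: dict[int, set[PawLabel]] = {f: set() for f in frames}
    for (f, _i), lab in labels.items():
        frame_labels[f].add(lab)

    while True:
        tentative: list[tuple[float, int, tuple[float, float], tuple[int, int], PawLabel]] = []
        for f in frames:
            for i in range(len(clusters_by_frame[f])):
                key = (f, i)
                if key in labels:
                    continue
                here = centroids[key]
                best = None
                for f2 in range(f - cfg.frame_window, f + cfg.frame_window + 1):
                    if f2 not in clusters_by_frame:
                        continue
                    for j in range(len(clusters_by_frame[(f2)])):
                        lab = labels.get((f2, j))
                        if lab is None or lab is PawLabel.UNCLASSIFIED:
                            continue
                        if lab in frame_labels[f]:
                            continue
                        d = _dist(here, centroids[(f2, j)])
                        if d > cfg.propagation_distance:
                            continue
                        cand = (d, f2, centroids[(f2, j)], key, lab)
                        if best is None or cand[:3] < best[:3]:
                            best = cand
                if best is not None:
                    tentative.append(best)
        if not tentative:
            break
        assigned = 0
        for d, src_f, _src_c, key, lab in sorted(tentative, key=lambda t: (t[0], t[1], t[2], t[3])):
            f, _i = key
            if key in labels:
                continue
            if lab in frame_labels[f]:
                logger.warning(
                    "frame %d: cluster at %s lost label %s to a nearer candidate",
                    f, centroids[key], lab.value,
                )
                continue
            labels[key] = lab
            frame_labels[f].add(lab)
            assigned += 1
        if assigned == 0:
            break

    for f in frames:
        for i in range(len(clusters_by_frame[f])):
            labels.setdefault((f, i), PawLabel.UNCLASSIFIED)
    return labels


def classify_paws(
    clusters_by_frame: Mapping[int, Sequence[PawCluster]],
    cfg: ClassificationConfig,
) -> list[ClassifiedFootfall]:
    """Full classification: four-paw anchor frames, then propagation.

    Returns one ClassifiedFootfall per detected cluster, ordered by frame
    and within-frame detection order.  Emits a warning when no frame holds
    exactly four clusters (everything then stays Unclassified).
    """
    cfg.validate()
    seed = classify_four_paw_frames(clusters_by_frame, cfg.right_to_left)
    if not seed and any(clusters_by_frame.values()):
        logger.warning(
            "no four-cluster frame found in the run; all clusters remain Unclassified"
        )
    labels = propagate_labels(clusters_by_frame, seed, cfg)
    out: list[ClassifiedFootfall] = []
    for f in sorted(clusters_by_frame):
        for i, cluster in enumerate(clusters_by_frame[f]):
            out.append(ClassifiedFootfall(cluster, labels[(f, i)]))
    return out
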