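"""Footfall detection: green thresholding, proximity clustering, size filter.

The illuminated trackway makes paw contacts bright green against a dark red
background, so detection reduces to (1) keeping pixels whose G value clears a
threshold inside the analysis band, (2) grouping nearby pixels into clusters
so the digits join the palm, and (3) discarding clusters whose pixel count is
implausibly small (specks, dust) or large (tail or nose streaks).

Clustering is single-linkage: two pixels belong to the same cluster whenever
they are connected by a chain of pixel pairs each within the proximity
threshold (Euclidean, inclusive).  For small integer thresholds this is a
connected-component sweep over a precomputed neighbourhood-offset stencil;
for general thresholds it falls back to a KD-tree pair query plus union-find.
Both paths return identical partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .config import DetectionThresholds
from .frames import FrameImage

__all__ = [
    "PawCluster",
    "threshold_green",
    "proximity_cluster",
    "filter_cluster_size",
    "compute_centroid",
    "detect_paws",
]

# Offset stencils stay small up to this threshold; beyond it the KD-tree
# path is cheaper.
_STENCIL_MAX_THRESHOLD = 3.0


@dataclass(eq=False)
class PawCluster:
    """A detected connected group of bright-green pixels in one frame.

    ``coords`` holds (x, y) integer pixel coordinates, x = column along the
    trackway, y = row across it, origin top-left, 0-based.  ``g_values`` are
    the corresponding G-channel intensities.
    """

    frame_index: int
    coords: np.ndarray  # (N, 2) int, columns (x, y)
    g_values: np.ndarray  # (N,) uint8

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 1:
            raise ValueError("cluster needs a non-empty (N, 2) coordinate array")
        g = np.asarray(self.g_values)
        if g.shape != (coords.shape[0],):
            raise ValueError("g_values must align with coords")
        self.coords = coords
        self.g_values = g

    @property
    def size(self) -> int:
        return int(self.coords.shape[0])

    @property
    def centroid(self) -> tuple[float, float]:
        cx, cy = compute_centroid(self.coords)
        return (cx, cy)

    @property
    def bounding_box(self) -> tuple[int, int, int, int]:
        """(x_min, y_min, x_max, y_max), inclusive."""
        mn = self.coords.min(axis=0)
        mx = self.coords.max(axis=0)
        return (int(mn[0]), int(mn[1]), int(mx[0]), int(mx[1]))

    @property
    def mean_g(self) -> float:
        return float(np.mean(self.g_values))


def threshold_green(
    img: FrameImage, green_threshold: int, band: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Pixels inside the row band with G >= green_threshold.

    Returns (coords, g_values) with coords as (N, 2) int (x, y) pairs.
    Raising the threshold never increases the number of returned pixels.
    """
    y0, y1 = band
    if not (0 <= y0 < y1 <= img.height):
        raise ValueError(f"band [{y0}, {y1}) empty or outside image of height {img.height}")
    g = img.pixels[y0:y1, :, 1]
    rows, cols = np.nonzero(g >= green_threshold)
    coords = np.column_stack([cols, rows + y0]).astype(np.int64)
    return coords, g[rows, cols].copy()


def _stencil_components(coords: np.ndarray, threshold: float) -> list[np.ndarray]:
    t2 = threshold * threshold
    tmax = int(np.floor(threshold))
    offsets = [
        (dx, dy)
        for dx in range(-tmax, tmax + 1)
        for dy in range(-tmax, tmax + 1)
        if 0 < dx * dx + dy * dy <= t2
    ]
    index = {(int(x), int(y)): i for i, (x, y) in enumerate(coords)}
    n = coords.shape[0]
    visited = np.zeros(n, dtype=bool)
    comps: list[np.ndarray] = []
    for i in range(n):
        if visited[i]:
            continue
        stack = [i]
        visited[i] = True
        member: list[int] = []
        while stack:
            j = stack.pop()
            member.append(j)
            x, y = int(coords[j, 0]), int(coords[j, 1])
            for dx, dy in offsets:
                k = index.get((x + dx, y + dy))
                if k is not None and not visited[k]:
                    visited[k] = True
                    stack.append(k)
        comps.append(np.array(sorted(member), dtype=np.intp))
    return comps


def _kdtree_components(coords: np.ndarray, threshold: float) -> list[np.ndarray]:
    n = coords.shape[0]
    tree = cKDTree(coords.astype(np.float64))
    pairs = tree.query_pairs(r=threshold, output_type="ndarray")
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    comps: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        comps.setdefault(int(lab), []).append(i)
    ordered = sorted(comps.values(), key=lambda m: m[0])
    return [np.array(m, dtype=np.intp) for m in ordered]


def proximity_cluster(coords: np.ndarray, proximity_threshold: float) -> list[np.ndarray]:
    """Partition pixel coordinates into single-linkage proximity clusters.

    Returns index arrays into ``coords``; every input index appears in
    exactly one cluster.  Clusters are ordered by their smallest input index
    and indices within a cluster ascend, so the result is independent of the
    traversal path.
    """
    if proximity_threshold <= 0:
        raise ValueError("proximity_threshold must be > 0")
    coords = np.asarray(coords)
    if coords.size == 0:
        return []
    coords = coords.reshape(-1, 2)
    integral = np.issubdtype(coords.dtype, np.integer) or np.all(coords == np.round(coords))
    if integral and proximity_threshold <= _STENCIL_MAX_THRESHOLD:
        return _stencil_components(np.asarray(coords, dtype=np.int64), proximity_threshold)
    return _kdtree_components(coords, proximity_threshold)


def filter_cluster_size(
    clusters: list[PawCluster], min_cluster_size: int, max_cluster_size: int
) -> list[PawCluster]:
    """Keep clusters with min <= size <= max (inclusive); order preserved."""
    if not 0 < min_cluster_size <= max_cluster_size:
        raise ValueError("cluster size bounds must satisfy 0 < min <= max")
    return [c for c in clusters if min_cluster_size <= c.size <= max_cluster_size]


def compute_centroid(coords: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean of pixel coordinates: C = (1/N) * sum(p_i)."""
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 2)
    if coords.shape[0] < 1:
        raise ValueError("cannot take the centroid of an empty cluster")
    mean = coords.mean(axis=0)
    return (float(mean[0]), float(mean[1]))


def detect_paws(
    img: FrameImage, thresholds: DetectionThresholds, band: tuple[int, int]
) -> list[PawCluster]:
    """Full single-frame detection: threshold, cluster, size-filter.

    Returns surviving clusters sorted by centroid x descending (stable), so
    the leading paws come first.
    """
    thresholds.validate()
    coords, g_values = threshold_green(img, thresholds.green_threshold, band)
    if coords.shape[0] == 0:
        return []
    groups = proximity_cluster(coords, thresholds.proximity_threshold)
    clusters = [
        PawCluster(img.frame_index, coords[idx], g_values[idx]) for idx in groups
    ]
    clusters = filter_cluster_size(
        clusters, thresholds.min_cluster_size, thresholds.max_cluster_size
    )
    order = sorted(range(len(clusters)), key=lambda i: -clusters[i].centroid[0])
    return [clusters[i] for i in order]
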