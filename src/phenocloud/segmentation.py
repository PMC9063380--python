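"""Euclidean-distance organ segmentation.

Two points are adjacent when their distance is strictly below the radius
threshold r_th; clusters are the connected components of that adjacency
graph, so any two points in different clusters are at least r_th apart.
r_th itself is chosen by a stability scan: the cluster count is recorded on
a geometric grid of candidate radii and the widest plateau of constant
count wins — below the plateau individual organs are still fragmented,
above it distinct organs begin to merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import PhenoCloudError
from .io import UP, PointCloud

DEFAULT_MIN_CLUSTER_SIZE = 30


@dataclass
class Cluster:
    """Member indices (into the parent cloud) of one segment."""

    indices: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.intp)
        if self.indices.size == 0:
            raise ValueError("a cluster cannot be empty")

    @property
    def size(self) -> int:
        return int(self.indices.size)

    def points(self, pc: PointCloud) -> np.ndarray:
        return pc.points[self.indices]


@dataclass
class SegmentationResult:
    clusters: list[Cluster]
    r_th: float
    residual_indices: np.ndarray


@dataclass
class SegmentedPlant:
    """Organ-level labelling: one stem, leaves ordered by attachment height."""

    stem: Cluster
    leaves: list[Cluster]
    residual_indices: np.ndarray
    cloud: PointCloud
    warnings: list[str] = field(default_factory=list)

    def labels(self) -> np.ndarray:
        """Per-point labels: 0 = stem, 1..k = leaves, -1 = residual."""
        out = np.full(len(self.cloud), -1, dtype=np.int32)
        out[self.stem.indices] = 0
        for i, leaf in enumerate(self.leaves, start=1):
            out[leaf.indices] = i
        return out


def _strict_pairs(points: np.ndarray, r_th: float):
    """Index pairs with pairwise distance strictly below r_th."""
    tree = cKDTree(points)
    pairs = tree.query_pairs(r_th, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]], axis=1)
        pairs = pairs[d < r_th]
    return pairs


def _component_labels(n: int, pairs: np.ndarray) -> np.ndarray:
    if len(pairs) == 0:
        return np.arange(n)
    graph = coo_matrix(
        (np.ones(len(pairs), dtype=np.int8), (pairs[:, 0], pairs[:, 1])),
        shape=(n, n),
    )
    _, labels = connected_components(graph, directed=False)
    return labels


def _partition(n: int, labels: np.ndarray, min_cluster_size: int, r_th: float
               ) -> SegmentationResult:
    order = np.argsort(labels, kind="stable")
    boundaries = np.flatnonzero(np.diff(labels[order])) + 1
    groups = np.split(order, boundaries)
    # deterministic ordering: by smallest member index
    groups.sort(key=lambda g: int(g.min()))
    clusters, residual = [], []
    for g in groups:
        g = np.sort(g)
        if g.size >= min_cluster_size:
            clusters.append(Cluster(g))
        else:
            residual.append(g)
    residual_idx = (np.sort(np.concatenate(residual)) if residual
                    else np.empty(0, dtype=np.intp))
    return SegmentationResult(clusters, float(r_th), residual_idx)


def euclidean_cluster(pc: PointCloud, r_th: float,
                      min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
                      ) -> SegmentationResult:
    """Cluster by strict-threshold connectivity (hops < r_th).

    Clusters smaller than ``min_cluster_size`` are moved to the residual
    set (noise fragments, stray reconstruction artefacts).
    """
    if len(pc) == 0:
        raise PhenoCloudError("cannot cluster an empty cloud")
    if r_th <= 0:
        raise ValueError("r_th must be positive")
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    labels = _component_labels(len(pc), _strict_pairs(pc.points, r_th))
    return _partition(len(pc), labels, min_cluster_size, r_th)


def default_radius_grid(pc: PointCloud, n_candidates: int = 25
                        ) -> np.ndarray:
    """Geometric grid from 0.5x to 20x the median nearest-neighbour distance."""
    tree = cKDTree(pc.points)
    d, _ = tree.query(pc.points, k=2, workers=-1)
    med = float(np.median(d[:, 1]))
    if med <= 0:
        med = 1e-6
    return np.geomspace(0.5 * med, 20.0 * med, n_candidates)


def scan_cluster_counts(pc: PointCloud, r_grid: np.ndarray,
                        min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
                        ) -> np.ndarray:
    """Cluster count (size >= min_cluster_size) at each candidate radius.

    The neighbour pairs are computed once at the largest radius and
    re-filtered per candidate, which matches clustering each radius from
    scratch because the strict-threshold graph at r is exactly the pairs
    with distance < r.
    """
    r_grid = np.asarray(r_grid, dtype=np.float64)
    tree = cKDTree(pc.points)
    pairs = tree.query_pairs(float(r_grid[-1]), output_type="ndarray")
    if len(pairs):
        dist = np.linalg.norm(
            pc.points[pairs[:, 0]] - pc.points[pairs[:, 1]], axis=1
        )
    else:
        dist = np.empty(0)
    counts = np.empty(len(r_grid), dtype=np.int64)
    for i, r in enumerate(r_grid):
        sub = pairs[dist < r] if len(pairs) else pairs
        labels = _component_labels(len(pc), sub)
        sizes = np.bincount(labels)
        counts[i] = int((sizes >= min_cluster_size).sum())
    return counts


def select_radius(pc: PointCloud, r_grid=None,
                  min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE) -> float:
    """Pick r_th as the smallest radius of the widest cluster-count plateau.

    Ties between equally long plateaus go to the one at smaller radius.
    """
    if len(pc) == 0:
        raise PhenoCloudError("cannot select a radius for an empty cloud")
    if r_grid is None:
        r_grid = default_radius_grid(pc)
    r_grid = np.asarray(r_grid, dtype=np.float64)
    if r_grid.size == 0:
        raise ValueError("empty radius grid")
    if np.any(r_grid <= 0) or np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be strictly increasing and positive")
    counts = scan_cluster_counts(pc, r_grid, min_cluster_size)
    # zero-count plateaus (everything below min_cluster_size) are not a
    # usable segmentation and never win the stability scan
    best_start, best_len = -1, 0
    start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[start]:
            if counts[start] > 0 and i - start > best_len:
                best_start, best_len = start, i - start
            start = i
    if best_start < 0:
        raise PhenoCloudError(
            "no candidate radius produced a cluster of minimum size"
        )
    return float(r_grid[best_start])


def _linearity(points: np.ndarray) -> float:
    """(lam1 - lam2) / lam1 from the covariance eigenvalues, in [0, 1]."""
    if len(points) < 3:
        return 0.0
    cov = np.cov(points.T)
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    if lam[0] <= 0:
        return 0.0
    return float((lam[0] - lam[1]) / lam[0])


def classify_organs(seg: SegmentationResult, pc: PointCloud,
                    up: np.ndarray = UP) -> SegmentedPlant:
    """Label one cluster as stem, the rest as leaves.

    The stem is the cluster maximising linearity x vertical extent: stems
    are elongated and broadly aligned with gravity, while leaf blades are
    planar.  Leaves are ordered bottom-to-top by the height of their point
    closest to the stem (their attachment).
    """
    if not seg.clusters:
        raise PhenoCloudError("segmentation produced no clusters")
    up = np.asarray(up, dtype=np.float64)
    up = up / np.linalg.norm(up)
    scores = []
    for cl in seg.clusters:
        pts = cl.points(pc)
        heights = pts @ up
        scores.append(_linearity(pts) * float(heights.max() - heights.min()))
    stem_idx = int(np.argmax(scores))
    stem = seg.clusters[stem_idx]
    leaves = [cl for i, cl in enumerate(seg.clusters) if i != stem_idx]

    warnings: list[str] = []
    if not leaves:
        warnings.append("single cluster: stem assigned, no leaves found")
    else:
        stem_tree = cKDTree(stem.points(pc))
        attach_heights = []
        for leaf in leaves:
            pts = leaf.points(pc)
            d, _ = stem_tree.query(pts, k=1)
            nearest = pts[int(np.argmin(d))]
            attach_heights.append(float(nearest @ up))
        order = np.argsort(attach_heights, kind="stable")
        leaves = [leaves[i] for i in order]
    return SegmentedPlant(stem, leaves, seg.residual_indices, pc, warnings)


def segment_plant(pc: PointCloud, r_th: float | None = None,
                  min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
                  r_grid=None, up: np.ndarray = UP
                  ) -> tuple[SegmentedPlant, float]:
    """Radius selection + clustering + organ labelling in one call."""
    if r_th is None:
        r_th = select_radius(pc, r_grid, min_cluster_size)
    seg = euclidean_cluster(pc, r_th, min_cluster_size)
    return classify_organs(seg, pc, up), float(r_th)
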