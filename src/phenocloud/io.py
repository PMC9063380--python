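"""Point-cloud container, file IO and photogrammetry pre-processing.

Coordinates are metric centimetres in a right-handed, z-up frame (gravity
along -z).  Structure-from-motion output has arbitrary scale, so calibration
to centimetres is the caller's responsibility (the CLI exposes ``--scale``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import _ply
from .errors import LoadError, PhenoCloudError

UP = np.array([0.0, 0.0, 1.0])


@dataclass
class PointCloud:
    """An ordered set of 3D points (cm) with optional per-point RGB colors."""

    points: np.ndarray
    colors: np.ndarray | None = None
    source: str | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if self.colors is not None:
            self.colors = np.atleast_2d(np.asarray(self.colors, dtype=np.uint8))
            if self.colors.shape != self.points.shape:
                raise ValueError("colors must match points one-to-one")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box as (min corner, max corner)."""
        return self.points.min(axis=0), self.points.max(axis=0)

    def select(self, indices) -> "PointCloud":
        """Sub-cloud at ``indices`` (order preserved)."""
        indices = np.asarray(indices)
        return PointCloud(
            self.points[indices],
            None if self.colors is None else self.colors[indices],
            self.source,
        )

    def transformed(self, rotation=None, translation=None,
                    scale: float = 1.0) -> "PointCloud":
        pts = self.points * scale
        if rotation is not None:
            pts = pts @ np.asarray(rotation, dtype=np.float64).T
        if translation is not None:
            pts = pts + np.asarray(translation, dtype=np.float64)
        return PointCloud(pts, self.colors, self.source)


def _check_finite(points: np.ndarray, path: str) -> None:
    bad = ~np.isfinite(points).all(axis=1)
    if bad.any():
        first = int(np.flatnonzero(bad)[0])
        raise LoadError(f"{path}: non-finite coordinate at record {first}")


def read_point_cloud(path, format: str = "auto") -> PointCloud:
    """Read a PLY (ascii / binary little-endian) or XYZ text point cloud."""
    path = Path(path)
    if not path.is_file():
        raise LoadError(f"no such file: {path}")
    if format == "auto":
        format = "ply" if path.suffix.lower() == ".ply" else "xyz"
    if format == "ply":
        vertex = _ply.read_ply(path)
        points = np.column_stack(
            [vertex["x"], vertex["y"], vertex["z"]]
        ).astype(np.float64)
        colors = None
        if all(c in vertex for c in ("red", "green", "blue")):
            colors = np.column_stack(
                [vertex["red"], vertex["green"], vertex["blue"]]
            ).astype(np.uint8)
    elif format == "xyz":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.strip()
                if not stripped or stripped.startswith("#"):
                    continue
                tokens = stripped.split()
                if len(tokens) < 3:
                    raise LoadError(f"{path}: line {lineno}: fewer than 3 columns")
                try:
                    rows.append([float(t) for t in tokens[:3]])
                except ValueError as exc:
                    raise LoadError(f"{path}: line {lineno}: {exc}") from exc
        if not rows:
            raise LoadError(f"{path}: no points")
        points = np.asarray(rows, dtype=np.float64)
        colors = None
    else:
        raise ValueError(f"unknown format {format!r}")
    if points.shape[0] < 1:
        raise LoadError(f"{path}: no points")
    _check_finite(points, str(path))
    return PointCloud(points, colors, source=str(path))


def write_point_cloud(pc: PointCloud, path, format: str = "ply_ascii",
                      labels=None) -> None:
    """Write a cloud as ``ply_ascii``, ``ply_binary`` or ``xyz``.

    ``labels`` (per-point integers, e.g. organ labels) are stored as an
    extra int32 PLY property; the xyz format keeps only coordinates.
    """
    if len(pc) == 0:
        raise PhenoCloudError("refusing to write an empty cloud")
    path = Path(path)
    if format in ("ply_ascii", "ply_binary"):
        _ply.write_ply(path, pc.points, colors=pc.colors, labels=labels,
                       binary=(format == "ply_binary"))
    elif format == "xyz":
        with open(path, "w") as fh:
            for p in pc.points:
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def mean_knn_distance(points: np.ndarray, k: int) -> np.ndarray:
    """Per-point mean Euclidean distance to the k nearest neighbours."""
    tree = cKDTree(points)
    # first column of the query is the point itself (distance 0)
    dists, _ = tree.query(points, k=k + 1, workers=-1)
    return dists[:, 1:].mean(axis=1)


def statistical_outlier_removal(pc: PointCloud, k: int = 16,
                                std_ratio: float = 2.0) -> PointCloud:
    """Drop points whose mean k-NN distance exceeds mean + std_ratio * std.

    The threshold statistics are global over the cloud; survivor order is
    preserved.  Standard filter for photogrammetric clouds, whose sparse
    reconstruction artefacts sit far from any surface.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if std_ratio <= 0:
        raise ValueError("std_ratio must be positive")
    if len(pc) <= k:
        raise PhenoCloudError(
            f"cannot form {k}-neighbourhoods with only {len(pc)} points"
        )
    stat = mean_knn_distance(pc.points, k)
    keep = stat <= stat.mean() + std_ratio * stat.std()
    return pc.select(np.flatnonzero(keep))


def _fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points; returns (unit normal, centroid)."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    return vt[2], centroid


def remove_ground_plane(pc: PointCloud, distance_threshold: float = 0.2,
                        min_inlier_fraction: float = 0.15,
                        max_tilt_deg: float = 30.0, n_iterations: int = 250,
                        seed: int = 0) -> PointCloud:
    """RANSAC removal of a dominant near-horizontal plane (soil/ground).

    The plane is removed only if its inlier fraction reaches
    ``min_inlier_fraction`` *and* its normal is within ``max_tilt_deg`` of
    vertical; otherwise the cloud is returned unchanged, so plant-only
    clouds pass through untouched.
    """
    if distance_threshold <= 0 or min_inlier_fraction <= 0:
        raise ValueError("thresholds must be positive")
    if len(pc) < 3:
        raise PhenoCloudError("need at least 3 points to fit a plane")
    rng = np.random.default_rng(seed)
    pts = pc.points
    best_count, best_inliers = 0, None
    for _ in range(n_iterations):
        idx = rng.choice(len(pts), size=3, replace=False)
        a, b, c = pts[idx]
        normal = np.cross(b - a, c - a)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue
        normal /= norm
        dist = np.abs((pts - a) @ normal)
        inliers = dist <= distance_threshold
        count = int(inliers.sum())
        if count > best_count:
            best_count, best_inliers = count, inliers
    if best_inliers is None or best_count < 3:
        return pc
    # refine on the consensus set, then re-select inliers once
    normal, centroid = _fit_plane(pts[best_inliers])
    dist = np.abs((pts - centroid) @ normal)
    inliers = dist <= distance_threshold
    frac = inliers.mean()
    tilt = np.degrees(np.arccos(min(1.0, abs(float(normal @ UP)))))
    if frac < min_inlier_fraction or tilt > max_tilt_deg:
        return pc
    return pc.select(np.flatnonzero(~inliers))


def voxel_downsample(pc: PointCloud, voxel_size: float) -> PointCloud:
    """One centroid per occupied voxel; grid anchored at the min corner."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    origin = pc.points.min(axis=0)
    keys = np.floor((pc.points - origin) / voxel_size).astype(np.int64)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    sums = np.zeros((len(uniq), 3))
    np.add.at(sums, inverse, pc.points)
    counts = np.bincount(inverse, minlength=len(uniq)).astype(np.float64)
    centroids = sums / counts[:, None]
    colors = None
    if pc.colors is not None:
        csum = np.zeros((len(uniq), 3))
        np.add.at(csum, inverse, pc.colors.astype(np.float64))
        colors = np.clip(np.rint(csum / counts[:, None]), 0, 255).astype(np.uint8)
    return PointCloud(centroids, colors, pc.source)
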