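"""Organ trait measurement: leaf length, leaf width, stem height, leaf count.

Leaf length is measured along the midrib rather than as the apex-stipule
chord, so curled leaves are not underestimated: the midrib is approximated
by a polyline through the apex, the stipule, and (by default) five internal
points, and the length is the sum of the segment lengths.  Leaf width is
the widest band across the leaf perpendicular to the apex-stipule axis;
the leaf is split into 25 equidistant bands along that axis and the width
is the largest 3D distance between the two lateral extremes of any band.
Stem height is a two-chord polyline through a bottom, middle and top stem
point, which tracks curved stems better than a single vertical extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import cdist

from .errors import MeasurementError, PhenoCloudError
from .io import UP
from .segmentation import SegmentedPlant

MIN_LEAF_POINTS = 5


@dataclass
class LeafTraits:
    """Measured landmarks and dimensions of a single leaf (cm)."""

    apex: np.ndarray
    stipule: np.ndarray
    midrib_polyline: np.ndarray          # (n_internal + 2, 3), stipule -> apex
    length: float
    width: float
    width_endpoints: tuple[np.ndarray, np.ndarray]   # (L_P, R_P)
    band_index: int
    leaf_index: int = 0

    def to_dict(self) -> dict:
        return {
            "leaf_index": self.leaf_index,
            "apex": self.apex.tolist(),
            "stipule": self.stipule.tolist(),
            "midrib_polyline": self.midrib_polyline.tolist(),
            "length_cm": self.length,
            "width_cm": self.width,
            "width_left": self.width_endpoints[0].tolist(),
            "width_right": self.width_endpoints[1].tolist(),
            "band_index": self.band_index,
        }


@dataclass
class PlantTraits:
    """Whole-plant trait report."""

    stem_height: float
    stem_points: np.ndarray              # (3, 3): bottom, middle, top
    n_leaves: int
    leaves: list[LeafTraits]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stem_height_cm": self.stem_height,
            "stem_points": self.stem_points.tolist(),
            "n_leaves": self.n_leaves,
            "leaves": [leaf.to_dict() for leaf in self.leaves],
            "warnings": list(self.warnings),
        }


def _diameter_pair(points: np.ndarray) -> tuple[int, int]:
    """Indices of the maximum-distance point pair (exact).

    Uses the convex hull to prune when the set is large; ties are broken
    by the lowest index pair, which keeps results stable under reordering.
    """
    n = len(points)
    candidates = np.arange(n)
    if n > 400:
        try:
            hull = ConvexHull(points)
            candidates = np.sort(hull.vertices)
        except QhullError:
            pass  # degenerate (flat/collinear) set: brute-force below
    sub = points[candidates]
    d = cdist(sub, sub)
    i, j = np.unravel_index(int(np.argmax(d)), d.shape)
    if i > j:
        i, j = j, i
    return int(candidates[i]), int(candidates[j])


def find_apex_stipule(leaf_points: np.ndarray, stem_points: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Locate the leaf tip and its attachment end.

    The pair is the leaf's farthest point pair; whichever member lies
    closer to the stem is the stipule, the other the apex.
    """
    leaf_points = np.asarray(leaf_points, dtype=np.float64)
    if len(leaf_points) < MIN_LEAF_POINTS:
        raise MeasurementError(
            f"leaf has {len(leaf_points)} points; need >= {MIN_LEAF_POINTS}"
        )
    i, j = _diameter_pair(leaf_points)
    p, q = leaf_points[i], leaf_points[j]
    stem_tree = cKDTree(np.asarray(stem_points, dtype=np.float64))
    dp, _ = stem_tree.query(p)
    dq, _ = stem_tree.query(q)
    return (q, p) if dp <= dq else (p, q)


def midrib_polyline(leaf_points: np.ndarray, apex: np.ndarray,
                    stipule: np.ndarray, n_internal: int = 5) -> np.ndarray:
    """Midrib approximation [stipule, p_1..p_n, apex].

    Leaf points are projected onto the apex-stipule axis; the projection
    range is split into ``n_internal + 1`` equal intervals and each internal
    polyline point is the centroid of the points falling in a slab (half an
    interval wide) around the interval boundary.  An empty slab falls back
    to the single point nearest the boundary plane.  The slab centroid sits
    on the midrib for a laterally symmetric lamina, so the construction is
    robust to sampling noise and reduces to the chord for flat leaves.
    """
    apex = np.asarray(apex, dtype=np.float64)
    stipule = np.asarray(stipule, dtype=np.float64)
    chord = apex - stipule
    chord_len = np.linalg.norm(chord)
    if chord_len < 1e-12:
        raise MeasurementError("apex and stipule coincide")
    if n_internal < 0:
        raise ValueError("n_internal must be >= 0")
    if n_internal == 0:
        return np.vstack([stipule, apex])
    u = chord / chord_len
    t = (np.asarray(leaf_points, dtype=np.float64) - stipule) @ u
    h = chord_len / (n_internal + 1)
    internal = []
    for i in range(1, n_internal + 1):
        center = i * h
        in_slab = np.abs(t - center) <= h / 4.0
        if in_slab.any():
            internal.append(leaf_points[in_slab].mean(axis=0))
        else:
            internal.append(leaf_points[int(np.argmin(np.abs(t - center)))])
    internal = np.asarray(internal)
    order = np.argsort((internal - stipule) @ u, kind="stable")
    return np.vstack([stipule, internal[order], apex])


def leaf_length(polyline: np.ndarray) -> float:
    """Sum of segment lengths of the midrib polyline (cm)."""
    polyline = np.asarray(polyline, dtype=np.float64)
    if polyline.ndim != 2 or len(polyline) < 2:
        raise MeasurementError("polyline needs at least 2 points")
    return float(np.linalg.norm(np.diff(polyline, axis=0), axis=1).sum())


@dataclass
class WidthResult:
    width: float
    left: np.ndarray
    right: np.ndarray
    band_index: int
    empty_band_fraction: float
    degenerate: bool = False


def _cross_axis(points: np.ndarray, e1: np.ndarray) -> np.ndarray | None:
    """Second principal direction orthogonalised against e1."""
    centered = points - points.mean(axis=0)
    cov = np.cov(centered.T)
    lam, vec = np.linalg.eigh(cov)
    # descending eigenvalue order; try PC2 then PC3
    for k in (1, 2):
        cand = vec[:, np.argsort(lam)[::-1][k]]
        cand = cand - (cand @ e1) * e1
        norm = np.linalg.norm(cand)
        if norm > 1e-8:
            return cand / norm
    return None


def leaf_width(leaf_points: np.ndarray, apex: np.ndarray, stipule: np.ndarray,
               n_bands: int = 25) -> WidthResult:
    """Maximum band width across the leaf (cm).

    Points are binned into ``n_bands`` equal intervals of projection onto
    the apex-stipule axis; per band the extreme points along the leaf's
    cross axis are L_P and R_P and the band width is their 3D distance.
    Empty bands are skipped; the result is the maximum over populated bands.
    """
    leaf_points = np.asarray(leaf_points, dtype=np.float64)
    if len(leaf_points) < MIN_LEAF_POINTS:
        raise MeasurementError(
            f"leaf has {len(leaf_points)} points; need >= {MIN_LEAF_POINTS}"
        )
    apex = np.asarray(apex, dtype=np.float64)
    stipule = np.asarray(stipule, dtype=np.float64)
    chord = apex - stipule
    chord_len = np.linalg.norm(chord)
    if chord_len < 1e-12:
        raise MeasurementError("apex and stipule coincide")
    e1 = chord / chord_len
    e2 = _cross_axis(leaf_points, e1)
    if e2 is None:
        zero = leaf_points[0]
        return WidthResult(0.0, zero, zero, 0, 1.0, degenerate=True)
    t = (leaf_points - stipule) @ e1
    lo, hi = float(t.min()), float(t.max())
    span = hi - lo
    if span <= 0:
        zero = leaf_points[0]
        return WidthResult(0.0, zero, zero, 0, 1.0, degenerate=True)
    band = np.minimum(((t - lo) / span * n_bands).astype(np.intp), n_bands - 1)
    s = leaf_points @ e2
    best = WidthResult(-1.0, leaf_points[0], leaf_points[0], -1, 0.0)
    n_empty = 0
    for b in range(n_bands):
        members = np.flatnonzero(band == b)
        if members.size == 0:
            n_empty += 1
            continue
        left = members[int(np.argmin(s[members]))]
        right = members[int(np.argmax(s[members]))]
        w = float(np.linalg.norm(leaf_points[left] - leaf_points[right]))
        if w > best.width:
            best = WidthResult(w, leaf_points[left], leaf_points[right], b, 0.0)
    best.empty_band_fraction = n_empty / n_bands
    if best.width <= 1e-12:
        best.width = 0.0
        best.degenerate = True
    return best


def stem_height(stem_points: np.ndarray, top_attachment: np.ndarray | None = None,
                up: np.ndarray = UP) -> tuple[float, np.ndarray]:
    """Two-chord stem height through bottom, middle and top stem points.

    The bottom is the stem point with minimal projection on the stem's
    principal axis (oriented upward) and the middle the point nearest the
    projection midpoint.  The top is the stem point closest to the topmost
    leaf's stipule when one is supplied (the paper's "where the topmost
    leaf is connected"), otherwise the maximal-projection point.
    """
    stem_points = np.asarray(stem_points, dtype=np.float64)
    if len(stem_points) < MIN_LEAF_POINTS:
        raise MeasurementError(
            f"stem has {len(stem_points)} points; need >= {MIN_LEAF_POINTS}"
        )
    up = np.asarray(up, dtype=np.float64)
    up = up / np.linalg.norm(up)
    centered = stem_points - stem_points.mean(axis=0)
    lam, vec = np.linalg.eigh(np.cov(centered.T))
    axis = vec[:, int(np.argmax(lam))]
    if axis @ up < 0:
        axis = -axis
    t = stem_points @ axis
    bottom = stem_points[int(np.argmin(t))]
    if top_attachment is not None:
        d = np.linalg.norm(stem_points - np.asarray(top_attachment), axis=1)
        top = stem_points[int(np.argmin(d))]
    else:
        top = stem_points[int(np.argmax(t))]
    mid_target = 0.5 * (t.min() + t.max())
    middle = stem_points[int(np.argmin(np.abs(t - mid_target)))]
    height = float(np.linalg.norm(bottom - middle) + np.linalg.norm(middle - top))
    return height, np.vstack([bottom, middle, top])


def count_leaves(plant: SegmentedPlant) -> int:
    """Number of leaves = number of segmented stipules (one per leaf)."""
    return len(plant.leaves)


def measure_plant(plant: SegmentedPlant, n_internal: int = 5,
                  n_bands: int = 25, up: np.ndarray = UP,
                  stem_points_manual: np.ndarray | None = None) -> PlantTraits:
    """Measure every organ of a segmented plant.

    Leaves failing preconditions are skipped with a warning instead of
    aborting the plant.  ``stem_points_manual`` (3 x 3 array) replaces the
    automatic bottom/middle/top selection, mirroring manual measurement
    from visual cues.
    """
    if plant.stem is None:
        raise PhenoCloudError("segmented plant has no stem")
    warnings = list(plant.warnings)
    stem_pts = plant.stem.points(plant.cloud)
    leaves: list[LeafTraits] = []
    for idx, leaf in enumerate(plant.leaves):
        pts = leaf.points(plant.cloud)
        try:
            apex, stipule = find_apex_stipule(pts, stem_pts)
            poly = midrib_polyline(pts, apex, stipule, n_internal)
            length = leaf_length(poly)
            wres = leaf_width(pts, apex, stipule, n_bands)
        except MeasurementError as exc:
            warnings.append(f"leaf {idx}: skipped ({exc})")
            continue
        if wres.degenerate:
            warnings.append(f"leaf {idx}: degenerate (collinear), width 0")
        elif wres.empty_band_fraction > 0.4:
            warnings.append(
                f"leaf {idx}: {wres.empty_band_fraction:.0%} of width bands empty"
            )
        leaves.append(LeafTraits(apex, stipule, poly, length, wres.width,
                                 (wres.left, wres.right), wres.band_index, idx))

    if stem_points_manual is not None:
        marks = np.asarray(stem_points_manual, dtype=np.float64).reshape(3, 3)
        height = float(np.linalg.norm(marks[0] - marks[1])
                       + np.linalg.norm(marks[1] - marks[2]))
        stem_marks = marks
    else:
        top_attach = leaves[-1].stipule if leaves else None
        height, stem_marks = stem_height(stem_pts, top_attach, up)
    return PlantTraits(height, stem_marks, count_leaves(plant), leaves, warnings)
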