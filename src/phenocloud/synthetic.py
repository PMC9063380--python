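"""Procedural chilli-like plants with exact analytic ground truth.

The generator emulates the statistical structure of a dense
photogrammetric (SfM) cloud of a single young chilli plant: a gently
curved stem (circular arc, cylindrical surface), leaves whose midribs are
circular arcs (leaf curl = total turning angle) carrying a tapered lamina,
golden-angle phyllotaxis, isotropic sensor noise, sparse uniform outliers
and an optional ground plane.  Midribs and the stem axis are circular arcs
because their arc lengths, chords and chord sums have closed forms, so the
measurement error of every trait is analytically checkable.

Ground truth (stem arc length, per-leaf midrib arc length and maximal
lamina width, organ labels) is a property of the generating surfaces, not
of the sampled points: changing density or noise changes the cloud, never
the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .io import PointCloud

GOLDEN_ANGLE_DEG = 137.5
_Z = np.array([0.0, 0.0, 1.0])

# labels in GroundTruthTraits.labels
LABEL_STEM = 0
LABEL_OUTLIER = -1
LABEL_GROUND = -2


@dataclass
class LeafSpec:
    """Geometry of one leaf: arc-length midrib + sin^e half-width profile."""

    midrib_arc_length: float
    curl_angle_deg: float = 0.0
    max_width: float | None = None        # default: arc length / 3
    width_profile_exponent: float = 1.0
    attachment_fraction: float = 1.0      # of stem arc length, in (0, 1]
    azimuth_deg: float | None = None      # None -> golden-angle sequence
    inclination_deg: float = 35.0         # initial elevation above horizontal

    @property
    def width(self) -> float:
        return (self.max_width if self.max_width is not None
                else self.midrib_arc_length / 3.0)


@dataclass
class SyntheticPlantSpec:
    stem_arc_length: float
    leaf_specs: list[LeafSpec]
    stem_bend_angle_deg: float = 0.0
    stem_bend_azimuth_deg: float = 0.0
    stem_radius: float = 0.25
    base_azimuth_deg: float = 0.0
    points_per_cm2: float = 50.0
    vein_points_per_cm: float = 40.0
    noise_sigma: float = 0.05
    outlier_fraction: float = 0.01
    ground_plane: bool = False
    leaf_clearance: float = 1.0           # unsampled petiole length
    seed: int = 0

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_specs)

    def validate(self) -> None:
        if self.stem_arc_length <= 0 or self.stem_radius <= 0:
            raise ValueError("stem dimensions must be positive")
        if not 0 <= self.outlier_fraction < 0.2:
            raise ValueError("outlier_fraction must be in [0, 0.2)")
        if self.noise_sigma < 0 or self.leaf_clearance < 0:
            raise ValueError("noise_sigma and leaf_clearance must be >= 0")
        if self.points_per_cm2 <= 0:
            raise ValueError("points_per_cm2 must be positive")
        fracs = [ls.attachment_fraction for ls in self.leaf_specs]
        if any(not 0 < f <= 1 for f in fracs):
            raise ValueError("attachment fractions must lie in (0, 1]")
        if any(b >= a for a, b in zip(fracs[1:], fracs[:-1])):
            raise ValueError("attachment fractions must be strictly increasing")
        for ls in self.leaf_specs:
            if ls.midrib_arc_length <= 0 or ls.width <= 0:
                raise ValueError("leaf dimensions must be positive")
            if not 0 <= ls.curl_angle_deg <= 270:
                raise ValueError("curl_angle_deg must be in [0, 270]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticPlantSpec":
        payload = dict(payload)
        payload["leaf_specs"] = [
            ls if isinstance(ls, LeafSpec) else LeafSpec(**ls)
            for ls in payload["leaf_specs"]
        ]
        return cls(**payload)


@dataclass
class GroundTruthTraits:
    """Analytic truth implied by a SyntheticPlantSpec."""

    stem_height: float
    n_leaves: int
    leaf_lengths: np.ndarray
    leaf_widths: np.ndarray
    labels: np.ndarray                    # per-point organ labels
    organ_counts: dict[str, int]
    min_organ_gap: float

    def to_dict(self) -> dict:
        return {
            "stem_height_cm": self.stem_height,
            "n_leaves": self.n_leaves,
            "leaf_lengths_cm": self.leaf_lengths.tolist(),
            "leaf_widths_cm": self.leaf_widths.tolist(),
            "organ_counts": dict(self.organ_counts),
            "min_organ_gap_cm": self.min_organ_gap,
        }


def _arc_points(t, arc_length, angle_rad, origin, e_t, e_n):
    """Points at arc-length fractions t of a circular arc.

    The arc starts at ``origin`` with tangent ``e_t`` and turns by
    ``angle_rad`` in total toward ``e_n``; angle 0 degenerates to a segment.
    """
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    if angle_rad < 1e-9:
        return origin + np.outer(t * arc_length, e_t)
    radius = arc_length / angle_rad
    theta = angle_rad * t
    return (origin
            + np.outer(radius * np.sin(theta), e_t)
            + np.outer(radius * (1.0 - np.cos(theta)), e_n))


def _arc_tangents(t, angle_rad, e_t, e_n):
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    theta = angle_rad * t
    return np.outer(np.cos(theta), e_t) + np.outer(np.sin(theta), e_n)


def _leaf_frame(azimuth_deg: float, inclination_deg: float):
    """(e1, e2, n): initial midrib direction, in-plane curl direction
    (drooping), and the lamina cross direction (horizontal)."""
    az = np.radians(azimuth_deg)
    inc = np.radians(inclination_deg)
    d = np.array([np.cos(az), np.sin(az), 0.0])
    e1 = np.cos(inc) * d + np.sin(inc) * _Z
    e2 = np.sin(inc) * d - np.cos(inc) * _Z
    n = np.cross(_Z, d)
    return e1, e2, n


def _profile_integral(exponent: float) -> float:
    t = np.linspace(0.0, 1.0, 2001)
    return float(np.trapezoid(np.sin(np.pi * t) ** exponent, t))


def generate_leaf(leaf: LeafSpec, attachment_point: np.ndarray,
                  azimuth_deg: float, rng: np.random.Generator,
                  points_per_cm2: float = 50.0,
                  vein_points_per_cm: float = 40.0,
                  noise_sigma: float = 0.0):
    """Sample one leaf surface; returns (points, truth dict).

    The lamina is sampled uniformly over the curved surface by rejection;
    the midrib vein is additionally sampled as a dense ridge whose first
    and last samples are the exact stipule and apex, mirroring the high
    texture (hence high SfM point density) of a protruding vein.
    """
    L = leaf.midrib_arc_length
    W = leaf.width
    curl = np.radians(leaf.curl_angle_deg)
    e1, e2, n = _leaf_frame(azimuth_deg, leaf.inclination_deg)
    origin = np.asarray(attachment_point, dtype=np.float64)

    def midrib(t):
        return _arc_points(t, L, curl, origin, e1, e2)

    exponent = leaf.width_profile_exponent
    area = L * W * _profile_integral(exponent)
    n_lamina = max(1, int(round(area * points_per_cm2)))
    t_acc = np.empty(0)
    v_acc = np.empty(0)
    while t_acc.size < n_lamina:
        t_try = rng.random(4 * n_lamina)
        v_try = rng.uniform(-1.0, 1.0, 4 * n_lamina)
        ok = np.abs(v_try) <= np.sin(np.pi * t_try) ** exponent
        t_acc = np.concatenate([t_acc, t_try[ok]])
        v_acc = np.concatenate([v_acc, v_try[ok]])
    t_s, v_s = t_acc[:n_lamina], v_acc[:n_lamina]
    lamina = midrib(t_s) + np.outer(v_s * W / 2.0, n)

    # vein positions are uniform random (equal spacing would be an
    # artificial regularity no real reconstruction has); the exact apex
    # and stipule anchor the two ends of the ridge
    n_vein = max(2, int(round(L * vein_points_per_cm)) + 1)
    t_vein = np.concatenate([[0.0], np.sort(rng.random(n_vein - 2)), [1.0]])
    vein = midrib(t_vein)

    points = np.vstack([lamina, vein])
    if noise_sigma > 0:
        points = points + rng.normal(0.0, noise_sigma, points.shape)
    truth = {
        "length": float(L),
        "width": float(W),
        "apex": midrib(1.0)[0],
        "stipule": origin.copy(),
    }
    return points, truth


def generate_stem(spec: SyntheticPlantSpec, rng: np.random.Generator):
    """Sample the stem cylinder; returns (points, attachment info list)."""
    S = spec.stem_arc_length
    bend = np.radians(spec.stem_bend_angle_deg)
    az = np.radians(spec.stem_bend_azimuth_deg)
    e_n = np.array([np.cos(az), np.sin(az), 0.0])
    origin = np.zeros(3)

    n_surface = max(1, int(round(2 * np.pi * spec.stem_radius * S
                                 * spec.points_per_cm2)))
    s = rng.random(n_surface)
    alpha = rng.uniform(0.0, 2.0 * np.pi, n_surface)
    axis_pts = _arc_points(s, S, bend, origin, _Z, e_n)
    tangents = _arc_tangents(s, bend, _Z, e_n)
    theta = bend * s
    n1 = np.outer(np.cos(theta), e_n) - np.outer(np.sin(theta), _Z)
    b = np.cross(tangents, n1)
    points = (axis_pts
              + spec.stem_radius * (np.cos(alpha)[:, None] * n1
                                    + np.sin(alpha)[:, None] * b))
    if spec.noise_sigma > 0:
        points = points + rng.normal(0.0, spec.noise_sigma, points.shape)

    attachments = []
    for i, leaf in enumerate(spec.leaf_specs):
        leaf_az = (leaf.azimuth_deg if leaf.azimuth_deg is not None
                   else spec.base_azimuth_deg + i * GOLDEN_ANGLE_DEG)
        axis_pt = _arc_points(leaf.attachment_fraction, S, bend, origin,
                              _Z, e_n)[0]
        radial = np.array([np.cos(np.radians(leaf_az)),
                           np.sin(np.radians(leaf_az)), 0.0])
        stipule = axis_pt + (spec.stem_radius + spec.leaf_clearance) * radial
        attachments.append((stipule, leaf_az))
    return points, attachments


def _analytic_organ_grids(spec: SyntheticPlantSpec, step: float = 0.1):
    """Noiseless fixed-resolution point grids of every organ surface."""
    grids = []
    bend = np.radians(spec.stem_bend_angle_deg)
    az = np.radians(spec.stem_bend_azimuth_deg)
    e_n = np.array([np.cos(az), np.sin(az), 0.0])
    S = spec.stem_arc_length
    ns = max(2, int(np.ceil(S / step)) + 1)
    s = np.linspace(0.0, 1.0, ns)
    axis_pts = _arc_points(s, S, bend, np.zeros(3), _Z, e_n)
    tangents = _arc_tangents(s, bend, _Z, e_n)
    theta = bend * s
    n1 = np.outer(np.cos(theta), e_n) - np.outer(np.sin(theta), _Z)
    b = np.cross(tangents, n1)
    angles = np.linspace(0.0, 2.0 * np.pi, 24, endpoint=False)
    stem_grid = (axis_pts[:, None, :]
                 + spec.stem_radius * (np.cos(angles)[None, :, None] * n1[:, None, :]
                                       + np.sin(angles)[None, :, None] * b[:, None, :])
                 ).reshape(-1, 3)
    grids.append(stem_grid)

    for i, leaf in enumerate(spec.leaf_specs):
        leaf_az = (leaf.azimuth_deg if leaf.azimuth_deg is not None
                   else spec.base_azimuth_deg + i * GOLDEN_ANGLE_DEG)
        axis_pt = _arc_points(leaf.attachment_fraction, S, bend, np.zeros(3),
                              _Z, e_n)[0]
        radial = np.array([np.cos(np.radians(leaf_az)),
                           np.sin(np.radians(leaf_az)), 0.0])
        stipule = axis_pt + (spec.stem_radius + spec.leaf_clearance) * radial
        e1, e2, n = _leaf_frame(leaf_az, leaf.inclination_deg)
        L, W = leaf.midrib_arc_length, leaf.width
        curl = np.radians(leaf.curl_angle_deg)
        nt = max(2, int(np.ceil(L / step)) + 1)
        t = np.linspace(0.0, 1.0, nt)
        mid = _arc_points(t, L, curl, stipule, e1, e2)
        pts = [mid]
        w = (W / 2.0) * np.sin(np.pi * t) ** leaf.width_profile_exponent
        nv = max(3, int(np.ceil(W / step)) + 1)
        for v in np.linspace(-1.0, 1.0, nv):
            if v == 0.0:
                continue
            pts.append(mid + np.outer(v * w, n))
        grids.append(np.vstack(pts))
    return grids


def min_organ_gap(spec: SyntheticPlantSpec, step: float = 0.1) -> float:
    """Minimum distance between any two organ surfaces.

    Computed on noiseless analytic grids at fixed resolution, so the value
    depends only on the geometry, not on sampling density or noise.
    """
    grids = _analytic_organ_grids(spec, step)
    gap = np.inf
    for i in range(len(grids)):
        tree = cKDTree(grids[i])
        for j in range(i + 1, len(grids)):
            d, _ = tree.query(grids[j], k=1)
            gap = min(gap, float(d.min()))
    return gap


def generate_plant(spec: SyntheticPlantSpec
                   ) -> tuple[PointCloud, GroundTruthTraits]:
    """Assemble stem + leaves (+ outliers, optional ground plane).

    Every organ consumes an independent child stream of the spec seed, so
    adding or editing one organ never perturbs another's samples.
    """
    spec.validate()
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(spec.seed).spawn(spec.n_leaves + 3)]
    stem_pts, attachments = generate_stem(spec, streams[0])

    chunks = [stem_pts]
    labels = [np.full(len(stem_pts), LABEL_STEM, dtype=np.int32)]
    organ_counts = {"stem": len(stem_pts)}
    lengths, widths = [], []
    for i, leaf in enumerate(spec.leaf_specs):
        stipule, leaf_az = attachments[i]
        pts, truth = generate_leaf(
            leaf, stipule, leaf_az, streams[1 + i],
            points_per_cm2=spec.points_per_cm2,
            vein_points_per_cm=spec.vein_points_per_cm,
            noise_sigma=spec.noise_sigma,
        )
        chunks.append(pts)
        labels.append(np.full(len(pts), i + 1, dtype=np.int32))
        organ_counts[f"leaf_{i + 1}"] = len(pts)
        lengths.append(truth["length"])
        widths.append(truth["width"])

    organ_pts = np.vstack(chunks)
    n_outliers = int(round(spec.outlier_fraction * len(organ_pts)))
    if n_outliers > 0:
        lo, hi = organ_pts.min(axis=0), organ_pts.max(axis=0)
        span = hi - lo
        out = streams[-2].uniform(lo - 0.2 * span, hi + 0.2 * span,
                                  (n_outliers, 3))
        chunks.append(out)
        labels.append(np.full(n_outliers, LABEL_OUTLIER, dtype=np.int32))
    organ_counts["outliers"] = n_outliers

    n_ground = 0
    if spec.ground_plane:
        radius = max(5.0, 1.3 * float(
            np.linalg.norm(organ_pts[:, :2], axis=1).max()))
        n_ground = int(round(np.pi * radius ** 2 * spec.points_per_cm2))
        rng_g = streams[-1]
        r = radius * np.sqrt(rng_g.random(n_ground))
        phi = rng_g.uniform(0.0, 2.0 * np.pi, n_ground)
        ground = np.column_stack([r * np.cos(phi), r * np.sin(phi),
                                  np.zeros(n_ground)])
        if spec.noise_sigma > 0:
            ground = ground + rng_g.normal(0.0, spec.noise_sigma, ground.shape)
        chunks.append(ground)
        labels.append(np.full(n_ground, LABEL_GROUND, dtype=np.int32))
    organ_counts["ground"] = n_ground

    cloud = PointCloud(np.vstack(chunks))
    truth = GroundTruthTraits(
        stem_height=float(spec.stem_arc_length),
        n_leaves=spec.n_leaves,
        leaf_lengths=np.asarray(lengths),
        leaf_widths=np.asarray(widths),
        labels=np.concatenate(labels),
        organ_counts=organ_counts,
        min_organ_gap=min_organ_gap(spec),
    )
    return cloud, truth


def paper_regime_spec(seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      stage: float | None = None,
                      n_leaves: int | None = None,
                      leaf_lengths=None,
                      curl_max_deg: float = 150.0,
                      noise_sigma: float = 0.05,
                      outlier_fraction: float = 0.01,
                      points_per_cm2: float = 50.0,
                      ground_plane: bool = False) -> SyntheticPlantSpec:
    """Draw a plant spec in the regime of the field study.

    A growth stage u in [0, 1] couples stem arc length (5 -> 27 cm) with
    leaf count (3 -> 11); leaf midrib lengths default to U(1.6, 6.5) cm,
    widths to one third of the length, curl to U(0, curl_max).  The topmost
    leaf attaches at the stem tip, matching the convention that stem height
    runs up to the topmost leaf connection.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    u = float(rng.random()) if stage is None else float(stage)
    n = int(round(3 + 8 * u)) if n_leaves is None else int(n_leaves)
    n = max(1, n)
    stem_len = 5.0 + 22.0 * u
    if leaf_lengths is None:
        leaf_lengths = rng.uniform(1.6, 6.5, n)
    leaf_lengths = np.asarray(leaf_lengths, dtype=np.float64)
    if len(leaf_lengths) != n:
        raise ValueError("leaf_lengths must match n_leaves")
    curls = rng.uniform(0.0, curl_max_deg, n)
    incs = rng.uniform(15.0, 40.0, n)
    if n == 1:
        fracs = np.array([1.0])
    else:
        fracs = np.linspace(0.35, 1.0, n)
        jitter = rng.uniform(-0.015, 0.015, n)
        jitter[0] = jitter[-1] = 0.0
        fracs = fracs + jitter
    leaf_specs = [
        LeafSpec(
            midrib_arc_length=float(leaf_lengths[i]),
            curl_angle_deg=float(curls[i]),
            attachment_fraction=float(fracs[i]),
            inclination_deg=float(incs[i]),
        )
        for i in range(n)
    ]
    return SyntheticPlantSpec(
        stem_arc_length=stem_len,
        leaf_specs=leaf_specs,
        stem_bend_angle_deg=float(rng.uniform(0.0, 25.0)),
        stem_bend_azimuth_deg=float(rng.uniform(0.0, 360.0)),
        stem_radius=0.15 + 0.25 * u,
        base_azimuth_deg=float(rng.uniform(0.0, 360.0)),
        points_per_cm2=points_per_cm2,
        noise_sigma=noise_sigma,
        outlier_fraction=outlier_fraction,
        ground_plane=ground_plane,
        seed=int(rng.integers(2 ** 31)),
    )


def arc_polyline(arc_length: float, angle_deg: float,
                 n_internal: int = 5) -> np.ndarray:
    """Polyline of n_internal + 2 points equally spaced *along* a circular
    arc — the closed-form reference for chord-sum length checks."""
    t = np.linspace(0.0, 1.0, n_internal + 2)
    return _arc_points(t, arc_length, np.radians(angle_deg),
                       np.zeros(3), np.array([1.0, 0.0, 0.0]),
                       np.array([0.0, 1.0, 0.0]))
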