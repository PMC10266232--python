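"""Arch ("∩"-type) seedling-avoidance trajectories in a vertical plane.

A weeding cycle moves the spray end-effector from one weed (S) to the next
(E) while clearing the crop plant standing between them.  The crop is
modelled as a vertical cylinder (standoff ``w1`` from S to the near edge of
its footprint, radius ``w2``, height ``h3``).  The trajectory is built in
the vertical plane N through the segment SE and consists of five phases:

    S -> P0        vertical ascent of height h1
    P0 -> P3       cubic Bezier transition rising by h2
    P3 -> P4       horizontal pass at height h1 + h2
    P4 -> P5       mirrored cubic Bezier transition
    P5 -> E        vertical descent

The Bezier control offsets ``alpha`` (length of P0P1, along the ascent
direction) and ``beta`` (length of P2P3, along the direction from P4 toward
P3) shape the transitions; they are bounded by 0.8*h2 and 0.8*(w1+w2)
respectively so that the curvature stays smooth and free of singularities.
All coordinates are millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PlanarPoint",
    "WorldPoint",
    "CropObstacle",
    "TrajectoryParams",
    "BezierSegment",
    "ArchTrajectory",
    "ClearanceReport",
    "PlaneEmbedding",
    "eval_cubic_bezier",
    "bezier_curvature",
    "build_arch",
    "path_length",
    "check_clearance",
    "plane_embedding",
]


@dataclass(frozen=True)
class PlanarPoint:
    """A point in the vertical plane N: ``u`` along SE, ``z`` upward (mm)."""

    u: float
    z: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.u) and math.isfinite(self.z)):
            raise ValueError("planar point coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.z], dtype=float)


@dataclass(frozen=True)
class WorldPoint:
    """A point in the robot base frame (mm)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.x, self.y, self.z))):
            raise ValueError("world point coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class CropObstacle:
    """Cylinder model of a crop plant.

    ``standoff_w1`` is the distance from S to the near edge of the cylinder
    footprint along u; the footprint occupies ``[w1, w1 + 2*w2]`` and the
    bottom-circle centre sits at ``u = w1 + w2``.
    """

    standoff_w1: float
    radius_w2: float
    height_h3: float

    def __post_init__(self) -> None:
        if self.standoff_w1 <= 0 or self.radius_w2 <= 0 or self.height_h3 <= 0:
            raise ValueError("obstacle parameters must be strictly positive")

    @property
    def footprint(self) -> tuple[float, float]:
        return (self.standoff_w1, self.standoff_w1 + 2.0 * self.radius_w2)

    @property
    def center_u(self) -> float:
        return self.standoff_w1 + self.radius_w2


@dataclass(frozen=True)
class TrajectoryParams:
    """Arch dimensions: ascent h1, Bezier transition rise h2 (mm)."""

    ascent_h1: float
    transition_h2: float
    clearance_margin: float = 0.0
    samples_per_segment: int = 200

    def __post_init__(self) -> None:
        if self.ascent_h1 < 0:
            raise ValueError("h1 must be non-negative")
        if self.transition_h2 <= 0:
            raise ValueError("h2 must be positive")
        if self.samples_per_segment < 2:
            raise ValueError("samples_per_segment must be >= 2")

    @property
    def apex(self) -> float:
        return self.ascent_h1 + self.transition_h2


@dataclass(frozen=True)
class BezierSegment:
    """Cubic Bezier defined by four planar control points."""

    p0: PlanarPoint
    p1: PlanarPoint
    p2: PlanarPoint
    p3: PlanarPoint

    def control_array(self) -> np.ndarray:
        return np.stack([p.as_array() for p in (self.p0, self.p1, self.p2, self.p3)])


def eval_cubic_bezier(seg: BezierSegment, t: float) -> PlanarPoint:
    """Evaluate B(t) = (1-t)^3 P0 + 3t(1-t)^2 P1 + 3t^2(1-t) P2 + t^3 P3."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"Bezier parameter t={t} outside [0, 1]")
    if t == 0.0:
        return seg.p0
    if t == 1.0:
        return seg.p3
    s = 1.0 - t
    w = np.array([s**3, 3 * t * s**2, 3 * t**2 * s, t**3])
    u, z = w @ seg.control_array()
    return PlanarPoint(u, z)


def _bezier_derivatives(seg: BezierSegment, t: float) -> tuple[np.ndarray, np.ndarray]:
    p = seg.control_array()
    d1 = 3 * ((1 - t) ** 2 * (p[1] - p[0]) + 2 * t * (1 - t) * (p[2] - p[1]) + t**2 * (p[3] - p[2]))
    d2 = 6 * ((1 - t) * (p[2] - 2 * p[1] + p[0]) + t * (p[3] - 2 * p[2] + p[1]))
    return d1, d2


def bezier_curvature(seg: BezierSegment, t: float) -> float:
    """Signed-magnitude curvature k(t) = |u'z'' - u''z'| / (u'^2 + z'^2)^(3/2).

    Raises if the first derivative vanishes at ``t`` (the curve has a
    parametric singularity there, e.g. a fully degenerate segment).
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"Bezier parameter t={t} outside [0, 1]")
    d1, d2 = _bezier_derivatives(seg, t)
    speed_sq = float(d1 @ d1)
    if speed_sq < 1e-18:
        raise ZeroDivisionError(f"zero first derivative at t={t}: curvature singular")
    cross = abs(d1[0] * d2[1] - d2[0] * d1[1])
    return cross / speed_sq**1.5


def _sample_bezier(seg: BezierSegment, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    s = 1.0 - t
    w = np.hstack([s**3, 3 * t * s**2, 3 * t**2 * s, t**3])
    return w @ seg.control_array()


@dataclass(frozen=True)
class PlaneEmbedding:
    """Rigid map between plane N coordinates (u, z) and the world frame.

    Forward sends a world point into the plane (S at the origin, u toward
    E); ``to_world`` is the exact inverse for points lying in the plane.
    """

    origin: np.ndarray  # world coordinates of S
    u_axis: np.ndarray  # horizontal unit vector S -> E
    base_z: float  # ground height of S (= E)

    def to_plane(self, p: WorldPoint) -> PlanarPoint:
        d = p.as_array() - self.origin
        return PlanarPoint(float(d[:2] @ self.u_axis[:2]), float(d[2]))

    def to_world(self, q: PlanarPoint) -> WorldPoint:
        w = self.origin + q.u * self.u_axis
        return WorldPoint(float(w[0]), float(w[1]), self.base_z + q.z)


def plane_embedding(s3: WorldPoint, e3: WorldPoint) -> PlaneEmbedding:
    """Embed the vertical plane through S and E, with S at the plane origin."""
    d = e3.as_array() - s3.as_array()
    horiz = math.hypot(d[0], d[1])
    if horiz < 1e-12:
        raise ValueError("coincident (or vertically stacked) endpoints: plane undefined")
    if abs(d[2]) > 1e-9:
        raise ValueError("S and E must be at the same ground height")
    u_axis = np.array([d[0] / horiz, d[1] / horiz, 0.0])
    return PlaneEmbedding(origin=s3.as_array(), u_axis=u_axis, base_z=s3.z)


@dataclass(frozen=True)
class ArchTrajectory:
    """The sampled ∩ trajectory plus its construction data."""

    s: PlanarPoint
    e: PlanarPoint
    bezier_up: BezierSegment
    bezier_down: BezierSegment
    p4: PlanarPoint
    p5: PlanarPoint
    alpha: float
    beta: float
    params: TrajectoryParams
    polyline: np.ndarray = field(repr=False)  # (n, 2) array of (u, z)
    phases: tuple[tuple[str, int, int], ...] = ()  # (name, start, stop) slices
    embedding: PlaneEmbedding | None = None

    @property
    def apex_z(self) -> float:
        return self.params.apex

    def world_polyline(self) -> np.ndarray:
        """Polyline lifted to the world frame via the embedding (n, 3)."""
        emb = self.embedding
        if emb is None:
            raise ValueError("trajectory has no world embedding attached")
        u = self.polyline[:, 0]
        z = self.polyline[:, 1]
        xy = emb.origin[None, :] + u[:, None] * emb.u_axis[None, :]
        out = xy.copy()
        out[:, 2] = emb.base_z + z
        return out

    def with_embedding(self, emb: PlaneEmbedding) -> "ArchTrajectory":
        return replace(self, embedding=emb)


def alpha_bound(params: TrajectoryParams) -> float:
    """Upper bound 0.8*h2 on the first control offset."""
    return 0.8 * params.transition_h2


def beta_bound(obs: CropObstacle) -> float:
    """Upper bound 0.8*(w1+w2) on the second control offset."""
    return 0.8 * (obs.standoff_w1 + obs.radius_w2)


def build_arch(
    s: PlanarPoint,
    e: PlanarPoint,
    obs: CropObstacle,
    params: TrajectoryParams,
    alpha: float,
    beta: float,
) -> ArchTrajectory:
    """Construct the ∩ trajectory for control offsets (alpha, beta).

    P0 = S + (0, h1); P3 = (w1, h1+h2) sits directly above the near edge of
    the obstacle footprint; P4 = (L - w1, h1+h2) is its mirror about the
    midpoint of SE, so the E-side transition is the exact mirror of the
    S-side one with the same offsets.
    """
    if abs(s.z) > 1e-9 or abs(e.z) > 1e-9:
        raise ValueError("trajectory endpoints must be at ground height (z = 0)")
    L = e.u - s.u
    if L <= 0:
        raise ValueError("E must lie at larger u than S")
    a_max = alpha_bound(params)
    b_max = beta_bound(obs)
    if not 0.0 <= alpha <= a_max + 1e-12:
        raise ValueError(f"alpha={alpha} outside [0, {a_max}]")
    if not 0.0 <= beta <= b_max + 1e-12:
        raise ValueError(f"beta={beta} outside [0, {b_max}]")
    if params.apex <= obs.height_h3:
        raise ValueError(
            f"infeasible scene: apex h1+h2={params.apex} does not exceed "
            f"obstacle height h3={obs.height_h3}"
        )

    h1, h2 = params.ascent_h1, params.transition_h2
    apex = params.apex
    w1 = obs.standoff_w1

    p0 = PlanarPoint(s.u, h1)
    p3 = PlanarPoint(s.u + w1, apex)
    # P1 along the ascent direction above P0; P2 back toward S from P3.
    p1 = PlanarPoint(p0.u, h1 + alpha)
    p2 = PlanarPoint(p3.u - beta, apex)
    bez_up = BezierSegment(p0, p1, p2, p3)

    p4 = PlanarPoint(e.u - w1, apex)
    p5 = PlanarPoint(e.u, h1)
    q1 = PlanarPoint(p4.u + beta, apex)
    q2 = PlanarPoint(p5.u, h1 + alpha)
    bez_down = BezierSegment(p4, q1, q2, p5)

    n = params.samples_per_segment
    pieces: list[tuple[str, np.ndarray]] = [
        ("ascent", np.array([[s.u, 0.0], [p0.u, p0.z]])),
        ("transition_up", _sample_bezier(bez_up, n)),
        ("horizontal", np.array([[p3.u, apex], [p4.u, apex]])),
        ("transition_down", _sample_bezier(bez_down, n)),
        ("descent", np.array([[p5.u, p5.z], [e.u, 0.0]])),
    ]
    rows: list[np.ndarray] = []
    phases: list[tuple[str, int, int]] = []
    start = 0
    for name, arr in pieces:
        if rows:
            arr = arr[1:]  # phases share their junction point
        rows.append(arr)
        phases.append((name, start, start + len(arr)))
        start += len(arr)
    polyline = np.vstack(rows)

    return ArchTrajectory(
        s=s,
        e=e,
        bezier_up=bez_up,
        bezier_down=bez_down,
        p4=p4,
        p5=p5,
        alpha=float(alpha),
        beta=float(beta),
        params=params,
        polyline=polyline,
        phases=tuple(phases),
    )


def path_length(traj: ArchTrajectory) -> float:
    """Total chord length of the sampled polyline (mm)."""
    pts = traj.polyline
    if len(pts) < 2:
        raise ValueError("polyline needs at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


@dataclass(frozen=True)
class ClearanceReport:
    """Result of checking the trajectory against a crop cylinder."""

    feasible: bool
    min_margin: float  # min(z) - (h3 + margin) over the footprint; +inf if outside
    min_z_over_footprint: float
    footprint_outside_span: bool = False


def check_clearance(
    traj: ArchTrajectory, obs: CropObstacle, margin: float = 0.0
) -> ClearanceReport:
    """Feasible iff min z over the footprint interval >= h3 + margin."""
    lo, hi = obs.footprint
    u = traj.polyline[:, 0]
    z = traj.polyline[:, 1]
    inside = (u >= lo) & (u <= hi)
    if not inside.any():
        return ClearanceReport(
            feasible=True,
            min_margin=math.inf,
            min_z_over_footprint=math.inf,
            footprint_outside_span=True,
        )
    min_z = float(z[inside].min())
    m = min_z - (obs.height_h3 + margin)
    return ClearanceReport(feasible=m >= 0.0, min_margin=m, min_z_over_footprint=min_z)
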