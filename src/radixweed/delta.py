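"""Delta parallel-manipulator kinematics and trajectory discretisation.

The three upper arms rotate about horizontal axes tangent to the base
circle at azimuths 0°, 120° and 240°; the parallelogram forearms keep the
travelling platform parallel to the base, so the platform pose is a pure
translation.  Joint angles are measured from the horizontal base plane,
positive downward (the knee-out elbow branch is used throughout, which is
the branch a physical machine runs on).  The base frame has its origin at
the base-circle centre, z pointing up; reachable targets lie below the base
(z < 0).

The planned arch trajectory is discretised into points spaced equally in
arc length and converted to per-step joint-angle differences, which is what
a stepper-driven machine consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import ArchTrajectory, WorldPoint

__all__ = [
    "DeltaGeometry",
    "JointAngles",
    "WorkspaceError",
    "inverse_kinematics",
    "forward_kinematics",
    "discretize",
    "discretize_polyline",
    "joint_deltas",
]

_AZIMUTHS = np.deg2rad([0.0, 120.0, 240.0])


class WorkspaceError(ValueError):
    """Raised when a target point is unreachable for at least one arm."""


@dataclass(frozen=True)
class DeltaGeometry:
    """Link dimensions in mm; defaults suit a small field manipulator."""

    base_radius: float = 150.0
    platform_radius: float = 50.0
    upper_arm: float = 200.0
    forearm: float = 400.0

    def __post_init__(self) -> None:
        if min(self.base_radius, self.platform_radius, self.upper_arm, self.forearm) <= 0:
            raise ValueError("all geometry lengths must be positive")
        if self.forearm <= abs(self.base_radius - self.platform_radius) - self.upper_arm:
            raise ValueError("workspace empty for this geometry")


@dataclass(frozen=True)
class JointAngles:
    theta1: float
    theta2: float
    theta3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3])


def _arm_angle(q: np.ndarray, g: DeltaGeometry) -> float:
    """Solve one arm in its own frame (shoulder on the +x axis).

    ``q`` is the platform anchor relative to the base centre, already
    rotated into the arm frame and shifted by the platform radius.  The
    elbow sits at (R + La*cos(theta), 0, -La*sin(theta)); the forearm rod
    closes the loop: |anchor - elbow| = Lb.
    """
    a = q[0] - g.base_radius
    b = q[2]
    k = (a * a + b * b + q[1] ** 2 + g.upper_arm**2 - g.forearm**2) / (2.0 * g.upper_arm)
    rho = math.hypot(a, b)
    if rho < 1e-12 or abs(k) > rho:
        raise WorkspaceError("target out of reach for this arm")
    delta = math.atan2(b, a)
    # a*cos(t) - b*sin(t) = k  ->  t = ±acos(k/rho) - delta; - is knee-out
    return -math.acos(max(-1.0, min(1.0, k / rho))) - delta


def inverse_kinematics(p: WorldPoint, g: DeltaGeometry = DeltaGeometry()) -> JointAngles:
    """Joint angles driving the platform centre to ``p`` (knee-out branch)."""
    pa = p.as_array()
    thetas = []
    for i, phi in enumerate(_AZIMUTHS):
        c, s = math.cos(phi), math.sin(phi)
        rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
        q = rot @ pa
        q[0] += g.platform_radius  # anchor sits platform_radius outboard of centre
        try:
            thetas.append(_arm_angle(q, g))
        except WorkspaceError as err:
            raise WorkspaceError(f"arm {i + 1} (azimuth {math.degrees(phi):.0f}°): {err}") from None
    return JointAngles(*thetas)


def forward_kinematics(a: JointAngles, g: DeltaGeometry = DeltaGeometry()) -> WorldPoint:
    """Platform centre for given joint angles: lower three-sphere intersection.

    Each forearm constrains the platform centre to a sphere of radius
    ``forearm`` centred at the elbow shifted inboard by the platform radius.
    """
    centers = []
    for theta, phi in zip(a.as_array(), _AZIMUTHS):
        radial = g.base_radius + g.upper_arm * math.cos(theta) - g.platform_radius
        centers.append(
            np.array(
                [radial * math.cos(phi), radial * math.sin(phi), -g.upper_arm * math.sin(theta)]
            )
        )
    c1, c2, c3 = centers
    # two plane equations from sphere differences, then the sphere quadratic
    A = np.array([2 * (c2 - c1), 2 * (c3 - c1)])
    b = np.array([c2 @ c2 - c1 @ c1, c3 @ c3 - c1 @ c1])
    # parametrise solutions along the null direction of A
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    null = np.cross(A[0], A[1])
    nn = np.linalg.norm(null)
    if nn < 1e-12:
        raise ValueError("degenerate configuration: sphere centres collinear")
    null /= nn
    d = sol - c1
    tb = d @ null
    disc = tb * tb - (d @ d - g.forearm**2)
    if disc < 0:
        raise ValueError("no sphere intersection: invalid joint angles")
    roots = [-tb + math.sqrt(disc), -tb - math.sqrt(disc)]
    pts = [sol + t * null for t in roots]
    p = min(pts, key=lambda v: v[2])  # lower intersection
    return WorldPoint(float(p[0]), float(p[1]), float(p[2]))


def discretize_polyline(points: np.ndarray, n: int = 100) -> np.ndarray:
    """Resample an (m, k) polyline to n points equally spaced in arc length."""
    if n < 2:
        raise ValueError("need at least 2 points")
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, pts.shape[1]))
    for k in range(pts.shape[1]):
        out[:, k] = np.interp(targets, cum, pts[:, k])
    out[0], out[-1] = pts[0], pts[-1]
    return out


def discretize(traj: ArchTrajectory, n: int = 100) -> list[WorldPoint]:
    """Equal-arc-length waypoints along the arch, in the world frame."""
    world = traj.world_polyline()
    pts = discretize_polyline(world, n)
    return [WorldPoint(*map(float, row)) for row in pts]


def joint_deltas(
    points: list[WorldPoint], g: DeltaGeometry = DeltaGeometry()
) -> tuple[np.ndarray, np.ndarray]:
    """IK at every waypoint and per-step joint differences.

    Returns (angles, deltas): angles is (n, 3); deltas is (n-1, 3) with
    deltas[i] = angles[i+1] - angles[i], so the running sum telescopes to
    the net rotation.  Workspace errors are re-raised with the waypoint
    index.
    """
    angles = np.empty((len(points), 3))
    for i, p in enumerate(points):
        try:
            angles[i] = inverse_kinematics(p, g).as_array()
        except WorkspaceError as err:
            raise WorkspaceError(f"waypoint {i}: {err}") from None
    return angles, np.diff(angles, axis=0)
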