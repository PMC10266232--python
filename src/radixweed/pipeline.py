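"""End-to-end weeding workflow: image -> weed positions -> arch plans -> joints.

One *weeding cycle* is the motion of the spray end-effector from the
current weed to the next.  The pipeline segments weeds from the image
(crop boxes are an input), maps centroids to robot-frame millimetres,
orders the weeds nearest-neighbour from the arm origin, and for each
consecutive pair plans a clearance-checked arch over the crop standing
between them, finishing with Delta-arm joint commands.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .delta import DeltaGeometry, discretize, joint_deltas
from .geometry import (
    CropObstacle,
    PlanarPoint,
    TrajectoryParams,
    WorldPoint,
    plane_embedding,
)
from .io import write_joint_csv, write_trajectory_csv
from .pso import OptResult, Scene, SwarmConfig, optimize_transition
from .segmentation import CalibratedCamera, SegConfig, pixel_to_robot, segment_weeds

logger = logging.getLogger("radixweed")

__all__ = ["PipelineConfig", "CropCylinder", "run_pipeline", "order_weeds", "collides"]


@dataclass(frozen=True)
class CropCylinder:
    """A crop cylinder in the robot ground plane (mm)."""

    center: tuple[float, float]
    radius: float
    height: float


@dataclass(frozen=True)
class PipelineConfig:
    seg: SegConfig = field(default_factory=SegConfig)
    calib: CalibratedCamera = field(default_factory=lambda: CalibratedCamera(mm_per_px=1.0))
    params: TrajectoryParams = field(
        default_factory=lambda: TrajectoryParams(ascent_h1=20.0, transition_h2=150.0)
    )
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    delta: DeltaGeometry = field(default_factory=DeltaGeometry)
    crop_height_mm: float = 150.0  # assumed plant height for every crop cylinder
    arm_origin: tuple[float, float] = (0.0, 0.0)
    arm_base_height_mm: float = 520.0  # ground plane sits this far below the arm base
    n_waypoints: int = 100
    seed: int = 0


def order_weeds(points_mm: list[tuple[float, float]], origin: tuple[float, float]):
    """Nearest-neighbour visiting order starting from the arm origin."""
    remaining = list(range(len(points_mm)))
    order: list[int] = []
    cur = np.asarray(origin, dtype=float)
    while remaining:
        d = [np.hypot(points_mm[i][0] - cur[0], points_mm[i][1] - cur[1]) for i in remaining]
        j = remaining.pop(int(np.argmin(d)))
        order.append(j)
        cur = np.asarray(points_mm[j])
    return order


def _crop_cylinders(crop_boxes, calib: CalibratedCamera, height: float) -> list[CropCylinder]:
    cyls = []
    for b in crop_boxes:
        xmin, ymin, xmax, ymax = (b.xmin, b.ymin, b.xmax, b.ymax) if hasattr(b, "xmin") else b
        cx = (xmin + xmax) / 2
        cy = (ymin + ymax) / 2
        w = pixel_to_robot((cx, cy), calib)
        radius = 0.5 * min(xmax - xmin, ymax - ymin) * calib.mm_per_px
        cyls.append(CropCylinder(center=(w.x, w.y), radius=radius, height=height))
    return cyls


def _obstacle_for_cycle(s: WorldPoint, e: WorldPoint, cyls: list[CropCylinder]):
    """Nearest crop cylinder that intrudes into the vertical plane of SE.

    Returns a CropObstacle in plane-N coordinates, or None when no crop
    stands between the weeds.
    """
    sv = np.array([s.x, s.y])
    ev = np.array([e.x, e.y])
    d = ev - sv
    L = float(np.linalg.norm(d))
    u_hat = d / L
    best = None
    for cyl in cyls:
        c = np.array(cyl.center) - sv
        u = float(c @ u_hat)
        perp = abs(float(c[0] * u_hat[1] - c[1] * u_hat[0]))
        if perp >= cyl.radius:  # cylinder does not cut the plane
            continue
        half = float(np.sqrt(cyl.radius**2 - perp**2))  # half-chord in the plane
        if u - half <= 0 or u + half >= L:  # not strictly between the weeds
            continue
        if best is None or perp < best[0]:  # nearest crop to the SE segment
            best = (perp, u, half, cyl.height)
    if best is None:
        return None
    _, u, half, h = best
    return CropObstacle(standoff_w1=u - half, radius_w2=half, height_h3=h)


def _virtual_obstacle(L: float) -> CropObstacle:
    """Tiny nominal cylinder so the arch construction is defined with no crop."""
    w2 = L / 8.0
    return CropObstacle(standoff_w1=L / 2.0 - w2, radius_w2=w2, height_h3=1.0)


def collides(world_polyline: np.ndarray, cyls: list[CropCylinder]) -> bool:
    """True if any polyline point lies inside any crop cylinder."""
    for cyl in cyls:
        dx = world_polyline[:, 0] - cyl.center[0]
        dy = world_polyline[:, 1] - cyl.center[1]
        inside = (np.hypot(dx, dy) < cyl.radius) & (world_polyline[:, 2] < cyl.height)
        if inside.any():
            return True
    return False


def run_pipeline(image: np.ndarray, crop_boxes, cfg: PipelineConfig, out_dir=None) -> dict:
    """Run segmentation, planning and joint generation; return the report.

    If ``out_dir`` is given, writes report.json plus per-cycle trajectory
    and joint CSVs there.
    """
    t0 = time.perf_counter()
    weeds = segment_weeds(image, [b.box if hasattr(b, "box") else b for b in crop_boxes], cfg.seg)
    logger.info("segmented %d weeds", len(weeds))

    weed_mm = []
    for wd in weeds:
        p = pixel_to_robot((wd.centroid[1], wd.centroid[0]), cfg.calib)
        weed_mm.append((p.x, p.y))
    order = order_weeds(weed_mm, cfg.arm_origin)
    cyls = _crop_cylinders(crop_boxes, cfg.calib, cfg.crop_height_mm)

    report: dict = {
        "n_weeds": len(weeds),
        "weeds_px": [list(w.centroid) for w in weeds],
        "weeds_mm": [list(weed_mm[i]) for i in order],
        "visit_order": order,
        "cycles": [],
        "seed": cfg.seed,
    }

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for k in range(len(order) - 1):
        a = weed_mm[order[k]]
        b = weed_mm[order[k + 1]]
        s3 = WorldPoint(a[0], a[1], 0.0)
        e3 = WorldPoint(b[0], b[1], 0.0)
        emb = plane_embedding(s3, e3)
        L = emb.to_plane(e3).u
        obs = _obstacle_for_cycle(s3, e3, cyls)
        has_crop = obs is not None
        if obs is None:
            obs = _virtual_obstacle(L)
        scene = Scene(
            s=PlanarPoint(0.0, 0.0), e=PlanarPoint(L, 0.0), obstacle=obs, params=cfg.params
        )
        swarm = SwarmConfig(
            n_particles=cfg.swarm.n_particles,
            n_max=cfg.swarm.n_max,
            omega=cfg.swarm.omega,
            c1=cfg.swarm.c1,
            c2=cfg.swarm.c2,
            seed=(cfg.seed + k) % 2**31,
            penalty=cfg.swarm.penalty,
        )
        entry: dict = {"cycle": k, "from": list(a), "to": list(b), "has_crop_obstacle": has_crop}
        try:
            res: OptResult = optimize_transition(scene, swarm)
        except (RuntimeError, ValueError) as err:
            logger.warning("cycle %d infeasible: %s", k, err)
            entry.update({"feasible": False, "error": str(err)})
            report["cycles"].append(entry)
            continue
        traj = res.trajectory.with_embedding(emb)
        wp = traj.world_polyline()
        entry.update(
            {
                "feasible": True,
                "alpha": res.alpha,
                "beta": res.beta,
                "fitness_mm": res.fitness,
                "min_margin_mm": res.min_margin if np.isfinite(res.min_margin) else None,
                "collision_free": not collides(wp, cyls),
            }
        )
        if out is not None:
            write_trajectory_csv(out / f"cycle_{k:03d}_trajectory.csv", traj)
            # joint commands computed in the arm frame (ground below the base)
            pts = discretize(traj, cfg.n_waypoints)
            pts = [WorldPoint(p.x, p.y, p.z - cfg.arm_base_height_mm) for p in pts]
            try:
                angles, deltas = joint_deltas(pts, cfg.delta)
            except Exception as err:  # waypoint outside the arm workspace
                logger.warning("cycle %d joint solve failed: %s", k, err)
                entry["joints_written"] = False
            else:
                write_joint_csv(out / f"cycle_{k:03d}_joints.csv", pts, angles, deltas)
                entry["joints_written"] = True
        report["cycles"].append(entry)

    report["elapsed_s"] = round(time.perf_counter() - t0, 3)
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
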