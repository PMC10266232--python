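"""File formats: YOLO label text, scene JSON, trajectory and joint CSVs."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import ArchTrajectory, CropObstacle, TrajectoryParams, WorldPoint

__all__ = [
    "DetectionBox",
    "read_yolo_labels",
    "write_yolo_labels",
    "read_scene_json",
    "write_scene_json",
    "write_trajectory_csv",
    "write_joint_csv",
]


@dataclass(frozen=True)
class DetectionBox:
    """Pixel-space half-open detection box."""

    label: int
    xmin: float
    ymin: float
    xmax: float
    ymax: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError("degenerate box: need xmin < xmax and ymin < ymax")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")

    @property
    def box(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)


def read_yolo_labels(path, img_width: int, img_height: int) -> list[DetectionBox]:
    """Parse YOLO label text: ``class cx cy w h [confidence]``, normalised."""
    boxes = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        cls = int(parts[0])
        cx, cy, w, h = (float(v) for v in parts[1:5])
        conf = float(parts[5]) if len(parts) > 5 else 1.0
        xmin = (cx - w / 2) * img_width
        xmax = (cx + w / 2) * img_width
        ymin = (cy - h / 2) * img_height
        ymax = (cy + h / 2) * img_height
        boxes.append(DetectionBox(cls, xmin, ymin, xmax, ymax, conf))
    return boxes


def write_yolo_labels(path, boxes, img_width: int, img_height: int, with_confidence=False):
    lines = []
    for b in boxes:
        cx = (b.xmin + b.xmax) / 2 / img_width
        cy = (b.ymin + b.ymax) / 2 / img_height
        w = (b.xmax - b.xmin) / img_width
        h = (b.ymax - b.ymin) / img_height
        line = f"{b.label} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
        if with_confidence:
            line += f" {b.confidence:.4f}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_scene_json(path):
    """Scene JSON: {s, e, obstacle: {w1, w2, h3}, params: {h1, h2, margin}}, mm."""
    d = json.loads(Path(path).read_text())
    s = WorldPoint(*d["s"])
    e = WorldPoint(*d["e"])
    obs = d["obstacle"]
    par = d.get("params", {})
    return (
        s,
        e,
        CropObstacle(obs["w1"], obs["w2"], obs["h3"]),
        TrajectoryParams(
            ascent_h1=par.get("h1", 20.0),
            transition_h2=par.get("h2", 150.0),
            clearance_margin=par.get("margin", 0.0),
        ),
    )


def write_scene_json(path, s: WorldPoint, e: WorldPoint, obs: CropObstacle, params: TrajectoryParams):
    d = {
        "s": [s.x, s.y, s.z],
        "e": [e.x, e.y, e.z],
        "obstacle": {"w1": obs.standoff_w1, "w2": obs.radius_w2, "h3": obs.height_h3},
        "params": {
            "h1": params.ascent_h1,
            "h2": params.transition_h2,
            "margin": params.clearance_margin,
        },
    }
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def write_trajectory_csv(path, traj: ArchTrajectory) -> None:
    """Columns: phase, t, u_mm, z_mm, x_mm, y_mm (world frame if embedded)."""
    world = traj.world_polyline() if traj.embedding is not None else None
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["phase", "t", "u_mm", "z_mm", "x_mm", "y_mm"])
        for name, start, stop in traj.phases:
            n = stop - start
            for k in range(n):
                i = start + k
                t = k / (n - 1) if n > 1 else 0.0
                u, z = traj.polyline[i]
                if world is not None:
                    x, y = world[i, 0], world[i, 1]
                else:
                    x, y = u, 0.0
                w.writerow([name, f"{t:.6f}", f"{u:.4f}", f"{z:.4f}", f"{x:.4f}", f"{y:.4f}"])


def write_joint_csv(path, points, angles: np.ndarray, deltas: np.ndarray) -> None:
    """Columns: step, x, y, z, theta1..3, dtheta1..3 (radians)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["step", "x_mm", "y_mm", "z_mm", "theta1", "theta2", "theta3", "dtheta1", "dtheta2", "dtheta3"]
        )
        for i, p in enumerate(points):
            d = deltas[i - 1] if i > 0 else np.zeros(3)
            w.writerow(
                [i, f"{p.x:.4f}", f"{p.y:.4f}", f"{p.z:.4f}"]
                + [f"{v:.8f}" for v in angles[i]]
                + [f"{v:.8f}" for v in d]
            )
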