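"""Turn a planned arch into Delta-arm joint commands.

Builds the benchmark arch, embeds it on a ground plane 520 mm below the arm
base, discretises it into 100 equal-arc-length waypoints, and solves the
inverse kinematics per waypoint; motors consume the per-step joint-angle
differences.
"""

import numpy as np

from radixweed.delta import DeltaGeometry, discretize, joint_deltas
from radixweed.geometry import PlanarPoint, WorldPoint, build_arch, plane_embedding
from radixweed.synth import reference_scene

_, _, obstacle, params = reference_scene()
traj = build_arch(PlanarPoint(0, 0), PlanarPoint(200, 0), obstacle, params, 30.0, 20.0)
emb = plane_embedding(WorldPoint(-100, 0, -520), WorldPoint(100, 0, -520))
traj = traj.with_embedding(emb)

points = discretize(traj, n=100)
angles, deltas = joint_deltas(points, DeltaGeometry())

print(f"waypoints: {len(points)}, first {points[0]}, last {points[-1]}")
print(f"net joint rotation (deg): {np.rad2deg(angles[-1] - angles[0]).round(2)}")
print(f"largest per-step joint change (deg): {np.rad2deg(np.abs(deltas).max()):.3f}")
# small per-step deltas (well under 10 degrees) show the solution stays on
# one elbow branch along the whole trajectory - no configuration flips.
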