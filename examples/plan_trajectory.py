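"""Plan the seedling-avoidance arch for the benchmark scene.

Two weeds 200 mm apart, a 150 mm tall crop cylinder (radius 40 mm, axis
100 mm from the start point) between them, planning height 170 mm.  The
particle swarm (5 particles, 200 iterations) searches the two Bezier
control offsets for the shortest clearance-feasible path.
"""

from radixweed.geometry import PlanarPoint, check_clearance, plane_embedding
from radixweed.pso import Scene, SwarmConfig, optimize_transition
from radixweed.synth import reference_scene

s3, e3, obstacle, params = reference_scene()
emb = plane_embedding(s3, e3)
L = emb.to_plane(e3).u

scene = Scene(s=PlanarPoint(0, 0), e=PlanarPoint(L, 0), obstacle=obstacle, params=params)
result = optimize_transition(scene, SwarmConfig(n_particles=5, n_max=200, seed=1))
report = check_clearance(result.trajectory, obstacle)

print(f"scene: |SE| = {L:.0f} mm, crop h3 = {obstacle.height_h3:.0f} mm, "
      f"apex = {params.apex:.0f} mm")
print(f"best control offsets: alpha = {result.alpha:.2f} mm, beta = {result.beta:.2f} mm")
print(f"path length (PSO fitness): {result.fitness:.2f} mm")
print(f"clearance margin over the crop footprint: {report.min_margin:.1f} mm")
# alpha = beta = 0 is optimal here: every offset in bounds already clears the
# crop, so the swarm simply drives toward the shortest (straightest) transitions;
# a positive margin means the arch passes that many mm above the plant top.
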