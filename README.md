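# radixweed

Planning and perception primitives for an intra-row precision-weeding robot:
a camera looks straight down at a crop row, classical colour segmentation
finds the weeds between the seedlings, a particle swarm plans a short
seedling-clearing arch between consecutive weeds, and a Delta parallel arm
executes the arch as a sequence of joint-angle commands.

## The problem and the model

A laser weeding end-effector must visit every weed in a row without touching
the crop seedlings growing between them. For each pair of consecutive weed
positions `S` and `E` (both on the ground), the tool plans a path in the
vertical plane through `S` and `E`:

1. **Vertical ascent** from `S` to `P0 = (0, h1)`.
2. **Cubic Bezier rise** from `P0` to `P3 = (w1, h1 + h2)`, where `w1` is the
   horizontal standoff to the nearest crop plant and `h1 + h2` is the apex
   height. Two free offsets shape the curve: `alpha` lifts the first control
   point `P1 = (0, h1 + alpha)` and `beta` pulls the second control point
   `P2 = (w1 - beta, h1 + h2)` back toward `S`.
3. **Horizontal pass** at the apex over the crop plant, modelled as a
   vertical cylinder of radius `w2` and height `h3`.
4. A **mirrored Bezier descent** and a final **vertical drop** to `E`.

The result is an ∩-shaped arch. A candidate `(alpha, beta)` is *feasible*
when the arch stays at least a safety margin above `h3` everywhere over the
cylinder's footprint; the planner minimises arc length over the feasible
set with a small particle swarm (5 particles, 200 iterations, inertia 0.7,
both acceleration coefficients 1.5) whose position update is damped by an
adaptive factor `r(n) = 1 - tanh(n / (1 + n_max))` that decays from 1 toward
~0.24 as iterations progress.

Weeds are found by classical colour segmentation: excess-green index
`ExG = 2G - R - B`, Otsu's threshold on the normalised index, a 3×3
morphological opening, and removal of connected components smaller than a
minimum connected domain size (MCDS, default 50 px). Detected crop boxes are
masked out first so only inter-plant vegetation survives.

The arch is discretised into equal-arc-length waypoints and converted to
joint angles of a three-arm Delta robot by closed-form inverse kinematics;
motors consume the per-step angle differences.

## Worked example

`examples/plan_trajectory.py` plans the benchmark scene — two weeds 200 mm
apart with a 150 mm tall, 40 mm radius crop cylinder standing 60 mm from the
start point, apex height 170 mm:

```text
scene: |SE| = 200 mm, crop h3 = 150 mm, apex = 170 mm
best control offsets: alpha = 0.00 mm, beta = 0.00 mm
path length (PSO fitness): 443.11 mm
clearance margin over the crop footprint: 20.0 mm
```

Because the apex already clears the plant for every in-bound offset, the
swarm converges to the straightest transitions (`alpha = beta = 0`) and the
443.11 mm length matches an exhaustive grid search over the offset box.

`examples/segment_field.py` segments a synthetic 1200×1200 field frame with
30 weed blobs and 4 crop plants:

```text
weeds drawn: 30, components reported: 30
recovered (centroid within 3 px): 30 -> recall 100.0%
first weed: centroid px (39.504731861198735, 1168.589905362776), area 317 px
```

`examples/joint_commands.py` turns an arch (with non-zero offsets
`alpha = 30`, `beta = 20`) into 100 Delta-arm waypoints on a ground plane
520 mm below the base:

```text
waypoints: 100, first WorldPoint(x=-100.0, y=0.0, z=-520.0), last WorldPoint(x=100.0, y=0.0, z=-520.0)
net joint rotation (deg): [-33.42  16.9   16.9 ]
largest per-step joint change (deg): 1.420
```

The other examples (`evaluate_detections.py`, `full_pipeline.py`) exercise
the detection metrics and the end-to-end image → report pipeline.

## Command-line tool

The `radixweed` CLI wraps the library:

```bash
radixweed synth --seed 7 --out scene/          # ground-truthed field image
radixweed segment scene/field.png --boxes scene/crops.txt --out weeds.json
radixweed plan --scene scene/scene.json --out plan/
radixweed evaluate --pred preds/ --gt labels/ --out metrics.json
radixweed run --image scene/field.png --boxes scene/crops.txt --out run/
```

`run` writes `report.json` plus per-cycle trajectory and joint CSVs. Cycles
whose waypoints fall outside the Delta arm's workspace are still planned and
reported, but flagged with `joints_written: false` and a warning — supply a
camera calibration in the pipeline YAML (`mm_per_px`, `camera_origin_world`)
that maps the frame into the arm's reach for real hardware.

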