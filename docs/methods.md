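# Methods

This note records the model implemented by `radixweed`, the parameter
choices with their rationale, what the synthetic generators do and do not
emulate, and the package's numerical choices and limitations.

## 1. Trajectory model

All planning happens in the vertical plane `N` through the start weed `S`
and end weed `E`, both assumed to lie on the same ground plane (`z = 0` in
plane coordinates `(u, z)`; an embedding maps plane coordinates back to
world coordinates). The ∩-type arch consists of five pieces:

| phase     | from            | to                    |
|-----------|-----------------|-----------------------|
| ascent    | `S = (0, 0)`    | `P0 = (0, h1)`        |
| rise      | cubic Bezier `P0 P1 P2 P3`, `P3 = (w1, H)` |
| apex pass | `P3`            | `P4 = (L - w1, H)`    |
| descent   | cubic Bezier mirroring the rise |
| drop      | `P5 = (L, h1)`  | `E = (L, 0)`          |

with `L = |SE|`, apex height `H = h1 + h2`, and control points

- `P1 = (0, h1 + alpha)` — vertically above `P0`; `0 ≤ alpha ≤ 0.8·h2`;
- `P2 = (w1 - beta, H)` — pulled horizontally back from `P3`;
  `0 ≤ beta ≤ 0.8·(w1 + w2)`.

`P4` is the mirror image of `P3` about the midpoint of `SE`, and the
descent Bezier mirrors the rise (`Q1 = (L - w1 + beta, H)`,
`Q2 = (L, h1 + alpha)`). This makes the arch mirror-symmetric for any `L`
and any crop position, so only two scalars are optimised. The 0.8 bound
factors keep the control polygon strictly inside the scene box and prevent
degenerate self-intersecting curves.

The crop plant between the two weeds is a vertical cylinder: standoff `w1`
(horizontal distance from `S` to the near edge), radius `w2`, height `h3`.
A candidate arch is *feasible* when its minimum height over the cylinder
footprint `[w1, w1 + 2·w2]` is at least `h3 + margin` (default margin
20 mm). Feasibility is checked on a dense polyline sample of the arch.

### Default planning parameters

| symbol | default | unit | rationale |
|--------|---------|------|-----------|
| `h1`   | 20   | mm | short vertical lift before curving; keeps the nozzle clear of soil clods while leaving most of the 170 mm apex budget to the Bezier rise |
| `h2`   | 150  | mm | Bezier rise so that `h1 + h2 = 170` mm, 20 mm above the tallest modelled seedling (`h3 = 150` mm) |
| `w1`   | 60   | mm | reference crop standoff |
| `w2`   | 40   | mm | reference crop radius |
| `h3`   | 150  | mm | reference seedling height |
| margin | 20   | mm | safety clearance above the seedling top |

`reference_scene()` packages these together with `|SE| = 200` mm, a
symmetric benchmark on which the optimal offsets are `(0, 0)` with arc
length 443.109888… mm (verified against an exhaustive grid search).

## 2. Swarm optimiser

Standard global-best PSO over the box `[0, 0.8·h2] × [0, 0.8·(w1+w2))]`:

```
v ← ω·v + c1·R1·(pbest − x) + c2·R2·(gbest − x)
x ← x + r(n)·v,    r(n) = 1 − tanh(n / (1 + n_max))
```

with ω = 0.7, c1 = c2 = 1.5, 5 particles, 200 iterations. The adaptive
factor `r` starts at 1 and decays to ≈ 0.2405 at the final iteration,
shrinking step sizes for late-stage refinement. Positions are clipped to
the box and the corresponding velocity component zeroed. Infeasible
candidates receive a 10⁶ mm penalty added to the arc length, so any
feasible arch dominates every infeasible one. `optimize_transition` raises
if the best particle is still infeasible after the budget. `grid_oracle`
(resolution ≥ 20 per axis) provides an exhaustive check used throughout the
tests; on randomised scenes the swarm lands within 1% of the grid optimum.

## 3. Weed segmentation

Chain on an RGB frame, crop boxes masked to black first:

1. `ExG = 2G − R − B` per pixel (int16, range −510…510);
2. min-max normalisation to uint8 and Otsu's between-class-variance
   threshold; foreground is strictly above the threshold;
3. **greenness floor**: a pixel is only foreground if its *raw* ExG is
   positive. Otsu always splits a histogram, even on a frame with no
   vegetation; the floor expresses the physical premise that vegetation is
   greener than soil, and turns "no green pixels" into "no detections"
   instead of hallucinated components;
4. morphological opening with a 3×3 cross structuring element (one erosion,
   one dilation) to cut pixel bridges and specks;
5. 8-connected component labelling; components with area below the minimum
   connected domain size (MCDS, default 50 px, inclusive `area ≥ mcds`) are
   discarded. MCDS trades small-weed recall against noise-blob precision.

Each surviving component becomes a weed record with pixel centroid, area,
and an axis-aligned (or optionally minimum-area rotated) bounding
rectangle. A pinhole-free affine calibration (`mm_per_px`, camera origin in
the robot frame, optional row-advance offset) converts pixel centroids to
robot-frame millimetres.

## 4. Detection metrics

Boxes are half-open pixel rectangles. Matching is greedy in descending
confidence; a prediction matches the free ground-truth box of highest IoU
if that IoU meets the threshold (default 0.5). Precision and recall are
percentages; displayed values use round-half-up to one decimal. Average
precision uses the all-point interpolation (precision envelope integrated
over recall); mAP averages AP over a threshold list. `augmented_count(n, k)
= n·(1 + k)` models offline augmentation that adds `k` variants per image.

## 5. Delta arm

Three-arm Delta robot, base joints at azimuths 0°/120°/240°. Defaults:
base radius 150 mm, platform radius 50 mm, upper arm 200 mm, forearm
400 mm. Inverse kinematics rotates the target into each arm's frame and
solves `a·cosθ − b·sinθ = k` in closed form, taking the knee-out branch
(`θ = −acos(k/ρ) − atan2(b, a)`), which keeps the elbow outside the work
volume and varies smoothly along trajectories. Forward kinematics solves
the three-sphere intersection (two plane equations by least squares plus
the null direction, taking the lower root) and is used as a round-trip
oracle in the tests (|FK(IK(p)) − p| < 10⁻⁶ mm).

The ground plane sits 520 mm below the base plane by default: with the
default link lengths, 600 mm is outside the reachable volume (the IK
discriminant goes negative at full extension), while 520 mm leaves reach
both at the apex and at the ground. Trajectories are discretised into
`n = 100` waypoints equally spaced in arc length (cumulative chord length
plus linear interpolation on a dense polyline); joint commands are the
per-step differences of the IK angles.

## 6. Synthetic scene generators

`gen_field_image` emulates a nadir frame of a crop row: brown soil
(RGB (130, 85, 60), ExG = −20) with ±12 uniform noise, 30 irregular green
weed blobs of 100–900 px (ellipses with harmonic radius wobble), and 4
larger crop plants (1500–4000 px). Blob colours are sampled so that blob
ExG exceeds soil ExG by a contrast (default 60) plus three noise standard
deviations, guaranteeing the vegetation-vs-soil premise the segmentation
chain assumes. Ground truth (centroids, areas, boxes) is taken from the
masks exactly as drawn, so segmentation error is attributable to the chain,
not to label noise. The generator does **not** emulate: shadows and
specular highlights, overlapping or touching plants, motion blur, colour
variation within a plant, perspective distortion, or partially green soil
(algae, residue). Reported recall is therefore an upper bound relative to
field imagery.

`gen_spray_scene` samples planning scenes (weed pair 200–400 mm apart,
`w1` 30–80 mm, `w2` 20–60 mm, `h3` 100–160 mm) that are feasible by
construction, resampling otherwise. `gen_detection_tables` lays out
non-overlapping ground-truth and prediction boxes on a grid reproducing
requested TP/FP/FN counts, for metric verification.

## 7. Numerical choices

- Arc length is the chord sum of a dense polyline (default 200 samples per
  Bezier); refining the sampling changes the length by < 0.1%.
- Bezier curvature is computed from exact analytic derivatives; a zero-speed
  point raises rather than returning a garbage value.
- Seeds are plain integers; derived per-image / per-cycle seeds are reduced
  modulo 2³¹ so they stay valid for every RNG backend.
- All percent displays use `decimal.Decimal` with round-half-up, avoiding
  banker's-rounding surprises at `.x5` boundaries.

## 8. Limitations

- The crop model is a single upright cylinder per transition; sprawling or
  leaning plants and multiple plants between one weed pair are out of
  scope (the pipeline picks the crop nearest the transition's chord).
- The planner optimises geometry only; no dynamics, jerk limits, or
  spray-timing constraints.
- Segmentation is colour-only and will fail on green-on-green scenes
  (grass-like weeds inside crop canopies); crop suppression relies on an
  upstream detector's boxes being correct.
- The camera model is a pure scale-and-offset; lens distortion and
  perspective are assumed to be corrected upstream.
- The pipeline plans cycles even when they exceed the arm's workspace and
  flags them (`joints_written: false`) instead of failing, leaving workspace
  layout to the deployment's calibration.
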