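import math

import numpy as np
import pytest
from shapely.geometry import MultiPoint, Point

from radixweed.geometry import (
    ArchTrajectory,
    BezierSegment,
    CropObstacle,
    PlanarPoint,
    TrajectoryParams,
    WorldPoint,
    bezier_curvature,
    build_arch,
    check_clearance,
    eval_cubic_bezier,
    path_length,
    plane_embedding,
)


def seg(*pts) -> BezierSegment:
    return BezierSegment(*(PlanarPoint(u, z) for u, z in pts))


UNIT_ARCH = seg((0, 0), (0, 1), (1, 1), (1, 0))


class TestCubicBezier:
    def test_endpoint_interpolation_is_exact(self):
        s = seg((0.1, 0.2), (5, 7), (-3, 2), (9.5, -1.25))
        assert eval_cubic_bezier(s, 0.0) == s.p0
        assert eval_cubic_bezier(s, 1.0) == s.p3

    def test_midpoint_matches_hand_expansion(self):
        # weights at t=0.5 are 1/8, 3/8, 3/8, 1/8
        p = eval_cubic_bezier(UNIT_ARCH, 0.5)
        assert p.u == pytest.approx(0.5, abs=1e-12)
        assert p.z == pytest.approx(0.75, abs=1e-12)

    @pytest.mark.parametrize("t", [-0.01, 1.01, 5.0])
    def test_t_outside_unit_interval_rejected(self, t):
        with pytest.raises(ValueError):
            eval_cubic_bezier(UNIT_ARCH, t)

    def test_samples_stay_in_control_point_convex_hull(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            pts = rng.uniform(-10, 10, size=(4, 2))
            s = seg(*pts)
            hull = MultiPoint([tuple(p) for p in pts]).convex_hull.buffer(1e-9)
            for t in np.linspace(0, 1, 41):
                b = eval_cubic_bezier(s, float(t))
                assert hull.contains(Point(b.u, b.z))


class TestCurvature:
    def test_straight_segment_has_zero_curvature(self):
        line = seg((0, 0), (1, 1), (2, 2), (3, 3))
        for t in np.linspace(0, 1, 11):
            assert bezier_curvature(line, float(t)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_finite_difference_oracle(self):
        h = 1e-5
        for t in np.linspace(0.1, 0.9, 9):
            pts = [eval_cubic_bezier(UNIT_ARCH, float(t + k * h)) for k in (-1, 0, 1)]
            d1 = np.array([(pts[2].u - pts[0].u) / (2 * h), (pts[2].z - pts[0].z) / (2 * h)])
            d2 = np.array(
                [
                    (pts[2].u - 2 * pts[1].u + pts[0].u) / h**2,
                    (pts[2].z - 2 * pts[1].z + pts[0].z) / h**2,
                ]
            )
            k_fd = abs(d1[0] * d2[1] - d2[0] * d1[1]) / (d1 @ d1) ** 1.5
            assert bezier_curvature(UNIT_ARCH, float(t)) == pytest.approx(k_fd, rel=1e-6)

    def test_quarter_circle_approximation_curvature(self):
        # the classic c = 0.5523 cubic approximates a quarter circle to a
        # radial error of ~0.03%, but its curvature (a second-derivative
        # quantity) deviates more: ~0.6% at the midpoint, ~2% at the ends
        R, c = 100.0, 0.5523
        quarter = seg((R, 0), (R, c * R), (c * R, R), (0, R))
        assert bezier_curvature(quarter, 0.5) == pytest.approx(1 / R, rel=0.01)

    def test_degenerate_segment_raises(self):
        point = seg((1, 1), (1, 1), (1, 1), (1, 1))
        with pytest.raises(ZeroDivisionError):
            bezier_curvature(point, 0.0)


OBS = CropObstacle(standoff_w1=60.0, radius_w2=40.0, height_h3=150.0)
PARAMS = TrajectoryParams(ascent_h1=20.0, transition_h2=150.0)


def arch(L=200.0, alpha=0.0, beta=0.0, obs=OBS, params=PARAMS) -> ArchTrajectory:
    return build_arch(PlanarPoint(0, 0), PlanarPoint(L, 0), obs, params, alpha, beta)


class TestBuildArch:
    def test_zero_offsets_still_interpolate_endpoints(self):
        t = arch(alpha=0.0, beta=0.0)
        b = t.bezier_up
        assert b.p1 == b.p0 and b.p2 == b.p3
        assert eval_cubic_bezier(b, 0.0) == b.p0
        assert eval_cubic_bezier(b, 1.0) == b.p3

    def test_polyline_spans_s_to_e_and_phases_are_continuous(self):
        t = arch(alpha=50.0, beta=30.0)
        assert np.allclose(t.polyline[0], [0, 0])
        assert np.allclose(t.polyline[-1], [200, 0])
        # consecutive phase slices share their junction sample
        gaps = np.linalg.norm(np.diff(t.polyline, axis=0), axis=1)
        assert gaps.max() < 81.0  # horizontal phase is one 80 mm chord

    def test_symmetric_scene_polyline_is_mirror_symmetric(self):
        for u_clear in (0.0, 37.0, 120.0):
            L = 2 * (OBS.standoff_w1 + OBS.radius_w2) + u_clear
            t = arch(L=L, alpha=40.0, beta=25.0)
            mirrored = np.column_stack([L - t.polyline[::-1, 0], t.polyline[::-1, 1]])
            assert np.allclose(t.polyline, mirrored, atol=1e-9)

    def test_benchmark_scene_apex_height(self):
        t = arch()
        assert t.apex_z == pytest.approx(170.0)
        assert t.polyline[:, 1].max() == pytest.approx(170.0, abs=1e-9)

    def test_horizontal_phase_at_apex(self):
        t = arch(alpha=30.0, beta=20.0)
        (name, start, stop) = t.phases[2]
        assert name == "horizontal"
        assert np.allclose(t.polyline[start:stop, 1], 170.0)

    @pytest.mark.parametrize(
        "alpha,beta", [(-1.0, 0.0), (0.8 * 150 + 1, 0.0), (0.0, -2.0), (0.0, 0.8 * 100 + 1)]
    )
    def test_out_of_bound_offsets_rejected(self, alpha, beta):
        with pytest.raises(ValueError):
            arch(alpha=alpha, beta=beta)

    def test_apex_not_above_obstacle_is_infeasible(self):
        tall = CropObstacle(60.0, 40.0, 171.0)
        with pytest.raises(ValueError, match="infeasible"):
            arch(obs=tall)

    def test_endpoints_off_ground_rejected(self):
        with pytest.raises(ValueError):
            build_arch(PlanarPoint(0, 5), PlanarPoint(200, 0), OBS, PARAMS, 0, 0)


class TestPathLength:
    def test_at_least_straight_line_distance(self):
        t = arch(alpha=60.0, beta=40.0)
        assert path_length(t) >= 200.0

    def test_refinement_changes_length_below_point1_percent(self):
        coarse = arch(alpha=60.0, beta=40.0)
        fine = arch(
            alpha=60.0,
            beta=40.0,
            params=TrajectoryParams(20.0, 150.0, samples_per_segment=400),
        )
        assert abs(path_length(fine) - path_length(coarse)) / path_length(fine) < 1e-3

    def test_invariant_under_plane_embedding(self):
        t = arch(alpha=45.0, beta=33.0)
        emb = plane_embedding(WorldPoint(12, -7, 3), WorldPoint(12 + 200 / math.sqrt(2), -7 + 200 / math.sqrt(2), 3))
        t3 = t.with_embedding(emb)
        world = t3.world_polyline()
        len3d = float(np.sum(np.linalg.norm(np.diff(world, axis=0), axis=1)))
        assert len3d == pytest.approx(path_length(t), abs=1e-9)


class TestClearance:
    def test_benchmark_scene_is_feasible(self):
        rep = check_clearance(arch(alpha=40.0, beta=30.0), OBS)
        assert rep.feasible
        assert rep.min_margin >= 0

    def test_obstacle_taller_than_apex_is_infeasible(self):
        tall = CropObstacle(60.0, 40.0, 171.0)
        t = arch()  # built against the shorter obstacle
        assert not check_clearance(t, tall).feasible

    def test_margin_boundary_bisection(self):
        t = arch(alpha=40.0, beta=30.0)
        achieved = check_clearance(t, OBS).min_z_over_footprint - OBS.height_h3
        assert check_clearance(t, OBS, margin=achieved).feasible
        assert not check_clearance(t, OBS, margin=achieved + 1e-9).feasible

    def test_footprint_outside_span_flagged_trivially_feasible(self):
        far = CropObstacle(standoff_w1=500.0, radius_w2=40.0, height_h3=150.0)
        rep = check_clearance(arch(), far)
        assert rep.feasible and rep.footprint_outside_span

    def test_min_margin_non_decreasing_in_alpha(self):
        # raising the first control point can only lift the curve over the crop
        betas = [0.0, 30.0, 60.0]
        for beta in betas:
            margins = [
                check_clearance(arch(alpha=a, beta=beta), OBS).min_margin
                for a in np.linspace(0, 120, 13)
            ]
            assert all(m2 >= m1 - 1e-9 for m1, m2 in zip(margins, margins[1:]))


class TestPlaneEmbedding:
    def test_axis_aligned_scene_is_identity_like(self):
        emb = plane_embedding(WorldPoint(0, 0, 0), WorldPoint(300, 0, 0))
        e = emb.to_plane(WorldPoint(300, 0, 0))
        assert (e.u, e.z) == pytest.approx((300.0, 0.0), abs=1e-12)

    def test_rotated_scene_maps_e_onto_u_axis(self):
        emb = plane_embedding(WorldPoint(0, 0, 0), WorldPoint(0, 300, 0))
        e = emb.to_plane(WorldPoint(0, 300, 0))
        assert (e.u, e.z) == pytest.approx((300.0, 0.0), abs=1e-9)
        back = emb.to_world(PlanarPoint(300.0, 0.0))
        assert np.allclose(back.as_array(), [0, 300, 0], atol=1e-9)

    def test_distance_preservation_and_round_trip_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            s = WorldPoint(*rng.uniform(-500, 500, 2), rng.uniform(0, 50))
            d = rng.uniform(10, 600, 2)
            e = WorldPoint(s.x + d[0], s.y + d[1], s.z)
            emb = plane_embedding(s, e)
            pe = emb.to_plane(e)
            assert abs(pe.u - math.hypot(d[0], d[1])) < 1e-9
            q = PlanarPoint(rng.uniform(0, 500), rng.uniform(0, 200))
            rt = emb.to_plane(emb.to_world(q))
            assert (rt.u, rt.z) == pytest.approx((q.u, q.z), abs=1e-9)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(ValueError):
            plane_embedding(WorldPoint(1, 2, 0), WorldPoint(1, 2, 0))
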