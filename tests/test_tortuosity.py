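import numpy as np
import pytest

import corochar as cc
from corochar.centerline import CenterlineBranch, branch_from_points
from corochar.phantom import analytic_tortuosity, sample_centerline
from corochar.tortuosity import (
    Bend,
    TortuosityParams,
    TortuosityProfile,
    compute_profile,
    detect_bends,
    local_tortuosity,
    tortuosity_angle,
    tortuosity_score,
    tract_tortuosity,
)


def straight_branch(length_mm=60.0, step=0.5):
    n = int(length_mm / step) + 1
    pts = np.column_stack([np.linspace(0, length_mm, n), np.zeros(n), np.zeros(n)])
    return branch_from_points(pts, resample_mm=step)


def analytic_branch(spec, step=0.5):
    pts, _, _ = sample_centerline(spec, step=0.1)
    return branch_from_points(pts, resample_mm=step)


def vertex_branch(angle_deg, arm_mm=15.0, step=0.25):
    """Two straight arms meeting at the origin with the given direction change."""
    a = np.deg2rad(angle_deg)
    d1 = np.array([1.0, 0.0, 0.0])
    d2 = np.array([np.cos(a), np.sin(a), 0.0])
    n = int(arm_mm / step)
    up = (-arm_mm + np.arange(n + 1) * step)[:, None] * d1
    dw = (np.arange(1, n + 1) * step)[:, None] * d2
    return branch_from_points(np.vstack([up, dw]), resample_mm=step)


class TestLocalTortuosity:
    def test_straight_branch_is_one_everywhere(self):
        br = straight_branch()
        prof = compute_profile(br)
        assert np.all(prof.valid[11:-11])
        assert np.allclose(prof.lt[prof.valid], 1.0, atol=1e-9)

    def test_circular_arc_matches_closed_form(self):
        spec = cc.VesselSpec(kind="circular_arc", arc_radius_mm=10.0,
                             arc_angle_deg=180.0)
        br = analytic_branch(spec)
        i = len(br.points) // 2
        assert local_tortuosity(br, i) == pytest.approx(
            analytic_tortuosity(spec, 10.0), abs=0.01)

    def test_helix_matches_closed_form(self):
        spec = cc.VesselSpec(kind="helix", helix_radius_mm=6.0,
                             helix_pitch_mm=12.0, turns=2.0)
        br = analytic_branch(spec)
        i = len(br.points) // 2
        assert local_tortuosity(br, i) == pytest.approx(
            analytic_tortuosity(spec, 10.0), rel=0.01)

    def test_window_beyond_branch_flagged_invalid(self):
        br = straight_branch(length_mm=20.0)
        prof = compute_profile(br)
        assert not prof.valid[0] and not prof.valid[-1]
        assert np.isnan(prof.lt[0])

    def test_lt_never_below_one(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(0.3, 0.1, (200, 3)), axis=0)
        prof = compute_profile(branch_from_points(pts))
        assert np.all(prof.lt[prof.valid] >= 1.0 - 1e-9)


class TestTortuosityAngle:
    def test_straight_branch_zero(self):
        br = straight_branch()
        prof = compute_profile(br)
        assert np.allclose(prof.ta_deg[prof.valid], 0.0, atol=1e-6)

    @pytest.mark.parametrize("angle", [30.0, 60.0, 90.0])
    def test_polyline_vertex_recovers_direction_change(self, angle):
        br = vertex_branch(angle)
        i = int(np.argmin(np.abs(br.abscissa - 15.0)))  # the vertex
        assert tortuosity_angle(br, i) == pytest.approx(angle, abs=2.0)

    def test_smooth_arc_center_equals_half_window_rotation(self):
        # each half-arc's fitted line is the tangent at its own midpoint, so
        # the angle between them equals the rotation across half the window
        spec = cc.VesselSpec(kind="circular_arc", arc_radius_mm=10.0,
                             arc_angle_deg=180.0)
        br = analytic_branch(spec)
        i = len(br.points) // 2
        expected = np.degrees(5.0 / 10.0)  # (window/2) / R
        assert tortuosity_angle(br, i) == pytest.approx(expected, abs=2.0)

    def test_rigid_motion_invariance(self):
        spec = cc.make_bent_branch([55.0, 40.0], 25.0)
        pts, _, _ = sample_centerline(spec, step=0.1)
        base = compute_profile(branch_from_points(pts))
        rng = np.random.default_rng(11)
        for _ in range(3):
            q = rng.normal(size=(3, 3))
            rot, _ = np.linalg.qr(q)
            if np.linalg.det(rot) < 0:
                rot[:, 0] *= -1
            moved = pts @ rot.T + rng.normal(0, 40, 3)
            prof = compute_profile(branch_from_points(moved))
            m = base.valid & prof.valid
            assert np.allclose(prof.ta_deg[m], base.ta_deg[m], atol=1e-6)


class TestBends:
    def test_three_50_degree_bends_detected(self):
        spec = cc.make_bent_branch([50.0, 50.0, 50.0], 25.0)
        br = analytic_branch(spec, step=0.5)
        bends = detect_bends(compute_profile(br), br)
        assert len(bends) == 3
        for b in bends:
            assert b.angle_deg == pytest.approx(50.0, abs=3.0)

    def test_sub_threshold_bends_ignored(self):
        spec = cc.make_bent_branch([30.0, 30.0], 25.0)
        br = analytic_branch(spec, step=0.5)
        assert detect_bends(compute_profile(br), br) == []

    def test_exact_threshold_counts(self):
        # a run with TA exactly 45.0 is a bend
        n = 60
        ta = np.zeros(n)
        ta[25:30] = 45.0
        prof = TortuosityProfile(lt=np.ones(n), ta_deg=ta, valid=np.ones(n, bool))
        br = CenterlineBranch(points=np.zeros((n, 3)),
                              abscissa=np.arange(n) * 0.5,
                              g=np.linspace(0, 1, n))
        bends = detect_bends(prof, br)
        assert len(bends) == 1
        assert bends[0].angle_deg == 45.0

    def test_nearby_runs_merge(self):
        n = 100
        ta = np.zeros(n)
        ta[40:44] = 50.0
        ta[46:50] = 55.0  # gap of 1 mm (< 2 mm) at 0.5 mm steps
        ta[70:74] = 60.0  # far away: separate bend
        prof = TortuosityProfile(lt=np.ones(n), ta_deg=ta, valid=np.ones(n, bool))
        br = CenterlineBranch(points=np.zeros((n, 3)),
                              abscissa=np.arange(n) * 0.5,
                              g=np.linspace(0, 1, n))
        bends = detect_bends(prof, br)
        assert [b.angle_deg for b in bends] == [55.0, 60.0]


class TestScoreAndTracts:
    def test_score_counts_branches_with_three_bends(self):
        b = lambda a: Bend(0, a, 0.0, 1.0)
        three = [b(50), b(50), b(50)]
        two = [b(50), b(50)]
        assert tortuosity_score([three] * 4, [60.0] * 4) == 4
        assert tortuosity_score([[], [], []], [60.0] * 3) == 0
        assert tortuosity_score([two, three], [60.0, 60.0]) == 1

    def test_short_branches_excluded(self):
        b = lambda a: Bend(0, a, 0.0, 1.0)
        three = [b(50), b(50), b(50)]
        assert tortuosity_score([three], [15.0]) == 0  # below 20 mm floor

    def test_adding_a_bend_never_decreases_score(self):
        rng = np.random.default_rng(5)
        b = lambda a: Bend(0, a, 0.0, 1.0)
        for _ in range(20):
            bends = [[b(50)] * int(rng.integers(0, 5)) for _ in range(4)]
            lengths = [60.0] * 4
            before = tortuosity_score(bends, lengths)
            k = int(rng.integers(0, 4))
            bends[k] = bends[k] + [b(50)]
            assert tortuosity_score(bends, lengths) >= before

    def test_straight_branch_tract_is_one(self):
        br = straight_branch()
        for zone in ("proximal", "medial", "distal"):
            assert tract_tortuosity(br, zone) == pytest.approx(1.0, abs=1e-9)

    def test_semicircle_tract_is_pi_over_two(self):
        spec = cc.VesselSpec(kind="circular_arc", arc_radius_mm=10.0,
                             arc_angle_deg=180.0)
        pts, _, _ = sample_centerline(spec, step=0.05)
        br = branch_from_points(pts, resample_mm=0.25)
        # whole branch in one "zone": force g inside proximal everywhere
        br.g = np.linspace(0.0, 0.33, len(br.points))
        assert tract_tortuosity(br, "proximal") == pytest.approx(np.pi / 2, abs=0.01)

    def test_single_zone_branch_matches_whole_branch_ratio(self):
        spec = cc.make_bent_branch([50.0], 25.0)
        pts, _, _ = sample_centerline(spec, step=0.1)
        br = branch_from_points(pts)
        br.g = np.linspace(0.34, 0.66, len(br.points))
        whole = br.abscissa[-1] / np.linalg.norm(br.points[-1] - br.points[0])
        assert tract_tortuosity(br, "medial") == pytest.approx(whole, rel=1e-9)

    def test_absent_zone_excluded(self):
        br = straight_branch()
        br.g = np.linspace(0.0, 0.3, len(br.points))  # proximal only
        assert tract_tortuosity(br, "medial") is None


def test_summary_on_tortuous_tree(straight_tree):
    summ = cc.summarize_tortuosity(straight_tree)
    assert summ.ts == 0
    assert summ.severity == "none"
    assert summ.lt_p95 == pytest.approx(1.0, abs=0.02)
    for z in ("proximal", "medial", "distal"):
        assert summ.tract_tortuosity[z] == pytest.approx(1.0, abs=0.01)
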