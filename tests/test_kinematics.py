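"""Wing-motion prescription: closed forms, symmetries, trajectory shapes."""

import numpy as np
import pytest

import flapwing as fw
from flapwing.kinematics import FlappingMotion, PlateGeometry


def _motion(kin=None, side="right"):
    kin = kin or fw.WingKinematics()
    geom = PlateGeometry(chord=1.0, span=2.39 / 0.78, side=side)
    return FlappingMotion(kin, geom)


class TestEulerAngles:
    def test_closed_forms_at_t0(self, default_kinematics):
        tp, tf, te = fw.euler_angles(default_kinematics, 0.0)
        assert tp == pytest.approx(70 * np.cos(np.radians(10)), abs=1e-9)
        assert tf == pytest.approx(0.0, abs=1e-12)
        assert te == pytest.approx(10 * np.cos(np.radians(-10)) + 10, abs=1e-9)

    def test_zero_elevation_amplitude_is_constant(self):
        kin = fw.WingKinematics(amp_elevation=0.0, phase_elevation=0.0)
        t = np.linspace(0, 3 * kin.period, 50)
        _, _, te = fw.euler_angles(kin, t)
        assert np.all(te == 0.0)
        assert not kin.has_figure_eight

    def test_elevation_at_twice_frequency(self, default_kinematics):
        kin = default_kinematics
        t = np.linspace(0, kin.period, 37)
        _, _, te1 = fw.euler_angles(kin, t)
        _, _, te2 = fw.euler_angles(kin, t + kin.period / 2)
        np.testing.assert_allclose(te1, te2, atol=1e-9)

    def test_periodicity(self, default_kinematics):
        kin = default_kinematics
        t = np.linspace(0, kin.period, 13)
        a1 = fw.euler_angles(kin, t)
        a2 = fw.euler_angles(kin, t + 5 * kin.period)
        for x, y in zip(a1, a2):
            np.testing.assert_allclose(x, y, atol=1e-7)

    def test_negative_time_rejected(self, default_kinematics):
        with pytest.raises(ValueError):
            fw.euler_angles(default_kinematics, -0.1)


class TestTransforms:
    def test_zero_angles_give_identity(self):
        kin = fw.WingKinematics(
            amp_positional=0, amp_feathering=0, amp_elevation=0,
            phase_positional=0, phase_feathering=0, phase_elevation=0,
        )
        r = _motion(kin).rotation(0.0)
        np.testing.assert_allclose(r, np.eye(3), atol=1e-12)

    def test_rotation_proper_at_random_times(self, rng):
        m = _motion()
        for t in rng.uniform(0, 5 * m.kin.period, 200):
            r = m.rotation(t)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-10)
            np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-10)

    def test_period_closure(self):
        m = _motion()
        r0, o0 = m.transform(0.2 * m.kin.period)
        r1, o1 = m.transform(1.2 * m.kin.period)
        np.testing.assert_allclose(r0, r1, atol=1e-7)
        np.testing.assert_allclose(o0, o1, atol=1e-12)

    def test_left_right_mirror_symmetry(self):
        tr = _motion(side="right").tip_trajectory(64)
        tl = _motion(side="left").tip_trajectory(64)
        np.testing.assert_allclose(tl, tr * np.array([-1, 1, 1]), atol=1e-12)


class TestWallVelocity:
    def test_static_plate_zero_velocity(self):
        kin = fw.WingKinematics(
            amp_positional=0, amp_feathering=0, amp_elevation=0,
            phase_positional=0, phase_feathering=0, phase_elevation=0,
        )
        m = _motion(kin)
        pts = m.geom.sample_points(4, 3)
        v = m.wall_velocity(0.1, pts)
        np.testing.assert_allclose(v, 0.0, atol=1e-8)

    def test_root_point_is_stationary(self):
        m = _motion()
        v = m.wall_velocity(0.3 * m.kin.period, np.zeros((1, 3)))
        np.testing.assert_allclose(v, 0.0, atol=1e-8)

    def test_finite_difference_step_insensitive(self):
        # halving the differencing step changes nothing at the tolerance level
        m = _motion()
        pts = m.geom.sample_points(3, 2)
        t = 0.37 * m.kin.period
        v1 = m.wall_velocity(t, pts, dt=m.kin.period * 1e-6)
        v2 = m.wall_velocity(t, pts, dt=m.kin.period * 5e-7)
        utip = m.mean_tip_speed(200)
        assert np.abs(v1 - v2).max() < 1e-6 * utip

    def test_mean_tip_speed_matches_reference(self, default_wing):
        # cycle-mean |tip velocity| vs the tabulated mean tip speed (5%)
        m = _motion()
        utip_chords = m.mean_tip_speed()
        utip_m = utip_chords * default_wing.mean_chord
        assert utip_m == pytest.approx(default_wing.utip_bar, rel=0.05)


def _count_self_intersections(curve2d):
    """Brute-force segment-pair intersection count of a closed polyline."""
    pts = np.vstack([curve2d, curve2d[:1]])
    segs = list(zip(pts[:-1], pts[1:]))
    count = 0
    for i in range(len(segs)):
        for j in range(i + 2, len(segs)):
            if i == 0 and j == len(segs) - 1:
                continue
            p, p2 = segs[i]
            q, q2 = segs[j]
            r = p2 - p
            s = q2 - q
            denom = r[0] * s[1] - r[1] * s[0]
            if abs(denom) < 1e-14:
                continue
            qp = q - p
            t = (qp[0] * s[1] - qp[1] * s[0]) / denom
            u = (qp[0] * r[1] - qp[1] * r[0]) / denom
            if 1e-9 < t < 1 - 1e-9 and 1e-9 < u < 1 - 1e-9:
                count += 1
    return count


class TestTipTrajectory:
    def test_rejects_too_few_samples(self):
        with pytest.raises(ValueError):
            _motion().tip_trajectory(7)

    def test_zero_elevation_stays_in_stroke_surface(self):
        kin = fw.WingKinematics(amp_elevation=0.0, phase_elevation=0.0)
        traj = _motion(kin).tip_trajectory(100)
        # tip stays on the sphere's equator plane z = 0
        np.testing.assert_allclose(traj[:, 2], 0.0, atol=1e-12)

    def test_projected_curve_always_revisits_midstroke_point(self):
        # the elevation oscillates at 2f, so the projected curve crosses
        # itself exactly once at stroke angle zero for every initial phase
        kin = fw.WingKinematics(elevation_initial_phase=45.0)
        t = np.arange(400) / 400 * kin.period
        tp, _, te = fw.euler_angles(kin, t)
        assert _count_self_intersections(np.column_stack([tp, te])) == 1

    @pytest.mark.parametrize(
        "phi_e0, expected",
        [(0.0, "U"), (180.0, "U"), (45.0, "eight"), (90.0, "eight"),
         (315.0, "eight")],
    )
    def test_shape_classification(self, phi_e0, expected):
        # U-shaped end-members have the crossing at an elevation extreme;
        # genuine figure-eights cross in the interior of the range
        from flapwing.kinematics import classify_tip_path

        kin = fw.WingKinematics(elevation_initial_phase=phi_e0)
        assert classify_tip_path(kin) == expected

    def test_line_shape_without_elevation(self):
        from flapwing.kinematics import classify_tip_path

        assert classify_tip_path(
            fw.WingKinematics(amp_elevation=0.0, phase_elevation=0.0)
        ) == "line"

    def test_frequency_rescaling_leaves_shape_invariant(self):
        m1 = _motion(fw.WingKinematics(frequency=218.0))
        m2 = _motion(fw.WingKinematics(frequency=109.0))
        np.testing.assert_allclose(
            m1.tip_trajectory(64), m2.tip_trajectory(64), atol=1e-9
        )


class TestReynolds:
    def test_reference_values(self):
        assert fw.reynolds_number(2.58, 0.78e-3, 1.5e-5) == pytest.approx(134, rel=0.01)
        assert fw.reynolds_number(0.645, 0.78e-3, 1.5e-5) == pytest.approx(33.5, rel=0.01)

    def test_linearity_and_validation(self):
        assert fw.reynolds_number(5.16, 0.78e-3, 1.5e-5) == pytest.approx(
            2 * fw.reynolds_number(2.58, 0.78e-3, 1.5e-5)
        )
        with pytest.raises(ValueError):
            fw.reynolds_number(-1.0, 0.78e-3, 1.5e-5)

    def test_physical_wing_invariants(self, default_wing):
        assert default_wing.reynolds == pytest.approx(134, rel=0.01)
        w2 = default_wing.at_reynolds(536.0)
        assert w2.reynolds == pytest.approx(536.0, rel=1e-9)
        assert w2.utip_bar / default_wing.utip_bar == pytest.approx(
            w2.frequency / default_wing.frequency
        )
        with pytest.raises(ValueError):
            fw.PhysicalWing(mean_chord=-1.0)
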