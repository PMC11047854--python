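"""Virtual-flux boundary: geometry, wall pressure, reconstruction physics."""

import numpy as np
import pytest

import flapwing as fw
from flapwing.kinematics import PlateGeometry
from flapwing.solver import FluidBlock, P_REF
from flapwing.simulation import ImmersedPlateSimulation
from flapwing.vfm import (
    boundary_pressure,
    locate_intersections,
    plate_pose,
)


class _Static:
    """Rigid pose: rotation + root fixed in time."""

    period = 1.0

    def __init__(self, r=np.eye(3), root=(0.0, 0.0, 0.0)):
        self.r = np.asarray(r, dtype=float)
        self.root = np.asarray(root, dtype=float)

    def transform(self, t):
        return self.r, self.root


def _tilted(deg):
    a = np.radians(deg)
    return np.array(
        [[np.cos(a), 0, -np.sin(a)], [0, 1, 0], [np.sin(a), 0, np.cos(a)]]
    )


class TestBoundaryPressure:
    def test_constant_field(self):
        assert boundary_pressure(0.37, 0.37, 1.0, 2.0) == pytest.approx(0.37)

    def test_hand_arithmetic(self):
        assert boundary_pressure(1.0, 4.0, 1.0, 2.0) == pytest.approx(0.0)

    def test_quadratic_even_field_exact(self):
        # p(h) = a0 + b0 h^2 satisfies dp/dn = 0 at the wall; the two-probe
        # formula recovers a0 exactly
        a0, b0 = 0.31, 0.07
        for h1, h2 in [(1.0, 2.0), (np.sqrt(3), 2 * np.sqrt(3)), (0.5, 1.7)]:
            p1 = a0 + b0 * h1 ** 2
            p2 = a0 + b0 * h2 ** 2
            assert boundary_pressure(p1, p2, h1, h2) == pytest.approx(a0, abs=1e-14)

    def test_equal_probes_rejected(self):
        with pytest.raises(ValueError):
            boundary_pressure(1.0, 2.0, 1.5, 1.5)


class TestLocateIntersections:
    def test_plate_outside_block_empty(self):
        block = FluidBlock((9, 9, 9), dx=1.0, origin=(0, 0, 0), nu=0.05,
                           periodic=(False,) * 3)
        geom = PlateGeometry(chord=1.0, span=2.0)
        pose = plate_pose(_Static(root=(30.0, 30.0, 30.0)), geom, 0.0)
        cr, _ = locate_intersections(pose, block)
        assert cr.n == 0

    def test_degenerate_plate_rejected(self):
        with pytest.raises(ValueError):
            PlateGeometry(chord=0.0, span=1.0)

    def test_axis_aligned_midplane_gives_half_ratios(self):
        block = FluidBlock((9, 9, 9), dx=1.0, origin=(-4, -4, -4), nu=0.05,
                           periodic=(False,) * 3)
        # plate in the x-y plane at z = 0.5: perpendicular links cut at a=1/2
        r = np.array([[1.0, 0, 0], [0, 0, -1], [0, 1, 0]])
        geom = PlateGeometry(chord=6.0, span=6.0)
        pose = plate_pose(_Static(r, root=(-3.0, 3.0, 0.5)), geom, 0.0)
        cr, _ = locate_intersections(pose, block)
        assert cr.n > 0
        straight = cr.alpha[: cr.n] == int(
            np.flatnonzero((block.lattice.e == [0, 0, 1]).all(axis=1))[0]
        )
        assert straight.any()
        np.testing.assert_allclose(cr.a[: cr.n][straight], 0.5, atol=1e-12)

    def test_crossings_lie_on_rectangle_random_pose(self, rng):
        # independent ray-rectangle oracle re-verifies every returned point
        block = FluidBlock((17, 17, 17), dx=0.5, origin=(-4, -4, -4), nu=0.05,
                           periodic=(False,) * 3)
        for _ in range(5):
            ang = rng.uniform(0, 360, 3)
            rz = fw.kinematics._rot_z(np.radians(ang[0]))
            ry = fw.kinematics._rot_y(np.radians(ang[1]))
            rx = fw.kinematics._rot_x(np.radians(ang[2]))
            pose = plate_pose(
                _Static(rz @ ry @ rx, root=rng.uniform(-1, 1, 3)),
                PlateGeometry(chord=1.3, span=2.1),
                0.0,
            )
            cr, _ = locate_intersections(pose, block)
            assert cr.n > 0
            pts = cr.points
            rel = pts - pose.origin
            s1 = rel @ pose.e1
            s2 = rel @ pose.e2
            dist = rel @ pose.normal
            assert np.abs(dist).max() < 1e-12 * block.dx + 1e-12
            assert (s1 > -1e-9).all() and (s1 < pose.span + 1e-9).all()
            assert (s2 > -1e-9).all() and (s2 < pose.chord + 1e-9).all()
            # each point must also lie on its link segment
            e = block.lattice.e[cr.alpha[: cr.n]].astype(float) * block.dx
            starts = (
                np.column_stack([cr.i, cr.j, cr.k])[: cr.n] * block.dx
                + block.origin
                - np.asarray(block.pad) * block.dx
            )
            t = np.einsum("ij,ij->i", pts - starts, e) / (e ** 2).sum(axis=1)
            assert (t > -1e-9).all() and (t < 1 + 1e-9).all()


class TestReconstruction:
    def _uniform_sim(self, motion, geom, nu=0.02):
        block = FluidBlock((25, 25, 25), dx=0.25, origin=(-3, -3, -3), nu=nu,
                           periodic=(False,) * 3)
        return ImmersedPlateSimulation([block], [(motion, geom)],
                                       dt_seconds=0.01, u_ref=0.05,
                                       area_ref=geom.area)

    def test_rest_plate_preserves_uniform_state(self):
        sim = self._uniform_sim(_Static(_tilted(25), root=(-1, 0, 0.07)),
                                PlateGeometry(chord=1.0, span=2.0))
        for _ in range(60):
            sim.step()
        p, u = sim.fine.macroscopics()
        assert np.abs(u).max() < 1e-13
        np.testing.assert_allclose(p, P_REF, atol=1e-13)

    def test_two_sided_no_leak(self):
        # reservoirs at different pressures separated by a full-span plate
        # stay separated: velocity remains at round-off for 1000 steps
        block = FluidBlock((19, 19, 19), dx=1 / 6, origin=(-1.5, -1.5, -1.5),
                           nu=0.02, periodic=(False,) * 3)
        r = np.array([[1.0, 0, 0], [0, 0, -1], [0, 1, 0]])
        geom = PlateGeometry(chord=8.0, span=8.0)
        motion = _Static(r, root=(-4.0, 0.0, 0.0143))
        full = block.f.shape[:3]
        z = (np.arange(full[2]) - block.pad[2]) * block.dx + block.origin[2]
        p = np.broadcast_to(
            np.where(z[None, None, :] > 0.0143, 0.34, 0.33), full
        ).copy()
        block.initialize(p, np.zeros(full + (3,)))
        sim = ImmersedPlateSimulation([block], [(motion, geom)], 0.01, 0.05, 1.0)
        for _ in range(1000):
            sim.step()
        pp, uu = block.macroscopics()
        assert np.abs(uu).max() < 1e-6
        zi = np.arange(block.shape[2]) * block.dx + block.origin[2]
        assert pp[:, :, zi < 0.0143].mean() == pytest.approx(0.33, abs=1e-6)
        assert pp[:, :, zi > 0.0143].mean() == pytest.approx(0.34, abs=1e-6)

    def test_half_ratio_extrapolation_identity(self, lattice):
        # with a = b = 1/2 the virtual equilibrium at E is 2 peq(vb) - peq(D):
        # cross-checked through the kernel on a single straight link
        from flapwing import _kernels

        block = FluidBlock((9, 9, 9), dx=1.0, origin=(-4, -4, -4), nu=0.05,
                           periodic=(False,) * 3)
        rng = np.random.default_rng(3)
        p = P_REF + rng.uniform(-0.01, 0.01, block.f.shape[:3])
        u = rng.uniform(-0.02, 0.02, block.f.shape[:3] + (3,))
        block.initialize(p, u)
        r = np.array([[1.0, 0, 0], [0, 0, -1], [0, 1, 0]])
        geom = PlateGeometry(chord=6.0, span=6.0)
        pose = plate_pose(_Static(r, root=(-3.0, 3.0, 0.5)), geom, 0.0)
        cr, cut = locate_intersections(pose, block)
        block._update_macro()
        from flapwing.vfm import compute_wall_pressures, reconstruct_boundary_links

        compute_wall_pressures(block, pose, cr)
        block.collide_stream()
        reconstruct_boundary_links(block, pose, cr, cut)
        # pick one straight vertical link with a = 1/2 below the plate
        up = int(np.flatnonzero((lattice.e == [0, 0, 1]).all(axis=1))[0])
        sel = np.flatnonzero(
            (cr.alpha[: cr.n] == up) & (np.abs(cr.a[: cr.n] - 0.5) < 1e-12)
        )
        m = sel[0]
        i, j, k = cr.i[m], cr.j[m], cr.k[m]
        down = lattice.opposite[up]
        w = lattice.w[down]
        e = lattice.e[down].astype(float)
        uvb = np.zeros(3)  # static plate
        peq_vb = w * (cr.pvb[m])
        pD = block._p[i, j, k]
        uD = np.array([block._ux[i, j, k], block._uy[i, j, k], block._uz[i, j, k]])
        eu = e @ uD
        peq_d = w * (pD + eu + 1.5 * eu ** 2 - 0.5 * uD @ uD)
        pneq_d = block.f[i, j, k, down] - peq_d
        expected = (2 * peq_vb - peq_d) + (1 - 1 / block.tau) * pneq_d
        assert block.f_new[i, j, k, down] == pytest.approx(expected, abs=1e-14)

    def test_impulsive_plate_develops_physical_wake(self):
        # broadside impulsive start: near-wall fluid follows the plate on
        # both sides, drag opposes the motion, and pressure is higher ahead
        U = 0.05
        dx, dt = 1 / 16, 0.01

        class Impulsive:
            period = 1.0
            v = U * dx / dt

            def transform(self, t):
                r = np.array([[1.0, 0, 0], [0, 0, -1], [0, 1, 0]])
                return r, np.array([-0.75, 0.5, -0.4 + self.v * t])

        geom = PlateGeometry(chord=1.0, span=1.5)
        block = FluidBlock((49, 49, 49), dx=dx, origin=(-1.5, -1.5, -1.5),
                           nu=0.02, periodic=(False,) * 3)
        sim = ImmersedPlateSimulation([block], [(Impulsive(), geom)],
                                      dt_seconds=dt, u_ref=U, area_ref=1.5)
        for _ in range(100):
            sim.step()
        p, u = block.macroscopics()
        zp = -0.4 + U * dx / dt * sim.time_seconds
        zi = np.arange(block.shape[2]) * dx + block.origin[2]
        ic = jc = block.shape[0] // 2
        behind = np.searchsorted(zi, zp) - 1
        ahead = behind + 1
        # no-penetration: adjacent nodes move with the plate within 25%
        assert u[ic, jc, behind, 2] > 0.7 * U
        assert u[ic, jc, ahead, 2] > 0.5 * U
        # pressure higher ahead of the plate than behind
        assert p[ic, jc, ahead + 1] > p[ic, jc, behind - 1]
        rec = sim.measure()
        assert rec["Fz"] < 0  # drag opposes +z motion
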