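"""Run drivers: immersed flapping plates on a (multi)block lattice.

All lab lengths are measured in mean chords L (the representative length),
so the wing chord is 1.0 and the domain is ``domain_chords`` per side.  The
lattice time step is fixed by the configured representative lattice speed U
(the cycle-mean wing-tip speed in lattice units): with tip path length P_tip
per cycle (in L) and finest spacing dx, one flapping period spans
``round(P_tip / (U dx))`` steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forces import ForceRecord, coefficients, momentum_exchange_force, surface_forces
from .kinematics import (
    FlappingMotion,
    OscillatingPlateMotion,
    PhysicalWing,
    PlateGeometry,
    WingKinematics,
)
from .multiblock import MultiblockSolver, build_layout
from .solver import FluidBlock
from .vfm import (
    Crossings,
    compute_wall_pressures,
    locate_intersections,
    plate_pose,
    reconstruct_boundary_links,
)

__all__ = [
    "ImmersedPlateSimulation",
    "hover_simulation",
    "oscillating_plate_simulation",
    "steps_per_cycle",
]


def steps_per_cycle(motion: FlappingMotion, resolution: int, u_lattice: float) -> int:
    """Lattice steps per flapping period on the finest tier.

    ``round(P_tip / (U dx))`` with the tip path length P_tip per cycle in
    chord units and ``dx = 1/resolution``.
    """
    p_tip = motion.tip_path_length() / 1.0  # already in chord units
    return int(round(p_tip * resolution / u_lattice))


@dataclass
class _Plate:
    motion: object
    geom: PlateGeometry
    crossings: Crossings | None = None
    pose: object | None = None
    pose_lat: object | None = None


class ImmersedPlateSimulation:
    """Time-steps one or more rigid plates through the fluid.

    Parameters
    ----------
    blocks : list of FluidBlock, coarsest to finest (one entry = uniform grid).
    plates : list of (motion, geometry) pairs; motions give poses in chord
        units and chord-units-per-second velocities.
    dt_seconds : physical time per finest-tier lattice step.
    u_ref, area_ref : reference lattice speed and reference area (chord^2
        units) for the aerodynamic coefficients.
    """

    def __init__(self, blocks, plates, dt_seconds, u_ref, area_ref):
        self.blocks = list(blocks)
        self.fine = self.blocks[-1]
        self.plates = [_Plate(m, g) for m, g in plates]
        self.dt_seconds = float(dt_seconds)
        self.u_ref = float(u_ref)
        self.area_ref = float(area_ref)
        self.step_count = 0
        self._cut = np.zeros(self.fine.f.shape[:3] + (27,), dtype=np.bool_)
        self.records: list[dict] = []
        if len(self.blocks) > 1:
            self._multi = MultiblockSolver(
                self.blocks, boundary_hook=self._boundary_step
            )
        else:
            self._multi = None

    # -- core stepping ------------------------------------------------------

    @property
    def time_seconds(self) -> float:
        return self.step_count * self.dt_seconds

    def _boundary_step(self, block: FluidBlock):
        """Collide-stream with the virtual-flux plates applied (finest tier).

        Called exactly once per finest-tier step in both the uniform and the
        multiblock mode; advances the fine-step counter.
        """
        t = self.time_seconds
        sigma = self.dt_seconds / block.dx  # chord/s -> lattice velocity
        block._update_macro()
        self._cut[:] = False
        for pl in self.plates:
            pl.pose = plate_pose(pl.motion, pl.geom, t)
            pl.crossings, _ = locate_intersections(pl.pose, block, self._cut)
            compute_wall_pressures(block, pl.pose, pl.crossings)
            # rescale the rigid-body velocity field to lattice units
            pl.pose.wm = pl.pose.wm * sigma
            pl.pose.v0 = pl.pose.v0 * sigma
        block.collide_stream()
        for pl in self.plates:
            reconstruct_boundary_links(block, pl.pose, pl.crossings, self._cut)
        for pl in self.plates:
            self._refill_swept_nodes(block, pl, t)
        self.step_count += 1

    def _refill_swept_nodes(self, block: FluidBlock, pl: _Plate, t: float):
        """Reset nodes the plate swept past this step to a wall equilibrium.

        A zero-thickness plate moving through the lattice leaves nodes whose
        distributions describe the wrong side; refilling them with the
        equilibrium at (local pressure, wall velocity) removes the resulting
        force spikes (the thin-wall analogue of fresh-node refilling at
        moving boundaries).
        """
        from .lattice import equilibrium

        pose_now = plate_pose(pl.motion, pl.geom, t)
        pose_next = plate_pose(pl.motion, pl.geom, t + self.dt_seconds)
        # bounding box of the union of both poses
        corners = []
        for pose in (pose_now, pose_next):
            for a in (0.0, 1.0):
                for b in (0.0, 1.0):
                    corners.append(
                        pose.origin + a * pose.span * pose.e1
                        + b * pose.chord * pose.e2
                    )
        corners = np.array(corners)
        full = np.array(block.f.shape[:3])
        lo = np.maximum(np.floor(block.lab_to_grid(corners.min(0))).astype(int) - 1, 0)
        hi = np.minimum(np.ceil(block.lab_to_grid(corners.max(0))).astype(int) + 2, full)
        if np.any(hi <= lo):
            return
        grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
        idx = np.stack(grids, axis=-1)
        pad_origin = block.origin - np.asarray(block.pad) * block.dx
        X = idx * block.dx + pad_origin
        def signed_side(pose):
            rel = X - pose.origin
            d = rel @ pose.normal
            s1 = rel @ pose.e1
            s2 = rel @ pose.e2
            inrect = (
                (s1 > -0.5 * block.dx) & (s1 < pose.span + 0.5 * block.dx)
                & (s2 > -0.5 * block.dx) & (s2 < pose.chord + 0.5 * block.dx)
            )
            return d, inrect
        d0, in0 = signed_side(pose_now)
        d1, in1 = signed_side(pose_next)
        flip = (d0 * d1 < 0) & in0 & in1
        if not flip.any():
            return
        sel = idx[flip]
        xs = X[flip]
        sigma = self.dt_seconds / block.dx
        uw = (xs - pose_next.hinge) @ (pose_next.wm.T * sigma) + pose_next.v0 * sigma
        p_loc = block._p[sel[:, 0], sel[:, 1], sel[:, 2]]
        block.f_new[sel[:, 0], sel[:, 1], sel[:, 2]] = equilibrium(p_loc, uw)

    def step(self):
        if self._multi is not None:
            self._multi.step()
        else:
            b = self.fine
            b.fill_ghosts()
            self._boundary_step(b)
            b.commit()

    # -- measurement --------------------------------------------------------

    def measure(self) -> dict:
        """Force record of the current state (before the next step)."""
        b = self.fine
        t = self.time_seconds
        sigma = self.dt_seconds / b.dx
        total = ForceRecord(t, np.zeros(3), np.zeros(3), np.zeros(3), 0.0, [])
        for pl in self.plates:
            pose = plate_pose(pl.motion, pl.geom, t)
            pose.wm = pose.wm * sigma
            pose.v0 = pose.v0 * sigma
            rec = surface_forces(b, pose, time=t)
            total.force = total.force + rec.force
            total.force_pressure = total.force_pressure + rec.force_pressure
            total.force_viscous = total.force_viscous + rec.force_viscous
            total.power += rec.power
            total.per_wing.append(rec)
        cl, ct, cpwr = coefficients(total, self.u_ref, self.area_ref)
        q = 0.5 * self.u_ref ** 2 * self.area_ref
        return {
            "t": t,
            "step": self.step_count,
            "CL": cl,
            "CT": ct,
            "CPWR": cpwr,
            "CLp": total.force_pressure[2] / q,
            "CLtau": total.force_viscous[2] / q,
            "Fz": total.force[2],
            "Fy": total.force[1],
            "Fx": total.force[0],
            "P": total.power,
            "Fz_per_wing": tuple(float(r.force[2]) for r in total.per_wing),
        }

    def run(self, n_steps: int, measure_every: int = 1, progress=None) -> pd.DataFrame:
        for s in range(n_steps):
            if measure_every and s % measure_every == 0:
                self.records.append(self.measure())
            self.step()
            if progress is not None and (s + 1) % max(n_steps // 10, 1) == 0:
                progress(s + 1, n_steps)
        if measure_every:
            self.records.append(self.measure())
        return pd.DataFrame(self.records)

    def noslip_residual(self) -> float:
        """Median |u_fluid(wall) - u_wall| over the cut links (lattice units).

        Per crossing, the fluid velocity is linearly extrapolated to the wall
        from the cut node D (distance a along the link) and the next node C
        (distance 1 + a): ``u(0) = (1 + a) u(D) - a u(C)``.  The caller
        normalizes by the tip speed.
        """
        b = self.fine
        b._update_macro()
        t = self.time_seconds
        sigma = self.dt_seconds / b.dx
        e = b.lattice.e
        full = np.array(b.f.shape[:3])
        res = []
        for pl in self.plates:
            pose = plate_pose(pl.motion, pl.geom, t)
            pose.wm = pose.wm * sigma
            pose.v0 = pose.v0 * sigma
            cr, _ = locate_intersections(pose, b,
                                         np.zeros(b.f.shape[:3] + (27,), np.bool_))
            if cr.n == 0:
                continue
            n = cr.n
            idx = np.column_stack([cr.i[:n], cr.j[:n], cr.k[:n]])
            ea = e[cr.alpha[:n]]
            idx_c = idx - ea
            ok = np.all((idx_c >= 0) & (idx_c < full), axis=1)
            u_all = np.stack([b._ux, b._uy, b._uz], axis=-1)
            uD = u_all[idx[:, 0], idx[:, 1], idx[:, 2]]
            idx_c = np.clip(idx_c, 0, full - 1)
            uC = u_all[idx_c[:, 0], idx_c[:, 1], idx_c[:, 2]]
            a = cr.a[:n, None]
            uw_est = (1.0 + a) * uD - a * uC
            uwall = (cr.points - pose.hinge) @ pose.wm.T + pose.v0
            r = np.linalg.norm(uw_est - uwall, axis=1)
            res.append(r[ok])
        if not res:
            return 0.0
        return float(np.median(np.concatenate(res)))


def hover_simulation(
    wing: PhysicalWing = None,
    kin: WingKinematics = None,
    resolution: int = 32,
    u_lattice: float = 0.04,
    domain_chords: float = 40.0,
    n_tiers: int = 4,
    root_offset=(0.0, 0.0, 0.0),
) -> tuple[ImmersedPlateSimulation, int]:
    """Two-winged hovering run; returns (simulation, steps_per_cycle).

    With ``n_tiers = 1`` a single uniform block of ``domain_chords`` per side
    at the given resolution is used (reduced desk-scale runs); otherwise the
    tiered layout of the full model.
    """
    wing = wing or PhysicalWing()
    kin = kin or WingKinematics(frequency=wing.frequency)
    span = wing.wing_length / wing.mean_chord
    geom_r = PlateGeometry(chord=1.0, span=span, root_offset=np.asarray(root_offset),
                           side="right")
    geom_l = PlateGeometry(chord=1.0, span=span, root_offset=np.asarray(root_offset),
                           side="left")
    motion_r = FlappingMotion(kin, geom_r)
    motion_l = FlappingMotion(kin, geom_l)
    spc = steps_per_cycle(motion_r, resolution, u_lattice)
    dt_seconds = kin.period / spc
    dx = 1.0 / resolution
    nu_lattice = u_lattice * resolution / wing.reynolds
    if n_tiers == 1:
        n = int(round(domain_chords * resolution)) + 1
        block = FluidBlock(
            (n, n, n), dx=dx,
            origin=(-0.5 * domain_chords,) * 3,
            nu=nu_lattice,
            periodic=(False, False, False),
            pressure_face="y+",
        )
        blocks = [block]
    else:
        layout = build_layout(1.0, resolution, domain_chords, n_tiers)
        blocks = []
        for lev, tier in enumerate(layout.tiers):
            nu_tier = nu_lattice * tier.dx / layout.finest.dx
            blocks.append(
                FluidBlock(
                    tier.shape, dx=tier.dx, origin=tier.origin, nu=nu_tier,
                    periodic=(False, False, False) if lev == 0 else (False,) * 3,
                    pressure_face="y+" if lev == 0 else None,
                )
            )
    area = 2.0 * 1.0 * span  # combined two-wing planform, chord^2 units
    sim = ImmersedPlateSimulation(
        blocks, [(motion_r, geom_r), (motion_l, geom_l)],
        dt_seconds, u_lattice, area,
    )
    return sim, spc


def oscillating_plate_simulation(
    resolution: int = 16,
    u_lattice: float = 0.05,
    domain_strokes: float = 8.0,
    reynolds: float = 100.0,
    span_strokes: float = 2.0,
    frequency: float = 1.0,
) -> tuple[ImmersedPlateSimulation, int]:
    """Heave-plus-pitch validation plate; lengths in stroke amplitudes L.

    The plate chord equals the stroke amplitude; the reference speed for the
    lift coefficient is the peak heave speed ``2 pi f L``.
    """
    motion = OscillatingPlateMotion(
        stroke=1.0, frequency=frequency, chord=1.0, span=span_strokes
    )
    u_peak = 2.0 * np.pi * frequency * 1.0  # chord-units / s
    # steps per cycle from the requirement that peak heave speed = u_lattice
    dx = 1.0 / resolution
    dt_seconds = u_lattice * dx / u_peak
    spc = int(round(motion.period / dt_seconds))
    nu_lattice = u_lattice * resolution / reynolds
    n = int(round(domain_strokes * resolution)) + 1
    block = FluidBlock(
        (n, n, n), dx=dx, origin=(-0.5 * domain_strokes,) * 3,
        nu=nu_lattice, periodic=(False, False, False), pressure_face="y+",
    )
    area = 1.0 * span_strokes
    sim = ImmersedPlateSimulation(
        [block], [(motion, motion.geom)], dt_seconds, u_lattice, area
    )
    return sim, spc
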