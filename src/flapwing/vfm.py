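"""Virtual flux method: no-slip moving plates on the Cartesian lattice.

A zero-thickness rectangle is imposed on a :class:`~flapwing.solver.FluidBlock`
by reconstructing, at every lattice link the rectangle cuts, the distribution
that would otherwise stream through it.  The wall state is the prescribed
rigid-body velocity (no slip) and a pressure extrapolated along the wall
normal with a zero-normal-gradient (Neumann) condition:

``p_vb = (h2^2 p1 - h1^2 p2) / (h2^2 - h1^2)``

with probes at distances ``h1 = sqrt(3) dx`` and ``h2 = 2 sqrt(3) dx`` from
the wall on the side of the node being reconstructed.  Both sides of the plate
maintain their own crossings and normals; no link ever streams through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .solver import FluidBlock

__all__ = ["PlatePose", "Crossings", "boundary_pressure",
           "locate_intersections", "reconstruct_boundary_links", "plate_pose"]

H1_FACTOR = np.sqrt(3.0)
H2_FACTOR = 2.0 * np.sqrt(3.0)


@dataclass
class PlatePose:
    """A rectangle's placement and rigid-body velocity field at one instant.

    ``origin`` is the corner at (span=0, chord=0); ``e1``/``e2`` are unit span
    and chord directions; ``normal = e1 x e2``.  The velocity of a lab point x
    is ``wm @ (x - hinge) + v0``.
    """

    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    span: float
    chord: float
    normal: np.ndarray
    hinge: np.ndarray
    wm: np.ndarray
    v0: np.ndarray


def plate_pose(motion, geom, t: float, dt_fd: float | None = None) -> PlatePose:
    """Build a :class:`PlatePose` from a rigid motion object at time ``t``.

    ``motion`` needs ``transform(t) -> (R, root)``; the velocity field is
    obtained by central differencing of the pose.
    """
    if geom.area <= 0:
        raise ValueError("degenerate plate")
    r, root = motion.transform(t)
    if hasattr(motion, "velocity_override"):
        # treadmill-style wall: geometry fixed, tangential wall velocity
        # prescribed directly (used by shear-driven validation cases)
        wm = np.zeros((3, 3))
        v0 = np.asarray(motion.velocity_override(t), dtype=float)
    else:
        if dt_fd is None:
            period = getattr(getattr(motion, "kin", motion), "period", None)
            dt_fd = (period or 1.0) * 1e-6
        r2, root2 = motion.transform(t + dt_fd)
        r1, root1 = motion.transform(max(t - dt_fd, 0.0))
        span_dt = t + dt_fd - max(t - dt_fd, 0.0)
        rdot = (r2 - r1) / span_dt
        v0 = (root2 - root1) / span_dt
        wm = rdot @ r.T
    corner = root + r @ np.array([0.0, 0.0, -0.5 * geom.chord])
    e1 = r[:, 0]
    e2 = r[:, 2]
    if getattr(geom, "side", "right") == "left":
        pass  # mirroring is already inside the motion's transform
    return PlatePose(
        origin=corner,
        e1=e1,
        e2=e2,
        span=geom.span,
        chord=geom.chord,
        normal=np.cross(e1, e2),
        hinge=root,
        wm=wm,
        v0=v0,
    )


class Crossings:
    """Structure-of-arrays set of link/plate intersections on one block."""

    def __init__(self, capacity: int):
        self.i = np.empty(capacity, dtype=np.int64)
        self.j = np.empty(capacity, dtype=np.int64)
        self.k = np.empty(capacity, dtype=np.int64)
        self.alpha = np.empty(capacity, dtype=np.int64)
        self.a = np.empty(capacity)
        self.side = np.empty(capacity)
        self.vx = np.empty(capacity)
        self.vy = np.empty(capacity)
        self.vz = np.empty(capacity)
        self.pvb = np.empty(capacity)
        self.n = 0

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.vx[: self.n], self.vy[: self.n], self.vz[: self.n]])

    def normals(self, pose: PlatePose) -> np.ndarray:
        """Side-signed unit normals (pointing toward each record's fluid node)."""
        return self.side[: self.n, None] * pose.normal[None, :]


def locate_intersections(
    pose: PlatePose, block: FluidBlock, cut: np.ndarray | None = None
) -> tuple[Crossings, np.ndarray]:
    """All lattice links of ``block`` cut by the rectangle, plus the cut mask.

    The search is restricted to the plate's bounding box inflated by one
    spacing.  ``a`` is the fraction of the link from the fluid node to the
    crossing point; each side of the plate produces its own records.
    """
    e1, e2 = pose.e1, pose.e2
    corners = (
        pose.origin[None, :]
        + np.outer([0, 1, 1, 0], e1 * pose.span)
        + np.outer([0, 0, 1, 1], e2 * pose.chord)
    )
    gmin = block.lab_to_grid(corners.min(axis=0)) - 1.5
    gmax = block.lab_to_grid(corners.max(axis=0)) + 1.5
    full = block.f.shape[:3]
    lo = np.maximum(np.floor(gmin).astype(int), 0)
    hi = np.minimum(np.ceil(gmax).astype(int) + 1, full)
    if cut is None:
        cut = np.zeros(full + (27,), dtype=np.bool_)
    nbox = int(np.prod(np.maximum(hi - lo, 0)))
    cr = Crossings(max(nbox * 27, 1))
    if nbox == 0:
        return cr, cut
    # padded-array origin (ghost cells sit before the interior origin)
    pad_origin = block.origin - np.asarray(block.pad) * block.dx
    cr.n = _kernels.find_crossings(
        lo[0], hi[0], lo[1], hi[1], lo[2], hi[2],
        pad_origin[0], pad_origin[1], pad_origin[2], block.dx,
        block._ex, block._ey, block._ez,
        pose.origin[0], pose.origin[1], pose.origin[2],
        e1[0], e1[1], e1[2], e2[0], e2[1], e2[2],
        pose.span, pose.chord,
        pose.normal[0], pose.normal[1], pose.normal[2],
        cr.i, cr.j, cr.k, cr.alpha, cr.a, cr.side, cr.vx, cr.vy, cr.vz,
        cut,
    )
    return cr, cut


def boundary_pressure(p1: float, p2: float, h1: float, h2: float) -> float:
    """Second-order Neumann extrapolation of the wall pressure (closed form)."""
    if h1 == h2:
        raise ValueError("probe distances h1 and h2 must differ")
    return (h2 ** 2 * p1 - h1 ** 2 * p2) / (h2 ** 2 - h1 ** 2)


def compute_wall_pressures(block: FluidBlock, pose: PlatePose, cr: Crossings,
                           h1: float | None = None, h2: float | None = None):
    """Fill ``cr.pvb`` from the block's current pressure field."""
    h1 = H1_FACTOR * block.dx if h1 is None else h1
    h2 = H2_FACTOR * block.dx if h2 is None else h2
    pad_origin = block.origin - np.asarray(block.pad) * block.dx
    _kernels.wall_pressures(
        block._p, pad_origin[0], pad_origin[1], pad_origin[2], block.dx,
        cr.n, cr.vx, cr.vy, cr.vz, cr.side,
        pose.normal[0], pose.normal[1], pose.normal[2], h1, h2,
        pose.origin[0], pose.origin[1], pose.origin[2],
        pose.e1[0], pose.e1[1], pose.e1[2],
        pose.e2[0], pose.e2[1], pose.e2[2],
        pose.span, pose.chord,
        cr.pvb,
    )


def reconstruct_boundary_links(block: FluidBlock, pose: PlatePose,
                               cr: Crossings, cut: np.ndarray):
    """Overwrite the streamed-in values at cut links in ``block.f_new``.

    Requires macroscopic fields current for time t (``block._update_macro()``)
    and ``compute_wall_pressures`` already applied.  Velocities are rescaled
    to lattice units (u_lattice = u_lab * dt / dx = u_lab with c = 1 in lab
    units per tier); the pose velocity field must already be in lattice units.
    """
    _kernels.reconstruct_links(
        block.f, block.f_new, block._p, block._ux, block._uy, block._uz,
        block.tau,
        block._ex, block._ey, block._ez, block._w, block._opp,
        cr.n, cr.i, cr.j, cr.k, cr.alpha, cr.a, cr.vx, cr.vy, cr.vz, cr.pvb,
        cut,
        pose.wm, pose.v0, pose.hinge[0], pose.hinge[1], pose.hinge[2],
    )
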