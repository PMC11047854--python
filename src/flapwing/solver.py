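"""Uniform-grid incompressible LBM block and its boundary conditions.

A :class:`FluidBlock` owns one Cartesian tier: the 27 pressure distributions
per node, the relaxation time, the grid spacing and the lab-frame origin.
Non-periodic axes carry a one-cell ghost rim; the rim is refilled every step
(zero-gradient copy, fixed-pressure equilibrium on the anchored face, or
inter-tier interpolation) before the fused collide-stream sweep, which always
wraps on the padded array.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .lattice import D3Q27, equilibrium, relaxation_time

__all__ = ["FluidBlock", "taylor_green_block"]

P_REF = 1.0 / 3.0  # far-field pressure, rho0 * cs^2 with c = 1


class FluidBlock:
    """One grid tier of the normalized incompressible D3Q27 solver.

    Parameters
    ----------
    shape : interior node counts (nx, ny, nz).
    dx : grid spacing in lab units.
    origin : lab coordinates of interior node (0, 0, 0).
    nu : kinematic viscosity in this tier's lattice units.
    periodic : per-axis periodicity; non-periodic axes get ghost cells.
    pressure_face : face name (e.g. "y+") on which pressure is anchored at
        the far-field value; all other non-periodic faces are zero-gradient.
    """

    def __init__(
        self,
        shape,
        dx: float,
        origin=(0.0, 0.0, 0.0),
        nu: float = 0.05,
        periodic=(True, True, True),
        pressure_face: str | None = None,
        p0: float = P_REF,
    ):
        self.lattice = D3Q27
        self.shape = tuple(int(n) for n in shape)
        self.dx = float(dx)
        self.dt = float(dx)  # acoustic scaling, c = dx/dt = 1
        self.origin = np.asarray(origin, dtype=float)
        self.nu = float(nu)
        self.tau = relaxation_time(nu)
        self.periodic = tuple(bool(b) for b in periodic)
        self.pressure_face = pressure_face
        self.p0 = float(p0)
        self.pad = tuple(0 if per else 1 for per in self.periodic)
        full = tuple(n + 2 * p for n, p in zip(self.shape, self.pad))
        self.f = np.empty(full + (27,), dtype=np.float64)
        self.f_new = np.empty_like(self.f)
        self._p = np.empty(full)
        self._ux = np.empty(full)
        self._uy = np.empty(full)
        self._uz = np.empty(full)
        self._ex = np.ascontiguousarray(self.lattice.e[:, 0])
        self._ey = np.ascontiguousarray(self.lattice.e[:, 1])
        self._ez = np.ascontiguousarray(self.lattice.e[:, 2])
        self._w = self.lattice.w
        self._opp = self.lattice.opposite
        self.time = 0.0
        self.initialize()

    # ---- indexing helpers -------------------------------------------------

    @property
    def interior(self):
        """Slice tuple selecting interior nodes of the padded arrays."""
        return tuple(slice(p, p + n) for p, n in zip(self.pad, self.shape))

    def node_positions(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.dx

    def lab_to_grid(self, x) -> np.ndarray:
        """Lab coordinates -> fractional padded-array indices."""
        x = np.asarray(x, dtype=float)
        return (x - self.origin) / self.dx + np.asarray(self.pad)

    # ---- state ------------------------------------------------------------

    def initialize(self, p=None, u=None):
        """Set distributions to equilibrium for given macroscopic fields."""
        full = self.f.shape[:3]
        if p is None:
            p = np.full(full, self.p0)
        if u is None:
            u = np.zeros(full + (3,))
        self.f[:] = equilibrium(p, u, self.lattice)
        self.time = 0.0

    def macroscopics(self):
        """(p, u) on interior nodes; u has shape (nx, ny, nz, 3)."""
        self._update_macro()
        sl = self.interior
        u = np.stack([self._ux[sl], self._uy[sl], self._uz[sl]], axis=-1)
        return self._p[sl].copy(), u

    def _update_macro(self):
        _kernels.macro_fields(
            self.f, self._ex, self._ey, self._ez,
            self._p, self._ux, self._uy, self._uz,
        )

    # ---- boundary handling ------------------------------------------------

    _FACES = {"x-": (0, 0), "x+": (0, 1), "y-": (1, 0), "y+": (1, 1),
              "z-": (2, 0), "z+": (2, 1)}

    def fill_ghosts(self):
        """Zero-gradient ghost copy on non-periodic faces; anchor pressure.

        On the anchored face the ghost keeps the adjacent interior velocity
        and non-equilibrium part but resets pressure to the far-field value.
        """
        for face, (axis, hi) in self._FACES.items():
            if self.periodic[axis]:
                continue
            g = [slice(None)] * 3
            a = [slice(None)] * 3
            n = self.shape[axis]
            if hi:
                g[axis] = n + 1
                a[axis] = n
            else:
                g[axis] = 0
                a[axis] = 1
            g, a = tuple(g), tuple(a)
            self.f[g] = self.f[a]
            if face == self.pressure_face:
                fa = self.f[a]
                p = fa.sum(axis=-1)
                # shift every distribution toward the anchored pressure
                self.f[g] = fa + self._w * (self.p0 - p)[..., None]

    # ---- update -----------------------------------------------------------

    def collide_stream(self):
        """One BGK collision + streaming sweep (boundaries must be current)."""
        _kernels.collide_stream(
            self.f, self.f_new, self.tau, self._ex, self._ey, self._ez, self._w
        )

    def commit(self):
        self.f, self.f_new = self.f_new, self.f
        self.time += self.dt
        if not np.isfinite(self.f[self.interior + (0,)]).all():
            raise FloatingPointError(
                f"non-finite distributions at t={self.time} (unstable run?)"
            )

    def step(self):
        """Plain step without immersed boundaries (periodic/outer faces only)."""
        self.fill_ghosts()
        self.collide_stream()
        self.commit()

    def total_pressure(self) -> float:
        return float(self.f[self.interior].sum())


def taylor_green_block(n: int, nu: float, u0: float = 0.05) -> tuple:
    """Periodic block initialized with the 2-D decaying vortex, plus oracle.

    The field ``u = u0 (cos x sin y, -sin x cos y, 0)`` with matching pressure
    is an exact Navier-Stokes solution decaying as ``exp(-2 nu t)`` (k = 1 per
    axis on a 2*pi-periodic cube, so the velocity rate is nu (kx^2 + ky^2)).
    Returns ``(block, exact)`` where ``exact(t)`` gives (p, u) arrays in
    lattice units on the block's nodes.
    """
    block = FluidBlock((n, n, n), dx=1.0, nu=nu)
    kx = 2.0 * np.pi / n
    x = np.arange(n) * kx
    X, Y, _ = np.meshgrid(x, x, x, indexing="ij")

    def exact(t: float):
        decay = np.exp(-2.0 * nu * (kx ** 2) * t)
        u = np.zeros((n, n, n, 3))
        u[..., 0] = u0 * np.cos(X) * np.sin(Y) * decay
        u[..., 1] = -u0 * np.sin(X) * np.cos(Y) * decay
        p = P_REF - 0.25 * (u0 ** 2) * (np.cos(2 * X) + np.cos(2 * Y)) * decay ** 2
        return p, u

    p, u = exact(0.0)
    block.initialize(p, u)
    return block, exact
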