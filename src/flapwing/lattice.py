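"""D3Q27 lattice definition and the incompressible-formulation primitives.

The solver evolves pressure distribution functions ``p_alpha = cs**2 * f_alpha``
on the 27-velocity cubic lattice.  Macroscopic pressure is the zeroth moment,
velocity the (rescaled) first moment, and the non-equilibrium second moment
carries the viscous stress.  All lattice quantities use ``c = 1`` so the sound
speed is ``cs = 1/sqrt(3)`` and the reference density ``rho0 = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LatticeModel",
    "D3Q27",
    "equilibrium",
    "macroscopics",
    "relaxation_time",
]


def _build_velocities() -> np.ndarray:
    """27 integer velocity vectors ordered by speed: rest, 6 faces, 12 edges, 8 corners."""
    import itertools

    all27 = list(itertools.product((0, 1, -1), repeat=3))
    all27.sort(key=lambda v: (abs(v[0]) + abs(v[1]) + abs(v[2]), v))
    return np.array(all27, dtype=np.int64)


@dataclass(frozen=True)
class LatticeModel:
    """The 27-direction cubic lattice with its weights and speeds."""

    e: np.ndarray = field(default_factory=_build_velocities)
    c: float = 1.0

    @property
    def w(self) -> np.ndarray:
        speed2 = (self.e ** 2).sum(axis=1)
        w = np.empty(27)
        w[speed2 == 0] = 8.0 / 27.0
        w[speed2 == 1] = 2.0 / 27.0
        w[speed2 == 2] = 1.0 / 54.0
        w[speed2 == 3] = 1.0 / 216.0
        return w

    @property
    def cs(self) -> float:
        return self.c / np.sqrt(3.0)

    @property
    def opposite(self) -> np.ndarray:
        """Index of -e[alpha] for each alpha."""
        e = self.e
        opp = np.empty(27, dtype=np.int64)
        for a in range(27):
            opp[a] = int(np.flatnonzero((e == -e[a]).all(axis=1))[0])
        return opp

    @property
    def q(self) -> int:
        return len(self.e)


D3Q27 = LatticeModel()


def equilibrium(p, u, lattice: LatticeModel = D3Q27) -> np.ndarray:
    """Equilibrium pressure distributions for pressure ``p`` and velocity ``u``.

    ``p`` scalar or array (...,); ``u`` array (..., 3).  Returns (..., 27).
    The weights' moment identities give ``sum_a peq_a = p`` and
    ``sum_a e_a peq_a = rho0 * cs**2 * u`` exactly.
    """
    p = np.asarray(p, dtype=float)
    u = np.asarray(u, dtype=float)
    e = lattice.e.astype(float)
    w = lattice.w
    c2 = lattice.c ** 2
    eu = u @ e.T  # (..., 27)
    u2 = (u * u).sum(axis=-1)[..., None]
    return w * (p[..., None] + (eu + 1.5 * eu ** 2 / c2 - 0.5 * u2))


def macroscopics(pa, lattice: LatticeModel = D3Q27):
    """Pressure, velocity and non-equilibrium stress from distributions.

    ``pa`` has shape (..., 27).  Returns ``(p, u, Pi_neq)`` with shapes
    (...,), (..., 3), (..., 3, 3); ``Pi_neq`` is symmetric.
    """
    pa = np.asarray(pa, dtype=float)
    e = lattice.e.astype(float)
    cs2 = lattice.cs ** 2
    p = pa.sum(axis=-1)
    u = (pa @ e) / cs2  # rho0 = 1
    eiej = np.einsum("ai,aj->aij", e, e)
    second = np.einsum("...a,aij->...ij", pa, eiej) / cs2
    # second moment of the equilibrium is cs^2 (p I + rho0 u u): subtracting
    # it leaves exactly the non-equilibrium stress
    uu = np.einsum("...i,...j->...ij", u, u)
    pi_neq = second - p[..., None, None] * np.eye(3) - uu
    return p, u, pi_neq


def relaxation_time(nu: float, c: float = 1.0, dx: float = 1.0) -> float:
    """BGK relaxation time ``tau = 3 nu / (c dx) + 1/2`` (with ``dt = dx/c``)."""
    tau = 3.0 * nu / (c * dx) + 0.5
    if tau <= 0.5:
        raise ValueError(f"relaxation time {tau} <= 1/2 is unstable/unphysical")
    return tau
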