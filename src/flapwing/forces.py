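"""Surface loads, aerodynamic coefficients and vortex diagnostics.

Forces on a plate are obtained by traction integration: at panel centres on
each side of the rectangle, the wall pressure is extrapolated along the
normal (the same second-order Neumann extrapolation the boundary condition
uses) and the viscous shear is the one-sided normal derivative of the
tangential velocity through the two probes and the no-slip wall value.  A
momentum-exchange summation over the cut links serves as an independent
cross-check of the same force.

Coefficients follow the hovering convention with the COMBINED planform area
of both wings as reference:

``CL = Fz / (1/2 rho U^2 SW)``, ``CT = Fy / (...)``,
``CPWR = sum(f_local . u_local) / (1/2 rho U^3 SW)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .solver import FluidBlock, P_REF
from .vfm import H1_FACTOR, H2_FACTOR, Crossings, PlatePose

__all__ = [
    "ForceRecord",
    "FlowDiagnostics",
    "surface_forces",
    "momentum_exchange_force",
    "coefficients",
    "velocity_gradients",
    "q_and_helicity",
]


@dataclass
class ForceRecord:
    """Aerodynamic loads of one step, in lattice units of the finest tier."""

    time: float
    force: np.ndarray            # (3,) total over all plates
    force_pressure: np.ndarray   # (3,) pressure part
    force_viscous: np.ndarray    # (3,) viscous part
    power: float
    per_wing: list | None = None

    @property
    def lift(self) -> float:
        return float(self.force[2])

    @property
    def thrust(self) -> float:
        return float(self.force[1])


def surface_forces(
    block: FluidBlock,
    pose: PlatePose,
    samples_per_chord: int | None = None,
    time: float = 0.0,
) -> ForceRecord:
    """Traction-integrated load on one plate (both sides).

    The plate is sampled at roughly the grid spacing; each sample contributes
    ``[-(p_side - p_ref) n_side + mu dut/dn] dA`` per side, and the power is
    the local traction dotted with the local wall velocity.
    """
    dx = block.dx
    n_span = max(int(round(pose.span / dx)), 2)
    n_chord = max(int(round(pose.chord / dx)), 2)
    if samples_per_chord is not None:
        n_chord = samples_per_chord
        n_span = max(int(round(samples_per_chord * pose.span / pose.chord)), 2)
    s = (np.arange(n_span) + 0.5) / n_span * pose.span
    c = (np.arange(n_chord) + 0.5) / n_chord * pose.chord
    S, C = np.meshgrid(s, c, indexing="ij")
    pts = (
        pose.origin[None, :]
        + S.ravel()[:, None] * pose.e1[None, :]
        + C.ravel()[:, None] * pose.e2[None, :]
    )
    d_area = (pose.span / n_span) * (pose.chord / n_chord)
    npts = len(pts)
    if npts == 0:
        return ForceRecord(time, np.zeros(3), np.zeros(3), np.zeros(3), 0.0)

    block._update_macro()
    pad_origin = block.origin - np.asarray(block.pad) * block.dx
    h1 = H1_FACTOR * dx
    h2 = H2_FACTOR * dx
    uwall = (pts - pose.hinge) @ pose.wm.T + pose.v0
    mu = block.nu  # rho0 = 1 in lattice units

    f_p = np.zeros(3)
    f_v = np.zeros(3)
    power = 0.0
    for sgn in (1.0, -1.0):
        n_side = sgn * pose.normal
        sgn_arr = np.full(npts, sgn)
        pw = np.empty(npts)
        _kernels.wall_pressures(
            block._p, pad_origin[0], pad_origin[1], pad_origin[2], dx,
            npts, pts[:, 0], pts[:, 1], pts[:, 2], sgn_arr,
            pose.normal[0], pose.normal[1], pose.normal[2], h1, h2,
            pose.origin[0], pose.origin[1], pose.origin[2],
            pose.e1[0], pose.e1[1], pose.e1[2],
            pose.e2[0], pose.e2[1], pose.e2[2],
            pose.span, pose.chord,
            pw,
        )
        u1 = np.empty((npts, 3))
        u2 = np.empty((npts, 3))
        h_eff = np.empty((npts, 2))
        _kernels.wall_velocity_probes(
            block._ux, block._uy, block._uz,
            pad_origin[0], pad_origin[1], pad_origin[2], dx,
            npts, pts[:, 0], pts[:, 1], pts[:, 2], sgn_arr,
            pose.normal[0], pose.normal[1], pose.normal[2], h1, h2,
            pose.origin[0], pose.origin[1], pose.origin[2],
            pose.e1[0], pose.e1[1], pose.e1[2],
            pose.e2[0], pose.e2[1], pose.e2[2],
            pose.span, pose.chord,
            u1, u2, h_eff,
        )
        # one-sided derivative through (0, uwall), (h1, u1), (h2, u2)
        ha = h_eff[:, 0]
        hb = h_eff[:, 1]
        c0 = -(ha + hb) / (ha * hb)
        c1 = hb / (ha * (hb - ha))
        c2 = -ha / (hb * (hb - ha))
        dudn = c0[:, None] * uwall + c1[:, None] * u1 + c2[:, None] * u2
        # keep only the tangential part of the shear
        dudn_t = dudn - (dudn @ n_side)[:, None] * n_side[None, :]
        tr_p = -(pw - P_REF)[:, None] * n_side[None, :]
        # dx factor converts the lab-length derivative to lattice units so the
        # viscous stress shares the (dimensionless) units of the pressure term
        tr_v = mu * dx * dudn_t
        f_p += tr_p.sum(axis=0) * d_area
        f_v += tr_v.sum(axis=0) * d_area
        # aerodynamic power consumed: the wing works against the fluid
        # traction, so the local force the wing exerts is -traction
        power -= float(((tr_p + tr_v) * uwall).sum()) * d_area
    total = f_p + f_v
    return ForceRecord(time, total, f_p, f_v, power)


def momentum_exchange_force(block: FluidBlock, cr: Crossings) -> np.ndarray:
    """Momentum-exchange force over the cut links (independent oracle).

    Must be called after the reconstruction, while ``block.f`` still holds the
    pre-collision state and ``block.f_new`` the reconstructed one.
    """
    fx, fy, fz = _kernels.momentum_exchange(
        block.f, block.f_new, block.tau,
        block._ex, block._ey, block._ez, block._w, block._opp,
        cr.n, cr.i, cr.j, cr.k, cr.alpha, cr.a,
    )
    # kernel result is in pure lattice units (area unit dx^2); dx^2 converts
    # to the stress-times-lab-area convention of surface_forces
    return np.array([fx, fy, fz]) * block.dx ** 2


def coefficients(record: ForceRecord, u_ref: float, area: float, rho: float = 1.0):
    """(CL, CT, CPWR) from a force record; ``area`` is the combined two-wing SW."""
    if u_ref <= 0:
        raise ValueError("reference speed must be positive")
    q = 0.5 * rho * u_ref ** 2 * area
    return (
        record.force[2] / q,
        record.force[1] / q,
        record.power / (q * u_ref),
    )


@dataclass
class FlowDiagnostics:
    """Velocity-gradient split and derived vortex measures on a grid."""

    D: np.ndarray        # (..., 3, 3) velocity gradient, D[i][j] = du_i/dx_j
    omega_t: np.ndarray  # antisymmetric part
    S: np.ndarray        # symmetric part
    Q: np.ndarray        # vortex criterion 1/2 (|Omega|^2 - |S|^2)
    helicity: np.ndarray
    helicity_norm: np.ndarray  # u.w/(|u||w|), 0 where undefined
    mask: np.ndarray     # True where helicity_norm is defined


def velocity_gradients(u: np.ndarray, dx: float = 1.0) -> FlowDiagnostics:
    """Central-difference gradient tensor and vortex diagnostics of a field.

    ``u`` has shape (nx, ny, nz, 3).  One-sided differences at the edges.
    """
    grads = [np.gradient(u[..., i], dx) for i in range(3)]
    D = np.stack(
        [np.stack([grads[i][j] for j in range(3)], axis=-1) for i in range(3)],
        axis=-2,
    )
    Dt = np.swapaxes(D, -1, -2)
    omega_t = 0.5 * (D - Dt)
    S = 0.5 * (D + Dt)
    Q = 0.5 * (
        (omega_t ** 2).sum(axis=(-2, -1)) - (S ** 2).sum(axis=(-2, -1))
    )
    w = np.stack(
        [
            D[..., 2, 1] - D[..., 1, 2],
            D[..., 0, 2] - D[..., 2, 0],
            D[..., 1, 0] - D[..., 0, 1],
        ],
        axis=-1,
    )
    hd = (u * w).sum(axis=-1)
    denom = np.linalg.norm(u, axis=-1) * np.linalg.norm(w, axis=-1)
    mask = denom > 0
    hn = np.zeros_like(hd)
    np.divide(hd, denom, out=hn, where=mask)
    return FlowDiagnostics(D, omega_t, S, Q, hd, hn, mask)


def q_and_helicity(diag: FlowDiagnostics, u_ref: float, l_ref: float):
    """Normalized Q* = Q/(U/L)^2 and hd* (already normalized)."""
    return diag.Q / (u_ref / l_ref) ** 2, diag.helicity_norm
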