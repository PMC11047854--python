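"""Post-processing: cycle averages, efficiency ellipses, optimal phase.

The phase sweep places each motion's cycle-averaged (power, lift) coefficient
pair in the plane; the eight figure-eight motions trace a closed curve
parametrized by the elevation initial phase.  Two elliptic descriptions are
provided:

* :func:`ellipse_fit` - algebraic direct least squares with the ellipse
  constraint (Fitzgibbon/Halir-Flusser), for arbitrary point sets;
* :func:`harmonic_ellipse` - the first-harmonic Fourier description of the
  phase-parametrized sweep, which traces an exact ellipse and carries the
  phase along the curve.  The sweep analysis uses this one: it reproduces the
  published ellipse geometry and makes the most-efficient-phase mapping
  intrinsic (the tangency parameter is the phase).

The most efficient motion maximizes lift per power, i.e. the tangent from the
origin to the ellipse in the (power, lift) plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .kinematics import PhysicalWing

__all__ = [
    "EllipseFit",
    "SweepResult",
    "cycle_average",
    "ellipse_fit",
    "harmonic_ellipse",
    "most_efficient_phase",
    "dimensionalize",
    "sweep_table",
]


def cycle_average(t: np.ndarray, values: np.ndarray, period: float,
                  cycle_index: int = 6) -> float:
    """Trapezoidal mean of a time series over cycle ``cycle_index`` (1-based).

    The window is [(k-1) T, k T]; the series must cover it.
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    t0 = (cycle_index - 1) * period
    t1 = cycle_index * period
    if t[0] > t0 + 1e-12 or t[-1] < t1 - 1e-12:
        raise ValueError(
            f"series [{t[0]}, {t[-1]}] does not cover cycle {cycle_index} "
            f"window [{t0}, {t1}]"
        )
    # interpolate onto the exact window edges for an unbiased mean
    inside = (t > t0) & (t < t1)
    tt = np.concatenate([[t0], t[inside], [t1]])
    vv = np.concatenate(
        [[np.interp(t0, t, values)], values[inside], [np.interp(t1, t, values)]]
    )
    return float(np.trapezoid(vv, tt) / period)


@dataclass(frozen=True)
class EllipseFit:
    """Ellipse in the (power coefficient, lift coefficient) plane.

    ``ll``/``ls`` are the long and short side lengths (semi-axes), ``theta``
    the inclination of the long axis from the power axis in degrees.  For
    harmonic fits, ``phase0``/``phase_dir`` map curve parameter to sweep
    phase (degrees).
    """

    center: tuple
    ll: float
    ls: float
    theta: float
    coeffs: tuple | None = None
    harmonic: tuple | None = None  # (ax, bx, ay, by) Fourier coefficients

    @property
    def aspect_ratio(self) -> float:
        return self.ll / self.ls

    def point(self, param):
        """Point(s) on the ellipse at curve parameter ``param`` (radians).

        For harmonic fits the parameter is the sweep phase; otherwise it is
        the standard ellipse eccentric anomaly.
        """
        param = np.asarray(param, dtype=float)
        if self.harmonic is not None:
            ax, bx, ay, by = self.harmonic
            x = self.center[0] + ax * np.cos(param) + bx * np.sin(param)
            y = self.center[1] + ay * np.cos(param) + by * np.sin(param)
            return np.stack([x, y], axis=-1)
        th = np.radians(self.theta)
        x = self.ll * np.cos(param)
        y = self.ls * np.sin(param)
        return np.stack(
            [
                self.center[0] + x * np.cos(th) - y * np.sin(th),
                self.center[1] + x * np.sin(th) + y * np.cos(th),
            ],
            axis=-1,
        )


def _conic_to_geometry(A, B, C, D, E, F):
    den = B * B - 4 * A * C
    x0 = (2 * C * D - B * E) / den
    y0 = (2 * A * E - B * D) / den
    Fc = A * x0 * x0 + B * x0 * y0 + C * y0 * y0 + D * x0 + E * y0 + F
    lam, vec = np.linalg.eigh(np.array([[A, B / 2], [B / 2, C]]))
    with np.errstate(invalid="raise"):
        semi = np.sqrt(-Fc / lam)
    order = np.argsort(-semi)
    semi = semi[order]
    v = vec[:, order[0]]
    theta = np.degrees(np.arctan2(v[1], v[0])) % 180.0
    return (x0, y0), semi[0], semi[1], theta


def ellipse_fit(x, y) -> EllipseFit:
    """Direct least-squares conic fit constrained to an ellipse.

    Requires at least 6 points in general position; raises ``ValueError`` for
    degenerate (e.g. collinear) input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 6:
        raise ValueError("need at least 6 points for an ellipse fit")
    sv = np.linalg.svd(
        np.column_stack([x - x.mean(), y - y.mean()]), compute_uv=False
    )
    if sv[1] <= 1e-9 * sv[0]:
        raise ValueError("collinear points cannot define an ellipse")
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
        M = S1 + S2 @ T
        M = np.linalg.solve(np.array([[0, 0, 2], [0, -1, 0], [2, 0, 0]], float), M)
        w, V = np.linalg.eig(M)
        cond = 4 * V[0] * V[2] - V[1] ** 2
        a1 = np.real(V[:, cond > 0][:, 0])
        coeffs = np.concatenate([a1, T @ a1])
        center, ll, ls, theta = _conic_to_geometry(*coeffs)
    except (np.linalg.LinAlgError, IndexError, FloatingPointError) as err:
        raise ValueError(f"degenerate point set for ellipse fit: {err}") from None
    if not np.isfinite(ll) or ls <= 0 or ll / ls > 1e6:
        raise ValueError("degenerate (nearly collinear) point set for ellipse fit")
    return EllipseFit(center, ll, ls, theta, coeffs=tuple(coeffs))


def harmonic_ellipse(phases_deg, x, y) -> EllipseFit:
    """First-harmonic Fourier ellipse of a phase-parametrized closed curve.

    ``x(phi) ~ x0 + ax cos phi + bx sin phi`` (same for y) fitted by least
    squares over the sweep phases; the singular values of the harmonic matrix
    give the semi-axes.  Needs at least 6 phases.
    """
    ph = np.radians(np.asarray(phases_deg, dtype=float))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(ph) < 6:
        raise ValueError("need at least 6 sweep phases")
    basis = np.column_stack([np.ones_like(ph), np.cos(ph), np.sin(ph)])
    cx, *_ = np.linalg.lstsq(basis, x, rcond=None)
    cy, *_ = np.linalg.lstsq(basis, y, rcond=None)
    M = np.array([[cx[1], cx[2]], [cy[1], cy[2]]])
    U, S, Vt = np.linalg.svd(M)
    if S[1] <= 1e-9 * S[0]:
        raise ValueError("degenerate (collinear) sweep points")
    theta = np.degrees(np.arctan2(U[1, 0], U[0, 0])) % 180.0
    return EllipseFit(
        (float(cx[0]), float(cy[0])), float(S[0]), float(S[1]), float(theta),
        harmonic=(float(cx[1]), float(cx[2]), float(cy[1]), float(cy[2])),
    )


def most_efficient_phase(fit: EllipseFit) -> tuple[float, float]:
    """Phase (deg) and ratio of the origin-tangent point maximizing lift/power.

    The most efficient motion is where a line from the origin is tangent to
    the ellipse with the greatest slope.  For harmonic fits the curve
    parameter is the sweep phase itself; otherwise the eccentric anomaly is
    returned.  Raises if the origin lies inside the ellipse (no tangent).
    """
    # origin inside test via the conic/parametric form
    c = np.asarray(fit.center)
    th = np.radians(fit.theta)
    rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
    if fit.harmonic is not None:
        ax, bx, ay, by = fit.harmonic
        M = np.array([[ax, bx], [ay, by]])
        local = np.linalg.solve(M, -c)
    else:
        local = rot @ (-c) / np.array([fit.ll, fit.ls])
    if (local ** 2).sum() < 1.0:
        raise ValueError("origin lies inside the ellipse; no tangent exists")

    def neg_ratio(p):
        x, y = fit.point(p)
        return -y / x

    grid = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    vals = np.array([neg_ratio(p) for p in grid])
    p0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(neg_ratio, bracket=(p0 - 0.1, p0, p0 + 0.1))
    return float(np.degrees(res.x) % 360.0), float(-res.fun)


def dimensionalize(cl_bar: float, ratio: float, wing: PhysicalWing):
    """(Fz in microN, P in microW, Fz/P in 1/(m/s)) from coefficient means.

    Inverts the coefficient definitions with the combined two-wing reference
    area; ``ratio`` is CL_bar / CPWR_bar so Fz/P = ratio / utip_bar.
    """
    q = 0.5 * wing.rho_air * wing.utip_bar ** 2 * wing.wing_area
    fz = cl_bar * q
    p = (cl_bar / ratio) * q * wing.utip_bar if ratio != 0 else np.inf
    return fz * 1e6, p * 1e6, (ratio / wing.utip_bar if ratio != 0 else 0.0)


def oscillating_plate_case(resolution: int = 16, cycles: int = 3,
                           reynolds: float = 100.0):
    """Heave-plus-pitch validation plate: CL(t) series and its cycle mean.

    Drives the solver with the translating/pitching plate motion and reports
    the lift-coefficient time series (with ``t_over_T``) and the trapezoidal
    mean over the final cycle.
    """
    from .simulation import oscillating_plate_simulation

    sim, spc = oscillating_plate_simulation(resolution=resolution,
                                            reynolds=reynolds)
    df = sim.run(spc * cycles, measure_every=2)
    period = sim.plates[0].motion.period
    df = df.assign(t_over_T=df.t / period)
    cl_bar = cycle_average(df.t.to_numpy(), df.CL.to_numpy(), period, cycles)
    return df, cl_bar


@dataclass
class SweepResult:
    """Cycle-averaged coefficients over the (phase, Reynolds) grid."""

    table: pd.DataFrame  # columns: phi_e0, Re, CL, CT, CPWR, ratio, figure_eight

    def points(self, re: float):
        sub = self.table[(self.table.Re == re) & self.table.figure_eight]
        sub = sub.sort_values("phi_e0")
        return sub.phi_e0.to_numpy(), sub.CPWR.to_numpy(), sub.CL.to_numpy()

    def ellipse(self, re: float) -> EllipseFit:
        ph, x, y = self.points(re)
        return harmonic_ellipse(ph, x, y)


def sweep_table(rows) -> SweepResult:
    """Build a SweepResult from dict rows, checking the ratio identity."""
    df = pd.DataFrame(rows)
    if "ratio" not in df:
        df["ratio"] = df.CL / df.CPWR
    if not np.allclose(df.ratio * df.CPWR, df.CL, rtol=1e-12, atol=1e-12):
        raise ValueError("ratio column inconsistent with CL/CPWR")
    return SweepResult(df)
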