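"""Rigid-wing hovering kinematics.

A fruit-fly-like hovering stroke is prescribed by three Euler angles:

* positional (flapping) angle  ``theta_p = A_p cos(2 pi f t + phi_p)``  about z,
* feathering (pitch) angle     ``theta_f = A_f sin(2 pi f t + phi_f)``  about the
  wing's own spanwise axis, and
* elevation (deviation) angle  ``theta_e = A_e cos(2 pi (2 f) t - phi_e0) + phi_e``
  about the stroke-plane axis perpendicular to the span.

The elevation motion runs at twice the flapping frequency; its initial phase
``phi_e0`` selects the shape of the wing-tip path: a planar line for ``A_e = 0``,
a U-shape for ``phi_e0`` in {0, 180} deg and a self-intersecting figure-eight
otherwise.

Conventions: the body axis lies along y, lift along z and thrust along y.  The
two wings hinge at a common root (default: the lab origin) and sweep around the
+x / -x half-spaces; the left wing is the mirror image of the right through the
y-z plane.  At zero angles the right wing spans +x with its chord along z, so
the lab-to-wing rotation is ``Rz(theta_p) @ Ry(-theta_e) @ Rx(theta_f)``:
positive elevation raises the tip and feathering rides with the stroke.
Angles are degrees at the API surface and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "PhysicalWing",
    "WingKinematics",
    "PlateGeometry",
    "FlappingMotion",
    "OscillatingPlateMotion",
    "reynolds_number",
    "euler_angles",
    "AONO_WING",
    "AONO_KINEMATICS",
]


def reynolds_number(utip_bar: float, chord: float, nu: float) -> float:
    """Wing-tip Reynolds number ``Re = utip_bar * Cm / nu``."""
    if utip_bar <= 0 or chord <= 0 or nu <= 0:
        raise ValueError("Reynolds number inputs must be positive")
    return utip_bar * chord / nu


@dataclass(frozen=True)
class PhysicalWing:
    """Morphology and air properties of the modelled insect (SI units)."""

    body_length: float = 2.78e-3
    mean_chord: float = 0.78e-3
    wing_length: float = 2.39e-3
    utip_bar: float = 2.58
    frequency: float = 218.0
    nu_air: float = 1.5e-5
    rho_air: float = 1.2

    def __post_init__(self):
        for name in (
            "body_length",
            "mean_chord",
            "wing_length",
            "utip_bar",
            "frequency",
            "nu_air",
            "rho_air",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def reynolds(self) -> float:
        return reynolds_number(self.utip_bar, self.mean_chord, self.nu_air)

    @property
    def wing_area(self) -> float:
        """Combined planform area of both wings, ``SW = 2 Cm R``."""
        return 2.0 * self.mean_chord * self.wing_length

    def at_reynolds(self, re: float) -> "PhysicalWing":
        """Rescale tip speed and wingbeat frequency to hit a target Re.

        The tip speed and frequency scale together (the stroke shape is
        unchanged), mirroring the way the sweep varies Re.
        """
        scale = re / self.reynolds
        return replace(
            self, utip_bar=self.utip_bar * scale, frequency=self.frequency * scale
        )


AONO_WING = PhysicalWing()


@dataclass(frozen=True)
class WingKinematics:
    """Amplitudes (deg), phases (deg) and frequency (Hz) of the three motions."""

    amp_positional: float = 70.0
    amp_feathering: float = 70.0
    amp_elevation: float = 10.0
    phase_positional: float = 10.0
    phase_feathering: float = 0.0
    phase_elevation: float = 10.0
    elevation_initial_phase: float = 10.0
    frequency: float = 218.0

    def __post_init__(self):
        if min(self.amp_positional, self.amp_feathering, self.amp_elevation) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def has_figure_eight(self) -> bool:
        """Zero elevation amplitude classifies the motion as 'without figure-eight'."""
        return self.amp_elevation != 0.0

    def without_figure_eight(self) -> "WingKinematics":
        return replace(self, amp_elevation=0.0, phase_elevation=0.0)


AONO_KINEMATICS = WingKinematics()


def euler_angles(kin: WingKinematics, t) -> tuple:
    """(theta_p, theta_f, theta_e) in degrees at time(s) ``t`` (s, >= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    w = 2.0 * np.pi * kin.frequency
    tp = kin.amp_positional * np.cos(w * t + np.radians(kin.phase_positional))
    tf = kin.amp_feathering * np.sin(w * t + np.radians(kin.phase_feathering))
    te = (
        kin.amp_elevation
        * np.cos(2.0 * w * t - np.radians(kin.elevation_initial_phase))
        + kin.phase_elevation
    )
    return tp, tf, te


def classify_tip_path(kin: WingKinematics, tol_deg: float = 1.0) -> str:
    """Shape class of the tip path: ``"line"``, ``"U"`` or ``"eight"``.

    With zero elevation amplitude the tip stays on the stroke surface
    ("line").  Otherwise the elevation (frequency 2f) traces a 1:2 Lissajous
    figure against the stroke angle: when the elevation initial phase is 0 or
    180 deg the two half-strokes retrace one parabolic arc (a "U"); any other
    phase opens the arc into two lobes with a transversal self-crossing (a
    figure-eight).  The classification follows that phase relationship.
    """
    if kin.amp_elevation == 0.0:
        return "line"
    rem = kin.elevation_initial_phase % 180.0
    return "U" if min(rem, 180.0 - rem) <= tol_deg else "eight"


@dataclass(frozen=True)
class PlateGeometry:
    """Zero-thickness rectangular plate, rigid in its own frame.

    The span runs along the wing axis x_W from the root, the chord along the
    wing-frame z axis centred on the mid-chord line (the feathering axis).
    """

    chord: float
    span: float
    root_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    side: Literal["left", "right"] = "right"

    def __post_init__(self):
        if self.chord <= 0 or self.span <= 0:
            raise ValueError("plate chord and span must be positive")
        object.__setattr__(
            self, "root_offset", np.asarray(self.root_offset, dtype=float)
        )

    @property
    def area(self) -> float:
        return self.chord * self.span

    def sample_points(self, n_span: int, n_chord: int) -> np.ndarray:
        """Panel-centre sampling of the rectangle in the wing frame, (N, 3)."""
        s = (np.arange(n_span) + 0.5) / n_span * self.span
        c = ((np.arange(n_chord) + 0.5) / n_chord - 0.5) * self.chord
        S, C = np.meshgrid(s, c, indexing="ij")
        pts = np.zeros((n_span * n_chord, 3))
        pts[:, 0] = S.ravel()
        pts[:, 2] = C.ravel()
        return pts

    @property
    def corners(self) -> np.ndarray:
        """The four rectangle corners in the wing frame, (4, 3)."""
        c = 0.5 * self.chord
        return np.array(
            [[0, 0, -c], [self.span, 0, -c], [self.span, 0, c], [0, 0, c]],
            dtype=float,
        )


def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


_MIRROR_YZ = np.diag([-1.0, 1.0, 1.0])
# wing-frame reflection that maps the plate rectangle onto itself (flips the
# plate normal): composing it with the lab mirror keeps the rotation proper
_FLIP_NORMAL = np.diag([1.0, -1.0, 1.0])


class FlappingMotion:
    """Rigid-body motion of one flapping wing.

    Provides the wing-to-lab transform, wall velocities of material points and
    the wing-tip trajectory.  Wall velocity is evaluated by central differencing
    of the pose with a step much shorter than any solver time step.
    """

    def __init__(self, kin: WingKinematics, geom: PlateGeometry):
        self.kin = kin
        self.geom = geom

    def rotation(self, t: float) -> np.ndarray:
        """Orthonormal wing-to-lab rotation at time t (det +1)."""
        tp, tf, te = euler_angles(self.kin, t)
        r = _rot_z(np.radians(tp)) @ _rot_y(-np.radians(te)) @ _rot_x(np.radians(tf))
        if self.geom.side == "left":
            # true mirror image through the y-z plane: the wing-frame leg of
            # the conjugation flips the plate normal (not the span), so the
            # rectangle maps onto its mirror twin and det stays +1
            r = _MIRROR_YZ @ r @ _FLIP_NORMAL
        return r

    def transform(self, t: float):
        """(rotation, translation): lab point = R @ wing point + root."""
        root = self.geom.root_offset
        if self.geom.side == "left":
            root = _MIRROR_YZ @ root
        return self.rotation(t), root

    def to_lab(self, t: float, pts_wing) -> np.ndarray:
        r, root = self.transform(t)
        return np.asarray(pts_wing, dtype=float) @ r.T + root

    def wall_velocity(self, t: float, pts_wing, dt: float | None = None) -> np.ndarray:
        """Lab-frame velocity of wing-frame material points (central difference)."""
        if dt is None:
            dt = self.kin.period * 1e-6
        lo = max(t - dt, 0.0)
        hi = t + dt
        return (self.to_lab(hi, pts_wing) - self.to_lab(lo, pts_wing)) / (hi - lo)

    def tip_point(self) -> np.ndarray:
        """Wing-frame point used as 'the tip': mid-chord at full span."""
        return np.array([self.geom.span, 0.0, 0.0])

    def tip_trajectory(self, n: int) -> np.ndarray:
        """Ordered lab-frame tip positions over one period, shape (n, 3)."""
        if n < 8:
            raise ValueError("need at least 8 samples for a trajectory")
        ts = np.arange(n) / n * self.kin.period
        return np.array([self.to_lab(t, self.tip_point()) for t in ts])

    def mean_tip_speed(self, n: int = 2000) -> float:
        """Cycle-mean |tip velocity| by quadrature (cross-check against utip_bar)."""
        ts = np.arange(n) / n * self.kin.period
        v = np.array([self.wall_velocity(t, self.tip_point()) for t in ts])
        return float(np.linalg.norm(v, axis=1).mean())

    def tip_path_length(self, n: int = 2000) -> float:
        """Closed tip-path length over one cycle."""
        traj = self.tip_trajectory(n)
        seg = np.diff(np.vstack([traj, traj[:1]]), axis=0)
        return float(np.linalg.norm(seg, axis=1).sum())


class OscillatingPlateMotion:
    """Heave-plus-pitch validation motion of a rectangular plate.

    The plate's centre translates along x as ``x(t) = L sin(2 pi f t)`` while
    the plate pitches about its spanwise (y) axis through the centre as
    ``theta(t) = pi/2 - (pi/4) sin(2 pi f t + pi/3)``; ``theta`` is measured
    from the x axis, so theta = pi/2 holds the plate broadside to the heave.
    """

    def __init__(self, stroke: float, frequency: float, chord: float, span: float):
        self.stroke = stroke
        self.frequency = frequency
        self.geom = PlateGeometry(chord=chord, span=span)

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def angle(self, t: float) -> float:
        return np.pi / 2 - (np.pi / 4) * np.sin(
            2 * np.pi * self.frequency * t + np.pi / 3
        )

    def displacement(self, t: float) -> float:
        return self.stroke * np.sin(2 * np.pi * self.frequency * t)

    def transform(self, t: float):
        # span along lab y; chord direction (cos th, 0, sin th) pitched about y
        th = self.angle(t)
        span_dir = np.array([0.0, 1.0, 0.0])
        chord_dir = np.array([np.cos(th), 0.0, np.sin(th)])
        r = np.column_stack([span_dir, np.cross(chord_dir, span_dir), chord_dir])
        centre = np.array([self.displacement(t), 0.0, 0.0])
        root = centre - r @ np.array([0.5 * self.geom.span, 0.0, 0.0])
        return r, root

    def to_lab(self, t: float, pts_wing) -> np.ndarray:
        r, root = self.transform(t)
        return np.asarray(pts_wing, dtype=float) @ r.T + root

    def wall_velocity(self, t: float, pts_wing, dt: float | None = None) -> np.ndarray:
        if dt is None:
            dt = self.period * 1e-6
        return (self.to_lab(t + dt, pts_wing) - self.to_lab(max(t - dt, 0), pts_wing)) / (
            t + dt - max(t - dt, 0)
        )
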