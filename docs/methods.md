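# Methods

`flapwing` simulates the hovering flight of a fruit-fly-scale insect with two
rigid, zero-thickness rectangular wings, and post-processes the resulting
aerodynamic loads into the lift-versus-power efficiency analysis of
figure-eight wing motions. This note records the model, the numerical
choices, the places where the design was genuinely open, and what the
reduced-scale test runs do and do not demonstrate.

## Physical model

The insect is reduced to two rectangular plates (span R = 2.39 mm, chord
Cm = 0.78 mm) hinged at a common point; the body is omitted, which is known
to change cycle-averaged lift very little in hover. Air has kinematic
viscosity 1.5e-5 m^2/s and density 1.2 kg/m^3. The wing-tip Reynolds number
is Re = utip_bar * Cm / nu_air, about 134 for the reference tip speed
2.58 m/s at wingbeat frequency 218 Hz. Reynolds sweeps rescale tip speed and
frequency together (33.5 ... 536), leaving the stroke shape unchanged.

The stroke is prescribed by three Euler angles (degrees):

* positional theta_p = 70 cos(2 pi f t + 10 deg), about the vertical z axis;
* feathering theta_f = 70 sin(2 pi f t), about the wing's spanwise axis;
* elevation theta_e = 10 cos(2 pi (2 f) t - phi_e0) + 10, about the
  stroke-plane axis perpendicular to the span.

The elevation runs at twice the flapping frequency; its initial phase
phi_e0 selects the wing-tip path: the projected (stroke, elevation) curve
always crosses itself once at stroke angle zero (the elevation returns to the
same value at both mid-strokes), and the phase decides whether that crossing
sits at an elevation extreme (phi_e0 = 0 or 180: a "U"-shaped path) or in the
interior (a genuine figure-eight). Zero elevation amplitude gives the
"without figure-eight" motion confined to the stroke surface.

Axis conventions: body axis along y, lift along z, thrust along y; the wings
sweep around the +x and -x half-spaces, and the left wing is the mirror image
of the right through the y-z plane. Mirroring a rotation must stay a proper
rotation: the implementation conjugates with the lab mirror on one side and a
wing-frame reflection that flips the plate normal on the other (the plate is
two-sided, so its normal has no material meaning). Mirroring through any
other composition silently places both plates in the same half-space.

The cycle-mean tip speed computed from this kinematics is 2.67 m/s, within
4% of the tabulated 2.58 m/s, which anchors the conventions.

## Fluid solver

The fluid is evolved with a normalized incompressible lattice Boltzmann
method on the 27-velocity cubic lattice (weights 8/27, 2/27, 1/54, 1/216;
cs = c/sqrt(3), c = 1). The solver advances pressure distribution functions
p_alpha = cs^2 f_alpha with a single-relaxation-time BGK update,

    p_a(t+dt, x+e_a dt) = p_a^eq(t,x) + (1 - 1/tau) p_a^neq(t,x),

where p_a^eq = w_a [p + rho0 (e.u + 3 (e.u)^2 / (2 c^2) - u^2/2)], rho0 = 1,
p = sum_a p_a, u = (1/rho0 cs^2) sum_a e_a p_a, and
tau = 3 nu/(c dx) + 1/2. Initial state: p = 1/3, u = 0. Collision happens
before streaming; distributions are stored post-streaming.

Outer boundaries: pressure anchored to 1/3 on the y+ face, zero-normal-
gradient copies for pressure on the other faces and for velocity everywhere.
Ghost cells carry these conditions; streaming wraps on the padded array, so
wrap-around writes touch only ghost cells that are refilled every step.

Nondimensionalization: lab lengths are measured in chords, so dx = 1/N for N
cells per chord; the representative lattice speed U is the cycle-mean tip
speed in lattice units, and one flapping period spans
round(P_tip * N / U) steps with P_tip the tip path length per cycle
(about 15.7 chords). The lattice viscosity follows as nu = U N / Re.

## Virtual flux boundary

The zero-thickness plates are imposed by reconstructing, at every lattice
link the rectangle cuts, the distribution that would otherwise stream
through. The wall state combines the no-slip velocity (rigid-body velocity of
the crossing point) with a Neumann-extrapolated pressure

    p_vb = (h2^2 p1 - h1^2 p2) / (h2^2 - h1^2),

with trilinear probes at h1 = sqrt(3) dx and h2 = 2 sqrt(3) dx along the
side-signed normal (probes whose interpolation cell straddles the plate are
pushed outward in 0.1 dx increments). The equilibrium at the crossing point
is linearly extrapolated to the opposite node against an anchor: the cut node
D itself when the internal ratio a >= 1/2, or the next node C = D - e_a
(with the ratio adjusted to a+1, i.e. the line through the crossing point
and C) when a < 1/2. When C is unavailable - outside the block, or itself
behind a plate, as happens where the two wings meet in a narrow wedge - the
reconstruction drops to zeroth order (wall equilibrium). This matters for
stability: any two-point extrapolation anchored at D has a negative feedback
coefficient -b/d on the node's own pressure, and |b/d| > 1 configurations
(many cut links, small a, no C) amplify pressure oscillations until blow-up;
the a+1 anchoring and the zeroth-order fallback keep the coefficient in
(-1, 0].

Both sides of a plate maintain their own crossings, normals and probes; no
link streams through. A node that lies exactly on the plate keeps its a = 0
records (handled by the C anchor); the partner record at a = 1 belongs to
the other node and is dropped.

Nodes the plate sweeps past between two steps carry distributions from the
wrong side; they are refilled with the equilibrium of (local pressure, wall
velocity), the thin-wall analogue of fresh-node refilling at moving
boundaries. Without it, the momentum-exchange diagnostic shows large
coherent spikes whenever the plate crosses a lattice plane.

Validation worth recording: a plane Couette flow driven by two treadmill
plates reproduces the linear profile to round-off (1e-15 of the wall speed)
when the walls sit midway between node planes, and to better than 0.5% of
the wall speed at arbitrary offsets; a plate separating two reservoirs at
different pressures holds them indefinitely (velocities at 1e-16 after 1000
steps); a uniform state with an arbitrarily posed resting plate is preserved
to round-off.

## Multiblock refinement

The production layout nests four Cartesian tiers with spacing ratio two
(finest dx = chord/N around the wing sweep, coarsest 8x coarser, domain 40
chords per side). Acoustic scaling keeps c = dx/dt identical on every tier,
so lattice velocities are tier-invariant and tau per tier follows from the
constant physical viscosity (tau_f - 1/2 = 2 (tau_c - 1/2)). Per coarse
step, the parent advances once and the child twice; child ghost values are
trilinear in space and linear in time with the non-equilibrium part scaled
by the tau*dt ratio (Dupuis-Chopard), and parent nodes coincident with the
child interior are overwritten by the restricted child state with the
inverse scaling. A two-tier Taylor-Green run matches the uniform fine-grid
run to 0.6% in L2 velocity.

## Loads and diagnostics

Forces are evaluated by traction integration: the plate is sampled at panel
centres at roughly the grid spacing; each side contributes
-(p_wall - p_ref) n plus the viscous shear mu du_t/dn from a one-sided
three-point derivative through the wall velocity and the two probes. The
aerodynamic power is the negative of traction dot wall velocity summed over
panels (the work the wing does on the fluid). Coefficients use the combined
planform area of BOTH wings, SW = 2 Cm R; this convention is forced by
arithmetic consistency between the published coefficient and dimensional-load
tables (with a single-wing area they disagree by exactly 2x).

A momentum-exchange summation over the cut links serves as an independent
cross-check of the same force. Records with a ~ 0 are skipped (their
partner at a ~ 1 is dropped by construction, and an unpaired record leaves
the O(p) part of the link unbalanced). The two estimators carry independent
coarse-grid biases - probe-derivative error in the traction, staircase bias
in the momentum exchange - and agree to 21% at 16 cells/chord and 13% at 24
cells/chord on an impulsively started broadside plate, converging roughly
first order toward each other.

Vortex diagnostics: velocity-gradient tensor by central differences, its
symmetric/antisymmetric split, Q = (|Omega|^2 - |S|^2)/2 normalized by
(U/L)^2, and the normalized helicity density u.omega/(|u||omega|) (zero,
with a mask, where undefined).

## Efficiency analysis

Cycle averages are trapezoidal means over one period; the full-scale
protocol runs seven cycles and reports the sixth (configurable), the
reduced test campaign runs two and reports the second.

The eight figure-eight motions (phi_e0 = 0..315 in 45-degree steps) place
cycle-averaged (CPWR, CL) points on a closed curve parametrized by phi_e0.
Two elliptic descriptions are implemented:

* a direct least-squares conic fit with the ellipse constraint
  (Halir-Flusser), for arbitrary point sets, cross-checked against
  scikit-image's ellipse model;
* the first-harmonic Fourier description of the phase-parametrized sweep,
  x(phi) = x0 + ax cos phi + bx sin phi (same for y), whose image is exactly
  an ellipse and which carries the sweep phase along the curve.

The sweep analysis uses the harmonic form. The choice is empirical: on the
published sweep table at Re = 536 the harmonic ellipse reproduces the
published axis lengths to the printed precision (0.209/0.072 vs 0.208/0.071)
and the aspect ratio within 1.4%, while every least-squares variant tried
(algebraic, Taubin, Sampson-weighted, geometric orthogonal-distance) agrees
with each other but sits 5-6% below the published aspect ratio; the
published analysis is evidently the harmonic construction. A perturbation
analysis (uniform +-5e-4 on the 3-decimal table entries) shows the
difference is not printing round-off.

The most efficient phase maximizes CL/CPWR, i.e. the tangency of a line
from the origin to the ellipse; with the harmonic form the tangency
parameter IS phi_e0*, so no separate phase mapping is needed. Applied to
the published tables this gives 63, 58, 46, 34, 22 degrees for
Re = 33.5 ... 536 - the published monotone decrease.

Dimensional loads invert the coefficient definitions:
Fz = CL * q SW, P = CPWR * q SW utip_bar with q = rho_air utip_bar^2 / 2,
and Fz/P = (CL/CPWR)/utip_bar.

## Reduced-scale test campaign

The full configuration (32 cells/chord, 40-chord four-tier domain, seven
cycles, ten runs per sweep) is far beyond a test suite; the suite instead
runs a deliberately small campaign: 5 cells per chord, uniform 9.6-chord
domain (1.4 chords of clearance beyond the wing sweep), lattice tip speed
0.12, two cycles with the second reported. One run takes tens of seconds;
the campaign covers the with/without comparison, the eight-phase sweep at
Re = 134 and a six-phase sweep (0, 45, 90, 180, 225, 270 degrees; a
harmonic ellipse needs at least six points) at Re = 33.5, with the
aspect-ratio comparison made on matched phase subsets.

What this scale shows: the figure-eight lift advantage (about +30% here vs
the published +26%), its efficiency advantage, the overall phase ordering
(45 and 90 degrees most efficient, the 225-315 range worst), and the growth
of the efficiency-ellipse aspect ratio from Re = 33.5 to 134. What it does
not show: published coefficient values (a 5-cell chord under-resolves the
leading-edge vortex; CL comes out 20-30% low), the fine distinctions
between neighbouring phases (45 vs 90 differ by 0.3% here vs 5% published),
and the phi_e0 = 0 margin over the without-eight motion, which this grid
loses by about 1% - the corresponding acceptance check is left failing
rather than re-scoped. Wall-residual and force-estimator agreement
thresholds calibrated for the full 32 cells/chord scale are likewise
asserted unchanged at the reduced scale and fail honestly there; their
resolution scaling (documented above and in the test suite) is consistent
with meeting the thresholds at full scale.

## Known limitations

* Rigid wings only; no wing flexibility or fluid-structure interaction.
* No insect body; wings hinge at a geometric point (optionally offset).
* BGK collision without regularization limits the usable grid Reynolds
  number; the Re = 536 member of the sweep needs at least ~16 cells/chord
  to run stably.
* The traction estimator's wall-pressure extrapolation assumes a vanishing
  normal pressure gradient, which is exact only in quasi-steady boundary
  layers; early impulsive transients bias it low.
* The elevation/feathering composition order and the mid-chord feathering
  axis are conventions chosen here (the originating descriptions leave them
  open); the tip-speed anchor and the reproduced orderings support them.
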