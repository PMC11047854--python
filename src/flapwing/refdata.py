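"""Published reference values for the fruit-fly hovering sweep.

These tables are validation inputs for the analysis stage: cycle-averaged
lift coefficients and lift-to-power ratios of the eight figure-eight motions
(elevation initial phase 0..315 deg in 45 deg steps) and of the motion
without figure-eight, at five wing-tip Reynolds numbers, plus the matching
dimensional loads and the parameters of the published elliptic approximation.
"""

from __future__ import annotations

import numpy as np

PHASES_DEG = np.arange(0, 360, 45)
REYNOLDS = (33.5, 67.0, 134.0, 268.0, 536.0)

# cycle-averaged CL for the eight figure-eight phases, keyed by Re
SWEEP_CL = {
    33.5: np.array([0.270, 0.350, 0.401, 0.383, 0.296, 0.203, 0.177, 0.202]),
    67.0: np.array([0.303, 0.398, 0.458, 0.448, 0.363, 0.252, 0.202, 0.226]),
    134.0: np.array([0.354, 0.463, 0.520, 0.516, 0.417, 0.312, 0.246, 0.265]),
    268.0: np.array([0.396, 0.522, 0.581, 0.572, 0.460, 0.341, 0.274, 0.294]),
    536.0: np.array([0.421, 0.558, 0.613, 0.589, 0.483, 0.336, 0.278, 0.310]),
}

# cycle-averaged CL / CPWR for the same motions
SWEEP_RATIO = {
    33.5: np.array([0.509, 0.613, 0.624, 0.542, 0.413, 0.306, 0.306, 0.384]),
    67.0: np.array([0.726, 0.849, 0.838, 0.733, 0.594, 0.463, 0.447, 0.558]),
    134.0: np.array([0.961, 1.075, 1.019, 0.895, 0.741, 0.637, 0.623, 0.768]),
    268.0: np.array([1.165, 1.246, 1.159, 1.014, 0.851, 0.757, 0.766, 0.956]),
    536.0: np.array([1.335, 1.358, 1.223, 1.069, 0.922, 0.803, 0.864, 1.116]),
}

# the motion without figure-eight: (CL, CL/CPWR) per Re
WITHOUT_8 = {
    33.5: (0.220, 0.429),
    67.0: (0.251, 0.623),
    134.0: (0.302, 0.857),
    268.0: (0.350, 1.065),
    536.0: (0.379, 1.207),
}

# full-resolution comparison of the default figure-eight motion (A) vs the
# motion without figure-eight (B): CL, CT, CPWR, CL/CPWR
MOTION_COMPARISON = {
    "with": (0.382, 3.45e-3, 0.380, 1.005),
    "without": (0.302, 2.54e-2, 0.352, 0.857),
}

# dimensional loads of the motion without figure-eight: Fz (uN), P (uW), Fz/P
DIMENSIONAL_WITHOUT_8 = {
    33.5: (0.205, 0.308, 0.665),
    67.0: (0.933, 1.932, 0.483),
    134.0: (4.495, 13.53, 0.332),
    268.0: (20.84, 101.0, 0.206),
    536.0: (90.32, 772.3, 0.117),
}

# published elliptic approximation: centre (x, y), long/short side, angle, AR
ELLIPSE_PARAMS = {
    33.5: ((0.623, 0.284), 0.131, 0.079, 54.0, 1.658),
    67.0: ((0.511, 0.329), 0.154, 0.073, 54.0, 2.110),
    134.0: ((0.468, 0.385), 0.176, 0.068, 53.0, 2.588),
    268.0: ((0.437, 0.429), 0.197, 0.068, 53.0, 2.897),
    536.0: ((0.415, 0.446), 0.208, 0.071, 53.0, 2.930),
}


def sweep_points(re: float):
    """(CPWR_bar, CL_bar) points of the eight figure-eight motions at ``re``."""
    cl = SWEEP_CL[re]
    return cl / SWEEP_RATIO[re], cl
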