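"""Embedded example data sets.

Three families ship with the package:

* ``degrees`` — a 2 (gender) x 4 (academic degree) table of degrees earned in
  US higher education in 2010-2011 (n = 2403).
* ``eyetracking`` — a 5 x 5 x 5 table of gaze locations (areas of interest)
  of two interacting persons at three time points (n = 8851 video frames),
  with many sampling zeros.
* ``sim_case{1..4}_phi{10,30,50}`` — the 2 x 4 population probability vectors
  used by the selection-rate simulation, one per (true hypothesis, Cramer's V)
  condition.  Each carries the cell positions that the simulation design
  forces to an observed zero (``star_cells``).

`reported_degrees_estimates` / `reported_eyetracking_estimates` return the
published reference estimates and bootstrap covariances for the two examples
(to the precision of the source tables); they are handy as deterministic
inputs for the fit and penalty stages without re-running a bootstrap.
"""

from __future__ import annotations

import numpy as np

from .tables import ContingencyTable, ProbabilityVector

__all__ = [
    "load_fixture",
    "available_fixtures",
    "SIM_POPULATIONS",
    "reported_degrees_estimates",
    "reported_eyetracking_estimates",
]

# 2 x 4: gender (female, male) x degree (bachelor's, master's, professional,
# doctorate)
_DEGREES = np.array([[933, 402, 51, 26], [661, 260, 44, 26]])
_DEGREES_LABELS = [
    ["female", "male"],
    ["bachelors", "masters", "professional", "doctorate"],
]

# 5 x 5 x 5 gaze table: person 1 at t, person 2 at t+20, person 2 at t+200;
# levels are nose, mouth, right eye, left eye, none.
_EYE = np.array(
    [
        [  # person 1: nose
            [51, 2, 42, 46, 7],
            [4, 0, 5, 3, 0],
            [44, 4, 174, 39, 2],
            [14, 3, 34, 36, 4],
            [4, 1, 26, 11, 0],
        ],
        [  # person 1: mouth
            [1, 0, 1, 2, 0],
            [0, 0, 0, 0, 0],
            [5, 0, 4, 2, 0],
            [1, 0, 3, 0, 0],
            [0, 0, 0, 0, 0],
        ],
        [  # person 1: right eye
            [1006, 112, 921, 495, 91],
            [81, 1, 79, 22, 2],
            [1084, 109, 1909, 397, 134],
            [486, 42, 419, 220, 33],
            [63, 3, 151, 26, 1],
        ],
        [  # person 1: left eye
            [34, 3, 7, 21, 1],
            [8, 0, 2, 1, 0],
            [23, 0, 20, 13, 3],
            [6, 11, 5, 0, 0],
            [0, 0, 3, 0, 0],
        ],
        [  # person 1: none
            [28, 0, 18, 4, 7],
            [0, 0, 2, 0, 0],
            [22, 2, 98, 14, 1],
            [5, 0, 25, 0, 0],
            [2, 0, 0, 0, 0],
        ],
    ]
)
_AOI = ["nose", "mouth", "right_eye", "left_eye", "none"]

# Simulation populations: 2 x 4 probabilities (row-major, 4-decimal printed
# values) and the cells forced to zero after data generation.  Cases 1-3 are
# generated under the ordered/equality hypotheses of the degrees example;
# case 4 satisfies none of them.
SIM_POPULATIONS: dict[str, dict] = {
    "sim_case1_phi10": {
        "pi": [0.1170, 0.1170, 0.1170, 0.1170, 0.1810, 0.1170, 0.1170, 0.1170],
        "stars": [(1, 2)],
    },
    "sim_case1_phi30": {
        "pi": [0.0787, 0.0787, 0.0787, 0.0787, 0.3706, 0.0787, 0.0787, 0.1573],
        "stars": [(1, 2)],
    },
    "sim_case1_phi50": {
        "pi": [0.0224, 0.0224, 0.0224, 0.0224, 0.7986, 0.0224, 0.0224, 0.0670],
        "stars": [(1, 2)],
    },
    "sim_case2_phi10": {
        "pi": [0.0569, 0.0569, 0.1708, 0.1708, 0.0569, 0.0569, 0.2598, 0.1710],
        "stars": [(1, 0), (1, 1)],
    },
    "sim_case2_phi30": {
        "pi": [0.0413, 0.0413, 0.1237, 0.1237, 0.0413, 0.0413, 0.4636, 0.1238],
        "stars": [(1, 0), (1, 1)],
    },
    "sim_case2_phi50": {
        "pi": [0.0347, 0.0347, 0.1040, 0.1040, 0.0347, 0.0347, 0.6185, 0.0347],
        "stars": [(1, 0), (1, 1)],
    },
    "sim_case3_phi10": {
        "pi": [0.1071, 0.1071, 0.1071, 0.1071, 0.1857, 0.1501, 0.1287, 0.1071],
        "stars": [(1, 3)],
    },
    "sim_case3_phi30": {
        "pi": [0.0618, 0.0618, 0.0618, 0.0618, 0.4069, 0.1853, 0.0988, 0.0618],
        "stars": [(1, 3)],
    },
    "sim_case3_phi50": {
        "pi": [0.0075, 0.0199, 0.0199, 0.0199, 0.4979, 0.2324, 0.1992, 0.0033],
        "stars": [(1, 3)],
    },
    "sim_case4_phi10": {
        "pi": [0.1070, 0.1070, 0.1070, 0.1070, 0.1071, 0.1287, 0.1501, 0.1861],
        "stars": [(1, 0)],
    },
    "sim_case4_phi30": {
        "pi": [0.0581, 0.0581, 0.0581, 0.0581, 0.0614, 0.0988, 0.2015, 0.4059],
        "stars": [(1, 0)],
    },
    "sim_case4_phi50": {
        "pi": [0.0560, 0.0514, 0.0514, 0.0514, 0.0017, 0.1028, 0.2570, 0.4283],
        "stars": [(1, 0)],
    },
}


def available_fixtures() -> list[str]:
    return ["degrees", "eyetracking", *SIM_POPULATIONS.keys()]


def load_fixture(name: str):
    """Return a packaged data set by name.

    ``degrees`` and ``eyetracking`` return a :class:`ContingencyTable` of
    observed counts; the ``sim_*`` names return a :class:`ProbabilityVector`
    (the printed 4-decimal values renormalized to sum exactly to 1, as
    multinomial sampling requires) with the designed zero cells attached as
    ``star_cells``.
    """
    if name == "degrees":
        return ContingencyTable(
            _DEGREES.copy(), labels=_DEGREES_LABELS,
            factor_names=["gender", "degree"],
        )
    if name == "eyetracking":
        return ContingencyTable(
            _EYE.copy(), labels=[_AOI, _AOI, _AOI],
            factor_names=["p1_t", "p2_t20", "p2_t200"],
        )
    if name in SIM_POPULATIONS:
        rec = SIM_POPULATIONS[name]
        pi = np.asarray(rec["pi"], dtype=float)
        return ProbabilityVector(
            pi / pi.sum(), (2, 4), star_cells=tuple(rec["stars"])
        )
    raise KeyError(
        f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
    )


def reported_degrees_estimates() -> tuple[np.ndarray, np.ndarray]:
    """Published reference (eta_hat, Sigma_hat) for the degrees example.

    eta are the four male-given-degree conditional probabilities; the
    covariance is a nonparametric-bootstrap estimate reported to two
    significant figures.
    """
    eta = np.array([0.415, 0.393, 0.463, 0.500])
    low = [
        [1.4e-4],
        [5.1e-6, 3.7e-4],
        [5.2e-6, 3.9e-6, 2.8e-3],
        [5.8e-6, 6.5e-5, -8.4e-6, 5.2e-3],
    ]
    return eta, _symmetrize(low, 4)


def reported_eyetracking_estimates() -> tuple[np.ndarray, np.ndarray]:
    """Published reference (eta_hat, adjusted Sigma_hat) for the gaze example.

    eta are 12 two-way marginal probabilities; components 3 and 4 are sampling
    zeros, whose zero bootstrap variances have already been replaced by the
    smallest positive diagonal entry (3.2e-7) with off-diagonals kept at 0.
    """
    eta = np.array(
        [0.017, 0.013, 0.000, 0.000, 0.410, 0.393,
         0.136, 0.131, 0.007, 0.004, 0.002, 0.004]
    )
    low = [
        [1.8e-6],
        [6.2e-7, 1.5e-6],
        [0.0, 0.0, 3.2e-7],
        [0.0, 0.0, 0.0, 3.2e-7],
        [-1.1e-6, -2.9e-7, 0.0, 0.0, 2.8e-5],
        [-5.8e-7, -4.9e-7, 0.0, 0.0, 6.7e-6, 2.6e-5],
        [-2.6e-7, -4.2e-7, 0.0, 0.0, -6.4e-6, -3.1e-7, 1.3e-5],
        [-2.3e-7, -2.5e-7, 0.0, 0.0, -1.5e-6, -5.3e-6, 4.0e-7, 1.2e-5],
        [-1.4e-8, -4.6e-8, 0.0, 0.0, -2.2e-7, -2.1e-7, 2.8e-8, -2.0e-7, 7.2e-7],
        [-5.6e-8, -5.5e-9, 0.0, 0.0, -2.0e-8, -1.8e-7, -3.1e-8, -6.2e-8,
         2.4e-7, 4.5e-7],
        [1.6e-8, -1.0e-8, 0.0, 0.0, -1.2e-8, -1.1e-7, 3.9e-8, -9.0e-8,
         8.9e-9, 5.4e-8, 3.2e-7],
        [-1.8e-8, -2.2e-8, 0.0, 0.0, -2.4e-7, -2.3e-7, -1.5e-8, -1.2e-7,
         1.6e-7, -1.2e-9, -7.4e-9, 4.2e-7],
    ]
    return eta, _symmetrize(low, 12)


def _symmetrize(lower_rows: list[list[float]], k: int) -> np.ndarray:
    m = np.zeros((k, k))
    for i, row in enumerate(lower_rows):
        m[i, : len(row)] = row
    return m + np.tril(m, -1).T
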