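import numpy as np
import pytest

import goricatab as gt
from goricatab.fixtures import (reported_degrees_estimates,
                                reported_eyetracking_estimates)
from goricatab.reparam import marginal_pattern_spec

# the 12 two-way marginal patterns of the gaze example, in report order:
# (p11+, p1+1, p22+, p2+2, p33+, p3+3, p34+, p3+4, p43+, p4+3, p44+, p4+4)
EYE_PATTERNS = [
    (0, 0, None), (0, None, 0), (1, 1, None), (1, None, 1),
    (2, 2, None), (2, None, 2), (2, 3, None), (2, None, 3),
    (3, 2, None), (3, None, 2), (3, 3, None), (3, None, 3),
]


@pytest.fixture(scope="session")
def degrees():
    return gt.load_fixture("degrees")


@pytest.fixture(scope="session")
def degrees_spec(degrees):
    return gt.builtin_spec("conditional_row", degrees.dims, level=1)


@pytest.fixture(scope="session")
def degrees_hset(degrees_spec):
    return gt.load_packaged_set("degrees", degrees_spec.names)


@pytest.fixture(scope="session")
def degrees_reported():
    return reported_degrees_estimates()


@pytest.fixture(scope="session")
def eyetracking():
    return gt.load_fixture("eyetracking")


@pytest.fixture(scope="session")
def eye_spec(eyetracking):
    return marginal_pattern_spec(eyetracking.dims, EYE_PATTERNS)


@pytest.fixture(scope="session")
def eye_hset(eye_spec):
    return gt.load_packaged_set("eyetracking", eye_spec.names)


@pytest.fixture(scope="session")
def eye_reported():
    return reported_eyetracking_estimates()


def grid_minimize(eta_hat, sigma, h, lo=-3.0, hi=3.0, steps=61, refine=3):
    """Independent dense-grid minimizer of the Mahalanobis distance subject
    to a hypothesis's constraints; oracle for K <= 3 systems."""
    inv = np.linalg.inv(sigma)
    k = len(eta_hat)
    center = np.array(eta_hat, dtype=float)
    width = hi - lo
    best = None
    for _ in range(refine + 1):
        axes = [np.linspace(c - width / 2, c + width / 2, steps)
                for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=1)
        tol = width / steps  # feasibility blur of one grid cell
        mask = np.ones(len(pts), dtype=bool)
        if h.n_eq:
            mask &= (np.abs(pts @ h.S.T - h.s) <= tol).all(axis=1)
        if h.n_ineq:
            mask &= (pts @ h.R.T - h.r >= -tol).all(axis=1)
        if not mask.any():
            width *= 1.5
            continue
        cand = pts[mask]
        d = cand - eta_hat
        obj = np.einsum("ij,jk,ik->i", d, inv, d)
        best = cand[np.argmin(obj)]
        center = best
        width = 4 * width / steps
    return best
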