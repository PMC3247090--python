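from itertools import combinations

import numpy as np
import pytest

from ladafl import CGHProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def noisy_step_profile(rng):
    """Step profile 0 -> 1 with small noise, n=6."""
    values = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]) + rng.normal(0, 0.01, 6)
    return CGHProfile(values=values)


def lad_vertex_oracle(design: np.ndarray, response: np.ndarray) -> float:
    """Exact global minimum of ``|response - design @ beta|_1``.

    The objective is piecewise linear and convex, so a minimum is
    attained at a vertex where some n rows of the design have zero
    residual.  Enumerate all invertible n-row subsets (plus beta = 0
    as a guard) and return the best objective.  Independent of the LP
    route; only feasible for small n.
    """
    design = np.asarray(design, dtype=float)
    response = np.asarray(response, dtype=float)
    m, n = design.shape
    best = float(np.abs(response).sum())  # beta = 0
    for rows in combinations(range(m), n):
        sub = design[list(rows)]
        if abs(np.linalg.det(sub)) < 1e-12:
            continue
        beta = np.linalg.solve(sub, response[list(rows)])
        obj = float(np.abs(response - design @ beta).sum())
        best = min(best, obj)
    return best
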