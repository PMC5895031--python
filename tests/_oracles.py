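"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the algorithms they check: the rigid-superposition
oracle searches rotation space numerically instead of solving it in closed
form, and the radius-of-gyration oracle evaluates the defining formula with
plain Python loops.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def rotation_search_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
    n_starts: int = 40,
    seed: int = 0,
) -> float:
    """Minimal weighted RMSD over proper rotations via multi-start search.

    Centres both point sets, then minimises the RMSD as a function of a
    rotation vector with Nelder-Mead from many random orientations.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    n = mobile.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    x = mobile - (w[:, None] * mobile).sum(axis=0)
    y = reference - (w[:, None] * reference).sum(axis=0)

    def cost(rotvec: np.ndarray) -> float:
        diff = x @ Rotation.from_rotvec(rotvec).as_matrix().T - y
        return math.sqrt(float((w * (diff**2).sum(axis=1)).sum()))

    rng = np.random.default_rng(seed)
    best = math.inf
    starts = [np.zeros(3)]
    for _ in range(n_starts):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        starts.append(axis * rng.uniform(0.0, math.pi))
    for s in starts:
        res = minimize(
            cost, s, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 2000},
        )
        best = min(best, float(res.fun))
    return best


def direct_radius_of_gyration(masses, coords) -> float:
    """Rg by direct evaluation of its definition, loop by loop."""
    total = 0.0
    com = [0.0, 0.0, 0.0]
    for m, xyz in zip(masses, coords):
        total += m
        for d in range(3):
            com[d] += m * xyz[d]
    com = [c / total for c in com]
    acc = 0.0
    for m, xyz in zip(masses, coords):
        acc += m * sum((xyz[d] - com[d]) ** 2 for d in range(3))
    return math.sqrt(acc / total)
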