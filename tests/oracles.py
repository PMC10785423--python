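"""Independent oracles for the minimax fitter, kept free of the LP path.

The grid-search oracle minimises the uniform error by exhaustive
evaluation over a coefficient box, refined in stages around the current
best point.  It shares no code with the linear-feasibility route: the
objective max_i |y_i - p(x_i)/q(x_i)| is evaluated directly.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


def grid_minimax(
    x: np.ndarray,
    y: np.ndarray,
    num_powers: tuple[int, ...],
    den_powers: tuple[int, ...],
    box: list[tuple[float, float]],
    points_per_dim: int = 21,
    stages: int = 8,
    delta: float = 1e-6,
) -> tuple[float, np.ndarray]:
    """Best uniform error over the coefficient box, by refined dense search.

    Returns ``(z, theta)``; ``z`` is an upper bound on the true optimum
    restricted to the box, tight to roughly the final grid spacing.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    phi = np.column_stack([x**p for p in num_powers])
    psi = (
        np.column_stack([x**p for p in den_powers])
        if den_powers
        else np.zeros((len(x), 0))
    )
    k = phi.shape[1] + psi.shape[1]
    assert len(box) == k

    def objective(theta: np.ndarray) -> float:
        p = phi @ theta[: phi.shape[1]]
        q = 1.0 + psi @ theta[phi.shape[1]:]
        if (q < delta).any():
            return np.inf
        return float(np.max(np.abs(y - p / q)))

    lo = np.array([b[0] for b in box], float)
    hi = np.array([b[1] for b in box], float)
    best_z, best_theta = np.inf, None
    seeds = []
    for _ in range(stages):
        axes = [np.linspace(a, b, points_per_dim) for a, b in zip(lo, hi)]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, k)
        a_part = mesh[:, : phi.shape[1]]
        b_part = mesh[:, phi.shape[1]:]
        p = a_part @ phi.T                       # (n_candidates, n_points)
        q = 1.0 + b_part @ psi.T
        with np.errstate(divide="ignore", invalid="ignore"):
            resid = np.abs(y[None, :] - p / q)
        z = np.where((q < delta).any(axis=1), np.inf, resid.max(axis=1))
        idx = int(np.argmin(z))
        if z[idx] < best_z:
            best_z, best_theta = float(z[idx]), mesh[idx].copy()
        seeds.append(mesh[idx].copy())
        # shrink the box to +-1 grid cell around the best point seen
        spacing = (hi - lo) / (points_per_dim - 1)
        lo = best_theta - spacing
        hi = best_theta + spacing
    # the minimax objective has narrow curved valleys that defeat pure
    # axis-aligned refinement; polish the grid candidates on the raw
    # objective with a derivative-free simplex search
    for seed in seeds[:3] + [best_theta]:
        res = minimize(
            objective, seed, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 20000, "maxfev": 20000},
        )
        if res.fun < best_z:
            best_z, best_theta = float(res.fun), res.x.copy()
    return best_z, best_theta


def best_uniform_polynomial(x: np.ndarray, y: np.ndarray, powers: tuple[int, ...]) -> float:
    """Exact discrete minimax error of a polynomial, by reference subsets.

    Monomials on a positive axis form a Chebyshev (Haar) system, so the
    best uniform approximation with k coefficients on a finite point set
    is characterised by a reference of k+1 points carrying equal,
    alternating-sign deviations.  Solving the levelled linear system for
    every (k+1)-subset and taking the candidate with the smallest
    full-set maximum residual yields the exact optimum (the optimal
    reference is among the subsets, and every candidate's full-set error
    is an upper bound).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    k = len(powers)
    if len(np.unique(x)) <= k:  # interpolation possible
        return 0.0
    best = np.inf
    for subset in itertools.combinations(range(len(x)), k + 1):
        idx = np.array(subset)
        order = idx[np.argsort(x[idx])]
        if len(np.unique(x[order])) < k + 1:
            continue
        signs = (-1.0) ** np.arange(k + 1)
        mat = np.column_stack([x[order][:, None] ** np.array(powers), signs])
        try:
            sol = np.linalg.solve(mat, y[order])
        except np.linalg.LinAlgError:
            continue
        coeffs = sol[:-1]
        err = float(np.max(np.abs(y - (x[:, None] ** np.array(powers)) @ coeffs)))
        best = min(best, err)
    return best


def best_uniform_line(x: np.ndarray, y: np.ndarray) -> float:
    """Exact discrete minimax error of a straight line (3-point references)."""
    return best_uniform_polynomial(x, y, (0, 1))
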