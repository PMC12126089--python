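"""Brute-force vertex-enumeration oracle for small bounded LPs.

Independent of the package's solver path: enumerates every basic feasible
solution of {A_eq x = b_eq, l <= x <= u} by fixing n - rank(A) variables at
their bounds and solving for the rest, then optimises objectives over the
vertex list.  Intended for fixtures with at most ~14 variables.
"""

from __future__ import annotations

import itertools

import numpy as np

FEAS_TOL = 1e-7


def enumerate_vertices(A_eq, b_eq, bounds) -> list[np.ndarray]:
    A = np.atleast_2d(np.asarray(A_eq, dtype=float))
    b = np.asarray(b_eq, dtype=float)
    m, n = A.shape
    rank = np.linalg.matrix_rank(A)
    lo = np.array([bd[0] for bd in bounds], dtype=float)
    hi = np.array([bd[1] for bd in bounds], dtype=float)
    vertices: list[np.ndarray] = []
    for free in itertools.combinations(range(n), n - rank):
        basic = [j for j in range(n) if j not in free]
        B = A[:, basic]
        if np.linalg.matrix_rank(B) < rank:
            continue
        choices = [sorted({lo[j], hi[j]}) for j in free]
        for pattern in itertools.product(*choices):
            x = np.zeros(n)
            rhs = b.copy()
            for j, val in zip(free, pattern):
                x[j] = val
                rhs = rhs - A[:, j] * val
            sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            x[basic] = sol
            if np.linalg.norm(A @ x - b, ord=np.inf) > FEAS_TOL:
                continue
            if np.any(x < lo - FEAS_TOL) or np.any(x > hi + FEAS_TOL):
                continue
            vertices.append(x)
    return vertices


def maximize(c, A_eq, b_eq, bounds) -> float | None:
    """Optimal value of max c.x over the polytope, None if infeasible."""
    vertices = enumerate_vertices(A_eq, b_eq, bounds)
    if not vertices:
        return None
    c = np.asarray(c, dtype=float)
    return max(float(c @ v) for v in vertices)


def two_stage_optimum(model, tradeoff: float) -> tuple[float | None, float | None]:
    """Oracle replica of the staged objective: (growth optimum, butyrate).

    Stage 2 appends the growth floor as an equality with a bounded slack so
    the cut polytope's vertices are enumerable by the same routine.
    """
    A = model.A_eq.toarray()
    b = model.b_eq
    bounds = list(model.bounds)
    g_star = maximize(model.growth_coeffs, A, b, bounds)
    if g_star is None:
        return None, None
    g_star = max(g_star, 0.0)
    if model.butyrate_var is None:
        return g_star, 0.0
    n = A.shape[1]
    # growth - slack = tradeoff * g_star, 0 <= slack <= (1 - tradeoff) g_star
    A2 = np.zeros((A.shape[0] + 1, n + 1))
    A2[: A.shape[0], :n] = A
    A2[-1, :n] = model.growth_coeffs
    A2[-1, -1] = -1.0
    b2 = np.concatenate([b, [tradeoff * g_star]])
    bounds2 = bounds + [(0.0, (1.0 - tradeoff) * g_star + FEAS_TOL)]
    c2 = np.zeros(n + 1)
    c2[model.butyrate_var] = 1.0
    butyrate = maximize(c2, A2, b2, bounds2)
    if butyrate is None:
        return g_star, None
    return g_star, max(butyrate, 0.0)
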