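"""Independent brute-force solver of the ε-SVR dual, used as a test oracle.

Solves, with a generic constrained optimizer (SLSQP), the convex quadratic
program

    min_{u, v in [0, c]^n}  1/2 (u-v)^T K (u-v) - y^T (u-v) + eps * sum(u+v)
    s.t.  sum(u - v) = 0

where K is the RBF Gram matrix, and recovers the bias from the KKT
conditions: for a free support vector (0 < beta_i < c), y_i - f(x_i) =
sign(beta_i) * eps; otherwise b lies in the interval implied by the bound
constraints and its midpoint is taken. This path shares nothing with the
package's SMO-based fit.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist


def qp_svr_predict(X, y, c, gamma, epsilon, X_query):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    K = np.exp(-gamma * cdist(X, X, "sqeuclidean"))

    def obj(z):
        beta = z[:n] - z[n:]
        return 0.5 * beta @ K @ beta - y @ beta + epsilon * z.sum()

    def jac(z):
        Kb = K @ (z[:n] - z[n:])
        return np.concatenate([Kb - y + epsilon, -Kb + y + epsilon])

    cons = {
        "type": "eq",
        "fun": lambda z: z[:n].sum() - z[n:].sum(),
        "jac": lambda z: np.concatenate([np.ones(n), -np.ones(n)]),
    }
    # SLSQP can stall on a bad line search; restart from several points and
    # keep the best feasible iterate, then verify KKT stationarity directly.
    rng = np.random.default_rng(0)
    best = None
    for trial in range(6):
        if trial == 0:
            z0 = np.zeros(2 * n)
        else:
            z0 = rng.uniform(0, c, 2 * n)
            shift = (z0[:n].sum() - z0[n:].sum()) / (2 * n)
            z0 = np.clip(z0 - np.concatenate([np.full(n, shift),
                                              np.full(n, -shift)]), 0, c)
        res = minimize(
            obj, z0, jac=jac, bounds=[(0.0, c)] * (2 * n),
            constraints=[cons], method="SLSQP",
            options={"maxiter": 10_000, "ftol": 1e-14},
        )
        z = np.clip(res.x, 0.0, c)
        if abs(z[:n].sum() - z[n:].sum()) > 1e-8 * max(1.0, c):
            continue
        if best is None or obj(z) < obj(best):
            best = z
    assert best is not None, "QP oracle: no feasible iterate found"
    # KKT check: with equality multiplier nu, the reduced gradient
    # r = g - nu*sign must be zero on free coordinates, >= 0 at the lower
    # bound and <= 0 at the upper bound.
    g = jac(best)
    sign = np.concatenate([np.ones(n), -np.ones(n)])
    scale = max(1.0, float(np.max(np.abs(g))))
    at_lo = best <= 1e-8 * max(1.0, c)
    at_hi = best >= c - 1e-8 * max(1.0, c)
    free = ~(at_lo | at_hi)
    tol = 1e-5 * scale
    if np.any(free):
        nu = float(np.median(g[free] * sign[free]))
    else:
        # nu feasible iff g*sign >= nu at lower bounds and <= nu at upper
        uppers = g[at_lo] * sign[at_lo]
        lowers = g[at_hi] * sign[at_hi]
        lo_nu = lowers.max() if lowers.size else -np.inf
        hi_nu = uppers.min() if uppers.size else np.inf
        assert lo_nu <= hi_nu + tol, "QP oracle: KKT violated (no feasible nu)"
        nu = float(np.clip(0.0, lo_nu, hi_nu))
    r = g - nu * sign
    assert np.all(np.abs(r[free]) < tol), "QP oracle: KKT violated on free coords"
    assert np.all(r[at_lo] > -tol) and np.all(r[at_hi] < tol), \
        "QP oracle: KKT violated at bounds"
    beta = best[:n] - best[n:]

    # bias via KKT: free SVs give equalities, bounded ones an interval
    e = y - K @ beta
    tol = 1e-7 * c
    free = [
        e[i] - np.sign(beta[i]) * epsilon
        for i in range(n)
        if tol < abs(beta[i]) < c - tol
    ]
    if free:
        b = float(np.mean(free))
    else:
        lowers, uppers = [], []
        for i in range(n):
            if abs(beta[i]) <= tol:          # inside tube: |y - f| <= eps
                lowers.append(e[i] - epsilon)
                uppers.append(e[i] + epsilon)
            elif beta[i] >= c - tol:         # at upper bound: y - f >= eps
                uppers.append(e[i] - epsilon)
            else:                            # at lower bound: y - f <= -eps
                lowers.append(e[i] + epsilon)
        b = (max(lowers) + min(uppers)) / 2
    Kq = np.exp(-gamma * cdist(np.atleast_2d(X_query), X, "sqeuclidean"))
    return Kq @ beta + b
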