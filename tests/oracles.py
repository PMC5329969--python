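"""Independent reference implementations used only as test oracles.

These deliberately avoid the code paths of the package: the Passing-Bablok
oracle is a plain O(n^2) loop, the knee oracle is a dense numerical-
differentiation grid, and the power-fit oracle is a coarse parameter grid
polished with a derivative-free simplex search.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def passing_bablok_brute(x, y):
    """All-pairs Passing-Bablok slope/intercept by explicit enumeration."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j] - x[i]
            dy = y[j] - y[i]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                s = float("inf") if dy > 0 else float("-inf")
            else:
                s = dy / dx
            if s == -1.0:
                continue
            slopes.append(s)
    slopes.sort()
    big_n = len(slopes)
    k = sum(1 for s in slopes if s < -1.0)
    if big_n % 2:
        slope = slopes[k + (big_n - 1) // 2]
    else:
        slope = 0.5 * (
            slopes[min(k + big_n // 2 - 1, big_n - 1)]
            + slopes[min(k + big_n // 2, big_n - 1)]
        )
    intercept = float(np.median(np.asarray(y) - slope * np.asarray(x)))
    return slope, intercept


def knee_rank_grid(a: float, b: float, c: float, n: int, m: int = 100_000):
    """Knee rank by brute-force curvature on a dense normalized grid.

    The fitted curve y = a*x**b + c is evaluated on m points, both axes are
    rescaled to [0, 1] (x by n, y by its range over [1, n]) and the
    plane-curve curvature is computed by numerical differentiation; the
    argmax gives the knee rank.
    """
    u = np.linspace(1.0 / n, 1.0, m)
    y = a * (u * n) ** b + c
    ynorm = (y - y[-1]) / (y[0] - y[-1])
    yp = np.gradient(ynorm, u)
    ypp = np.gradient(yp, u)
    kappa = np.abs(ypp) / (1.0 + yp**2) ** 1.5
    # exclude the grid boundary where one-sided differences are biased
    interior = slice(2, m - 2)
    idx = 2 + int(np.argmax(kappa[interior]))
    return float(u[idx] * n)


def power_fit_grid(ranks, values):
    """Least-squares (a, b, c) by coarse grid search plus simplex polishing.

    Returns the parameters and the residual sum of squares.  Independent of
    the package's gradient-based fit.
    """
    x = np.asarray(ranks, dtype=float)
    y = np.asarray(values, dtype=float)

    def sse(params):
        a, b, c = params
        if a <= 0 or b >= 0 or c < 0:
            return np.inf
        r = y - (a * x**b + c)
        return float(np.dot(r, r))

    span = y[0] - y[-1]
    best, best_obj = None, np.inf
    for a in span * np.geomspace(0.25, 4.0, 13):
        for b in np.linspace(-2.5, -0.1, 25):
            for c in np.linspace(0.0, 2.0 * y[-1], 13):
                obj = sse((a, b, c))
                if obj < best_obj:
                    best, best_obj = (a, b, c), obj
    polish = minimize(
        sse, best, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000,
                 "maxfev": 20000},
    )
    a, b, c = polish.x
    return (float(a), float(b), float(c)), float(polish.fun)
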