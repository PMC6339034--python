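"""Independent reference implementations used only to check the package."""

import numpy as np
from scipy.optimize import minimize


def arc(a, b):
    return float(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0)))


def karcher_brute_force(points):
    """Grid search over S^2 followed by local refinement in spherical coords.

    Independent of the package's tangent-space iteration: directly minimizes
    the sum of squared arc lengths.
    """
    points = np.asarray(points, float)

    def objective_vec(m):
        return sum(arc(m, p) ** 2 for p in points)

    # Fibonacci sphere grid
    n = 20000
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    grid = np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)
    cos = np.clip(grid @ points.T, -1, 1)
    costs = (np.arccos(cos) ** 2).sum(axis=1)
    best = grid[np.argmin(costs)]

    def spherical(ang):
        t, p = ang
        return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])

    t0 = np.arccos(np.clip(best[2], -1, 1))
    p0 = np.arctan2(best[1], best[0])
    res = minimize(lambda ang: objective_vec(spherical(ang)), x0=[t0, p0],
                   method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
    return spherical(res.x)


def two_pass_covariance(rows):
    """Textbook unbiased covariance, computed the slow explicit way."""
    rows = np.asarray(rows, float)
    n, d = rows.shape
    mean = rows.sum(axis=0) / n
    out = np.zeros((d, d))
    for r in rows:
        diff = (r - mean)[:, None]
        out += diff @ diff.T
    return out / (n - 1)


def finite_difference_gradient(fun, x, h=1e-6):
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy()
        xm = x.copy()
        xp[idx] += h
        xm[idx] -= h
        g[idx] = (fun(xp) - fun(xm)) / (2 * h)
        it.iternext()
    return g
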