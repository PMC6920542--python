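"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the code paths they validate: the weighted-median
oracle inverts the weighted CDF by bisection, and the likelihood oracle
integrates the latent confounder out numerically.
"""

import numpy as np
from scipy import stats


def brute_force_weighted_median(values, weights):
    """Bisection inversion of the interpolated weighted CDF."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    p = (np.concatenate([[0.0], cw[:-1]]) + w / 2.0) / cw[-1]

    def cdf(t):
        if t <= v[0]:
            return p[0]
        if t >= v[-1]:
            return p[-1]
        k = np.searchsorted(v, t, side="right") - 1
        if v[k + 1] == v[k]:
            return p[k + 1]
        return p[k] + (p[k + 1] - p[k]) * (t - v[k]) / (v[k + 1] - v[k])

    if p[0] >= 0.5:
        return v[0]
    if p[-1] <= 0.5:
        return v[-1]
    lo, hi = v[0], v[-1]
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if cdf(mid) < 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def latent_u_loglik_quadrature(params, data, nodes: int = 80):
    """Gauss–Hermite integration of the confounder out of the structural densities."""
    t, w = np.polynomial.hermite.hermgauss(nodes)
    u = np.sqrt(2.0) * t
    total = 0.0
    for i in range(data.n):
        mx = params.omega_X + data.Z[i] @ params.alpha + params.delta_X * u
        my = (
            params.omega_Y
            + params.theta * data.X[i]
            + data.Z[i] @ params.beta
            + params.delta_Y * u
        )
        fx = stats.norm.pdf(data.X[i], mx, params.sigma_X)
        fy = stats.norm.pdf(data.Y[i], my, params.sigma_Y)
        total += np.log((w * fx * fy).sum() / np.sqrt(np.pi))
    return total
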