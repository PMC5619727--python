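"""Independent oracles used by the test suite.

These deliberately avoid the closed-form algebra of the package: the
marginal-likelihood oracle integrates the partition means analytically
through explicit stacked-covariance matrix algebra and the variance by
adaptive quadrature on log sigma2; the g oracle is a grid search with
local refinement; the marker-selection oracle enumerates all prefixes.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp


def _stacked_quadratics(y: np.ndarray, model, b0: float, g: float):
    """(log|C|, w'C^-1 w) for w = vec(y - b0), C = I + g Z(Z'Z)^-1 Z'."""
    n, J = y.shape
    Z = np.kron(np.ones((n, 1)), model.design)  # nJ x P stacked design
    H = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
    C = np.eye(n * J) + g * H
    _, logdetC = np.linalg.slogdet(C)
    w = (y - b0).reshape(-1)
    return logdetC, float(w @ np.linalg.solve(C, w))


def _log_integrand(t: float, N: int, logdetC: float, q0: float) -> float:
    s2 = np.exp(t)
    return -0.5 * (N * np.log(2 * np.pi * s2) + logdetC + q0 / s2)


def oracle_log_marginal(y, model, b0: float, g: float) -> float:
    """Quadrature oracle for log p(y | model, g)."""
    y = np.asarray(y, dtype=float)
    N = y.size
    logdetC, q0 = _stacked_quadratics(y, model, b0, g)
    grid = np.linspace(-45, 12, 500)
    shift = max(_log_integrand(t, N, logdetC, q0) for t in grid)
    val, _ = quad(
        lambda t: np.exp(_log_integrand(t, N, logdetC, q0) - shift),
        -55, 18, limit=300,
    )
    return shift + np.log(val)


def oracle_sigma2_posterior_mean(y, model, b0: float, g: float) -> float:
    """Quadrature oracle for E[sigma2 | y, model, g]."""
    y = np.asarray(y, dtype=float)
    N = y.size
    logdetC, q0 = _stacked_quadratics(y, model, b0, g)
    grid = np.linspace(-45, 12, 500)
    shift = max(_log_integrand(t, N, logdetC, q0) for t in grid)
    f = lambda t: np.exp(_log_integrand(t, N, logdetC, q0) - shift)
    den, _ = quad(f, -55, 18, limit=300)
    num, _ = quad(lambda t: np.exp(t) * f(t), -55, 18, limit=300)
    return num / den


def grid_g_oracle(beta, models, b0: float, n_grid: int = 400) -> float:
    """Grid-search maximiser of the model-averaged log marginal over g.

    400 log-spaced values on [1e-3, 1e3], then local bracket refinement
    around the argmax; a bracket sitting on the grid edge is expanded
    outward until it contains the maximiser.
    """
    from methylselect.bayes import _batch_stats, _log_marginal_from_stats

    beta = np.asarray(beta, dtype=float)
    K, n, J = beta.shape
    N = n * J
    TSS, F, _, pm = _batch_stats(beta, models, b0)
    log_prior = np.log(models.prior)

    def obj(g: float) -> float:
        lm = _log_marginal_from_stats(TSS, F, pm, N, g)
        return float(logsumexp(lm + log_prior, axis=1).sum())

    grid = np.logspace(-3, 3, n_grid)
    vals = np.array([obj(g) for g in grid])
    i = int(np.argmax(vals))
    lo = np.log(grid[max(i - 1, 0)])
    hi = np.log(grid[min(i + 1, n_grid - 1)])
    # expand past a boundary argmax until the objective turns over
    while i == n_grid - 1 and obj(np.exp(hi + 1.0)) > obj(np.exp(hi)):
        hi += 1.0
    while i == 0 and obj(np.exp(lo - 1.0)) > obj(np.exp(lo)):
        lo -= 1.0
    res = minimize_scalar(
        lambda t: -obj(np.exp(t)), bounds=(lo, hi + (1.0 if i == n_grid - 1 else 0.0)),
        method="bounded", options={"xatol": 1e-12},
    )
    return float(np.exp(res.x))


def brute_force_select(probs, fdr_level: float):
    """All-prefix enumeration of the Bayes FDR selection rule.

    Returns the indices (into the descending-probability order) of the
    largest admissible prefix, honouring all-in/all-out tie groups.
    """
    probs = np.asarray(probs, dtype=float)
    order = np.argsort(-probs, kind="stable")
    p = probs[order]
    best = 0
    for r in range(1, p.size + 1):
        if r < p.size and p[r] == p[r - 1]:
            continue  # cutting inside a tie group is not admissible
        if np.mean(1.0 - p[:r]) <= fdr_level:
            best = r
    return order[:best]
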