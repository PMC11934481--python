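"""Brute-force random-intercept model likelihood, independent of statsmodels.

Evaluates the marginal ML log-likelihood of y ~ N(X beta, sigma^2 I +
tau^2 Z Z') directly via the multivariate-normal density, profiling beta
out with GLS and maximising over (log sigma, log tau) numerically.  Used
only as an oracle against the package's mixed-model fits on tiny data.
"""

import numpy as np
from scipy import optimize


def _profile_nll(theta, y, X, G):
    log_sigma, log_tau = theta
    s2, t2 = np.exp(2 * log_sigma), np.exp(2 * log_tau)
    n = len(y)
    V = s2 * np.eye(n) + t2 * (G[:, None] == G[None, :])
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e12
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
    r = yi - Xi @ beta
    logdet = 2 * np.log(np.diag(L)).sum()
    return 0.5 * (n * np.log(2 * np.pi) + logdet + r @ r)


def ml_loglik(y, X, groups):
    """Maximised marginal ML log-likelihood, by direct numerical search."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    G = np.asarray(groups)
    sd0 = np.log(max(y.std(), 1e-3))
    best = np.inf
    for start in [(sd0, sd0 - 1), (sd0, sd0 - 4), (sd0 - 1, sd0), (sd0, -8.0)]:
        res = optimize.minimize(
            _profile_nll,
            start,
            args=(y, X, G),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        best = min(best, res.fun)
    return -best
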