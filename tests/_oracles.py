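"""Independent numerical oracles used by the model tests.

The adaptive Gauss-Hermite integrator evaluates the marginal likelihood
of the crossed Poisson random-intercept model by brute-force tensor
quadrature over the joint random-effect space (feasible only for a
handful of players and fixtures).  It shares no code with the Laplace
implementation it checks.
"""

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import gammaln


def agh_poisson_marginal_loglik(y, eta_fixed, pi, fi, qp, qf, sigma_p, sigma_f,
                                n_nodes=15):
    """Adaptive tensor Gauss-Hermite marginal log-likelihood.

    The grid is centred at the joint posterior mode and scaled by the
    Cholesky factor of the inverse curvature (both found numerically,
    independently of the package's Newton machinery).
    """
    y = np.asarray(y, float)
    dp, dfx = sigma_p ** 2, sigma_f ** 2
    q = qp + qf

    def logjoint(b):
        b = np.atleast_2d(b)
        u, v = b[:, :qp], b[:, qp:]
        eta = eta_fixed + u[:, pi] + v[:, fi]
        return ((y * eta - np.exp(eta) - gammaln(y + 1)).sum(axis=1)
                - 0.5 * (u ** 2).sum(axis=1) / dp
                - 0.5 * (v ** 2).sum(axis=1) / dfx
                - 0.5 * qp * np.log(2 * np.pi * dp)
                - 0.5 * qf * np.log(2 * np.pi * dfx))

    res = minimize(lambda b: -logjoint(b)[0], np.zeros(q), method="BFGS",
                   options={"gtol": 1e-12})
    mode = res.x
    h = 1e-5
    H = np.zeros((q, q))
    for i in range(q):
        for j in range(q):
            ei = np.zeros(q); ei[i] = h
            ej = np.zeros(q); ej[j] = h
            H[i, j] = (logjoint(mode + ei + ej)[0] - logjoint(mode + ei - ej)[0]
                       - logjoint(mode - ei + ej)[0]
                       + logjoint(mode - ei - ej)[0]) / (4 * h * h)
    C = np.linalg.cholesky(np.linalg.inv(-H))
    nodes, weights = hermegauss(n_nodes)
    grids = np.meshgrid(*([nodes] * q), indexing="ij")
    Z = np.stack([g.ravel() for g in grids], axis=1)
    W = np.ones(Z.shape[0])
    for k in range(q):
        W = W * np.tile(np.repeat(weights, n_nodes ** (q - 1 - k)), n_nodes ** k)
    B = mode[None, :] + Z @ C.T
    log_integrand = logjoint(B) + 0.5 * (Z ** 2).sum(axis=1)
    m = log_integrand.max()
    return float(np.log(np.exp(log_integrand - m) @ W) + m
                 + np.log(np.linalg.det(C)))


def tiny_crossed_poisson(rate=10.0, reps=5, sigma_p=0.5, sigma_f=0.3, seed=42,
                         qp=3, qf=2):
    """Small crossed Poisson dataset with known random intercepts."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sigma_p, qp)
    v = rng.normal(0, sigma_f, qf)
    pi, fi, y = [], [], []
    for p in range(qp):
        for f in range(qf):
            for _ in range(reps):
                y.append(rng.poisson(rate * np.exp(u[p] + v[f])))
                pi.append(p)
                fi.append(f)
    return (np.array(y, float), np.array(pi), np.array(fi))
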