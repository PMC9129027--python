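"""Independent numerical oracles used by the test suite.

The marginal-likelihood oracle integrates the conjugate priors numerically —
quasi-Monte-Carlo importance sampling over the regression coefficients and a
dense log-variance grid for the inverse-gamma residual variance — without
ever forming the closed-form Student-t scale matrix, so it is an independent
check of the analytic marginalization.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, multivariate_t, norm, qmc

from medbayes.core import EffectPriorSpec, MediationData, as_model

SIGMA_LEVELS = (0.1, 0.3, 1.0, 3.0, 10.0)


def numint_marginal_loglik(response, design, prior_variances, weights,
                           kappa: float, lamb: float, n_qmc_log2: int = 12,
                           n_t: int = 1401, t_lo: float = -40.0,
                           t_hi: float = 40.0, seed: int = 7,
                           proposal_df: float = 4.0,
                           proposal_inflate: float = 2.0) -> float:
    """Brute-force marginal log density of one regression equation.

    Integrates  N(r | X b, sigma^2 W^-1) * N(b | 0, sigma^2 V)
                * InvGamma(sigma^2 | kappa/2, lamb/2)
    over the coefficients b and the residual variance.  The variance slice is
    one-dimensional and handled exactly on a dense log grid; b is handled by
    scrambled-Sobol importance sampling from a mixture of fat-tailed
    Student-t proposals centered at a ridge estimate, with one mixture
    component per residual-scale level so both the small-sigma and the
    prior-dominated large-sigma regions are covered.
    """
    r = np.asarray(response, float).ravel()
    X = np.asarray(design, float)
    if X.ndim == 1:
        X = X[:, None]
    v = np.asarray(prior_variances, float).ravel()
    w = np.asarray(weights, float).ravel()
    n = r.size

    t = np.linspace(t_lo, t_hi, n_t)                     # t = log sigma^2
    sig2 = np.exp(t)
    a, b_rate = kappa / 2.0, lamb / 2.0
    log_ig_jac = (a * np.log(b_rate) - gammaln(a) - (a + 1) * t
                  - b_rate / sig2 + t)
    lik_const = -0.5 * n * np.log(2 * np.pi) + 0.5 * np.log(w).sum()

    keep = v > 0
    Xk, vk = X[:, keep], v[keep]
    p = Xk.shape[1]
    if p == 0:
        rss = float(r @ (w * r))
        integrand = lik_const - 0.5 * n * t - rss / (2 * sig2) + log_ig_jac
        dt = t[1] - t[0]
        return float(logsumexp(integrand) + np.log(dt))

    G = Xk.T @ (w[:, None] * Xk) + np.diag(1.0 / vk)
    shape = np.linalg.inv(G)
    bhat = shape @ (Xk.T @ (w * r))
    comps = [(bhat, proposal_inflate ** 2 * s ** 2 * shape)
             for s in SIGMA_LEVELS]
    K = 2 ** n_qmc_log2
    eng = qmc.Sobol(d=p + 2, scramble=True, seed=seed)
    pts = eng.random(K) * (1 - 1e-12) + 5e-13
    z = norm.ppf(pts[:, :p])
    gdraw = chi2.ppf(pts[:, p], proposal_df)
    pick = (pts[:, p + 1] * len(comps)).astype(int)
    bs = np.empty((K, p))
    for ci, (mu, cov) in enumerate(comps):
        idx = pick == ci
        L = np.linalg.cholesky(cov)
        bs[idx] = mu + (z[idx] @ L.T) * np.sqrt(proposal_df / gdraw[idx])[:, None]
    logq = logsumexp([multivariate_t.logpdf(bs, loc=mu, shape=cov,
                                            df=proposal_df)
                      for mu, cov in comps], axis=0) - np.log(len(comps))

    resid = r[None, :] - bs @ Xk.T
    rss_b = (resid ** 2) @ w                             # (K,)
    b_quad = (bs ** 2 / vk[None, :]).sum(axis=1)
    prior_const = -0.5 * p * np.log(2 * np.pi) - 0.5 * np.log(vk).sum()
    integrand = (lik_const - 0.5 * n * t[None, :]
                 - rss_b[:, None] / (2 * sig2[None, :])
                 + prior_const - 0.5 * p * t[None, :]
                 - b_quad[:, None] / (2 * sig2[None, :])
                 + log_ig_jac[None, :] - logq[:, None])
    dt = t[1] - t[0]
    return float(logsumexp(integrand) + np.log(dt) - np.log(K))


def numint_joint_loglik(theta, data: MediationData, priors: EffectPriorSpec,
                        seed: int = 7, **kwargs) -> float:
    """Brute-force joint log likelihood of (m, y) under one causal model.

    Builds the two regression equations (with the role swap for reactive
    configurations, and the canonical partial-mediation order for the
    Markov-equivalent (1, *, 1)) and integrates each numerically.
    """
    model = as_model(theta)
    phi_a, phi_b, phi_c = priors.phi_sq
    one = np.ones((data.n, 1))

    def equation(resp, X_blocks, v_blocks, w, kappa, lamb, eq_seed):
        design = np.hstack([one] + X_blocks)
        v = np.concatenate([np.atleast_1d(b) for b in v_blocks])
        return numint_marginal_loglik(resp, design, v, w, kappa, lamb,
                                      seed=eq_seed, **kwargs)

    if model.theta == (1, "*", 1):
        model = as_model((1, 1, 1))
    if not model.reactive:
        blocks_m, v_m = [], [np.array([priors.tau_mu_sq[0]])]
        if model.theta_a:
            blocks_m.append(data.X)
            v_m.append(np.full(data.X.shape[1], phi_a))
        ll_m = equation(data.m, blocks_m, v_m, data.w_m,
                        priors.kappa[0], priors.lamb[0], seed)
        blocks_y, v_y = [], [np.array([priors.tau_mu_sq[1]])]
        if model.theta_c:
            blocks_y.append(data.X)
            v_y.append(np.full(data.X.shape[1], phi_c))
        if model.theta_b == 1:
            blocks_y.append(data.m[:, None])
            v_y.append(np.array([phi_b]))
        ll_y = equation(data.y, blocks_y, v_y, data.w_y,
                        priors.kappa[1], priors.lamb[1], seed + 1)
        return ll_m + ll_y

    # reactive: marginal y-equation (edge c), conditional m given y (edge a)
    blocks_y, v_y = [], [np.array([priors.tau_mu_sq[1]])]
    if model.theta_c:
        blocks_y.append(data.X)
        v_y.append(np.full(data.X.shape[1], phi_c))
    ll_y = equation(data.y, blocks_y, v_y, data.w_y,
                    priors.kappa[1], priors.lamb[1], seed)
    blocks_m = []
    v_m = [np.array([priors.tau_mu_sq[0]])]
    if model.theta_a:
        blocks_m.append(data.X)
        v_m.append(np.full(data.X.shape[1], phi_a))
    blocks_m.append(data.y[:, None])
    v_m.append(np.array([phi_b]))
    ll_m = equation(data.m, blocks_m, v_m, data.w_m,
                    priors.kappa[0], priors.lamb[0], seed + 1)
    return ll_y + ll_m


def ols_beta_se(y, X):
    """Closed-form OLS coefficients and classical standard errors."""
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    return beta, se
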