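"""Independent oracles used by the tests.

These deliberately take different computational routes than the package:

* :func:`mcmc_posterior_laplace` samples the logistic posterior under the
  *analytically marginalized* iid Laplace(0,1) prior (valid when the
  coupling strength is zero), via emcee — no scale-mixture machinery.
* :func:`mcmc_posterior_hierarchy` samples the full (beta, u, v) hierarchy
  for an arbitrary precision matrix.
* :func:`binomial_tail_sum` sums the binomial pmf term by term.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def _log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray, b: float):
    a = X @ beta + b
    t = 2.0 * y - 1.0
    return -np.logaddexp(0.0, -t * a).sum()


def mcmc_posterior_laplace(
    X: np.ndarray,
    y: np.ndarray,
    bias_prior_variance: float = 100.0,
    n_steps: int = 6000,
    burn: int = 2000,
    seed: int = 0,
):
    """Posterior mean/variance of (beta, bias) under an iid Laplace(0,1) prior.

    Returns ``(mean, var)`` over the stacked vector ``(beta_1..beta_p, b)``.
    """
    import emcee

    p = X.shape[1]

    def logpost(theta):
        beta, b = theta[:p], theta[p]
        lp = -np.abs(beta).sum() - b * b / (2.0 * bias_prior_variance)
        return _log_likelihood(X, y, beta, b) + lp

    n_walkers = max(2 * (p + 1) + 2, 24)
    rng = np.random.default_rng(seed)
    start = 0.1 * rng.standard_normal((n_walkers, p + 1))
    sampler = emcee.EnsembleSampler(n_walkers, p + 1, logpost)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(start, n_steps, progress=False)
    chain = sampler.get_chain(discard=burn, flat=True)
    return chain.mean(axis=0), chain.var(axis=0)


def mcmc_posterior_hierarchy(
    X: np.ndarray,
    y: np.ndarray,
    J: np.ndarray,
    bias_prior_variance: float = 100.0,
    n_steps: int = 8000,
    burn: int = 3000,
    seed: int = 0,
):
    """Posterior mean/variance of (beta, bias) sampling the full hierarchy.

    The state is (beta, b, u, v) with u, v ~ N(0, J^{-1}) and
    beta_i | u_i, v_i ~ N(0, u_i^2 + v_i^2).
    """
    import emcee

    p = X.shape[1]
    dim = 3 * p + 1

    def logpost(theta):
        beta = theta[:p]
        b = theta[p]
        u = theta[p + 1 : 2 * p + 1]
        v = theta[2 * p + 1 :]
        s2 = u * u + v * v
        if (s2 < 1e-12).any():
            return -np.inf
        lp = -0.5 * (u @ J @ u + v @ J @ v)
        lp += -0.5 * np.sum(np.log(s2) + beta * beta / s2)
        lp += -b * b / (2.0 * bias_prior_variance)
        return _log_likelihood(X, y, beta, b) + lp

    n_walkers = max(2 * dim + 2, 48)
    rng = np.random.default_rng(seed)
    start = np.concatenate(
        [
            0.1 * rng.standard_normal((n_walkers, p + 1)),
            1.0 + 0.1 * rng.standard_normal((n_walkers, 2 * p)),
        ],
        axis=1,
    )
    sampler = emcee.EnsembleSampler(n_walkers, dim, logpost)
    sampler.run_mcmc(start, n_steps, progress=False)
    chain = sampler.get_chain(discard=burn, flat=True)
    return chain[:, : p + 1].mean(axis=0), chain[:, : p + 1].var(axis=0)


def binomial_tail_sum(n_correct: int, n_trials: int, p0: float) -> float:
    """P[Binomial(n_trials, p0) >= n_correct] by direct pmf summation."""
    ks = np.arange(n_correct, n_trials + 1)
    log_pmf = (
        gammaln(n_trials + 1)
        - gammaln(ks + 1)
        - gammaln(n_trials - ks + 1)
        + ks * np.log(p0)
        + (n_trials - ks) * np.log1p(-p0)
    )
    return float(np.exp(log_pmf).sum())
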