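"""Independent oracles used by the test suite: a 1-D grid integration of
the z-marginalised posterior for b_H, and batch-means Monte-Carlo standard
errors for MCMC output."""

import numpy as np
from scipy import stats


def grid_posterior_moments(c, mu_a, sigma1_sq, sigma2_sq, weights,
                           prior_mean=0.0, prior_var=100.0,
                           lo=-5.0, hi=5.0, n_grid=40001):
    """Mean and sd of the marginal posterior of b_H by grid integration of

        p(b | c) ∝ N(b | prior) * prod_j [w1 N(c_j|0,s1) + w2 N(c_j|b mu_a,s2)]

    (the latent indicators summed out analytically).
    """
    c = np.asarray(c, dtype=float)
    b = np.linspace(lo, hi, n_grid)
    w1, w2 = weights
    comp1 = w1 * stats.norm.pdf(c, 0.0, np.sqrt(sigma1_sq))
    logpost = stats.norm.logpdf(b, prior_mean, np.sqrt(prior_var))
    # loop over grid in blocks to bound memory
    block = 2000
    for start in range(0, n_grid, block):
        bb = b[start:start + block, None]
        comp2 = w2 * stats.norm.pdf(c[None, :], bb * mu_a, np.sqrt(sigma2_sq))
        mix = np.clip(comp1[None, :] + comp2, 1e-300, None)
        logpost[start:start + block] += np.log(mix).sum(axis=1)
    logpost -= logpost.max()
    dens = np.exp(logpost)
    dens /= np.trapezoid(dens, b)
    mean = np.trapezoid(b * dens, b)
    var = np.trapezoid((b - mean) ** 2 * dens, b)
    return mean, np.sqrt(var)


def batch_means_mcse(draws, n_batches=25):
    """Monte-Carlo standard error of the chain mean by batch means."""
    draws = np.asarray(draws, dtype=float)
    n = (draws.size // n_batches) * n_batches
    batches = draws[:n].reshape(n_batches, -1).mean(axis=1)
    return batches.std(ddof=1) / np.sqrt(n_batches)
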