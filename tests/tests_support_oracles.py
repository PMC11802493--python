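"""Independent oracles used by the end-to-end checks: a known-prior cell
simulator and a brute-force grid posterior for the gamma-mixture model."""

import math

import numpy as np
from scipy import stats


def simulate_prior_cells(n, seed, w=0.9, mean1=1.0, mean2=5.0, shape=5.0,
                         e_low=1.0, e_high=50.0):
    """(a, E) cells with relative risks drawn from a two-component gamma
    prior and counts from the conditional Poisson."""
    rng = np.random.default_rng(seed)
    E = rng.uniform(e_low, e_high, n)
    comp1 = rng.random(n) < w
    lam = np.where(
        comp1,
        rng.gamma(shape, mean1 / shape, n),
        rng.gamma(shape, mean2 / shape, n),
    )
    a = rng.poisson(lam * E)
    return list(zip(a.tolist(), E.tolist()))


def grid_posterior(fit, a, E, lam_max=80.0, n_grid=800001):
    """Numeric posterior EBGM and 5th percentile by direct integration of
    prior(lambda) x Poisson(a | lambda E) on a fine grid."""
    grid = np.linspace(1e-9, lam_max, n_grid)
    prior = (
        fit.w * stats.gamma(fit.alpha1, scale=1 / fit.beta1).pdf(grid)
        + (1 - fit.w) * stats.gamma(fit.alpha2, scale=1 / fit.beta2).pdf(grid)
    )
    like = stats.poisson(grid * E).pmf(a)
    post = prior * like
    post /= np.trapezoid(post, grid)
    ebgm = math.exp(np.trapezoid(post * np.log(grid), grid))
    cdf = np.cumsum(post) * (grid[1] - grid[0])
    eb05 = grid[np.searchsorted(cdf, 0.05)]
    return ebgm, float(eb05)
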