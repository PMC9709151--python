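"""Independent oracles used to cross-check the package's computations.

These implementations deliberately avoid the code paths they verify:
the collapsed single-cell posterior is computed by direct numeric
quadrature, chance levels by brute-force enumeration of response tuples,
and the binomial tail by an explicit sum of probability masses.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.special import expit
from scipy.stats import expon, norm


def quadrature_single_cell_posterior(
    n_trials: int,
    n_correct: int,
    prior_mean: float = -0.5,
    prior_sd: float = 1.0,
    sigma_alpha_rate: float = 1.0,
    sigma_gamma_rate: float = 2.0,
    interval_mass: float = 0.89,
):
    """Posterior of the success probability for one individual x behavior.

    With a single cell the hierarchical model collapses: the linear
    predictor eta = alpha + gamma is, conditional on the two scales,
    normal with mean ``prior_mean`` and sd ``sqrt(prior_sd^2 + sa^2 + sg^2)``.
    The scale priors are integrated out on a grid to get the marginal
    prior of eta; the binomial likelihood then gives a 1-D posterior.
    Returns (mean_p, pi_low, pi_high).
    """
    sa = np.linspace(1e-4, 14.0 / sigma_alpha_rate, 400)
    sg = np.linspace(1e-4, 14.0 / sigma_gamma_rate, 400)
    wa = expon(scale=1.0 / sigma_alpha_rate).pdf(sa)
    wg = expon(scale=1.0 / sigma_gamma_rate).pdf(sg)
    eta = np.linspace(-12.0, 12.0, 4001)
    sd = np.sqrt(prior_sd**2 + sa[:, None] ** 2 + sg[None, :] ** 2)
    weight = wa[:, None] * wg[None, :]
    prior = np.array(
        [np.sum(norm.pdf(e, prior_mean, sd) * weight) for e in eta]
    )
    prior /= np.trapezoid(prior, eta)
    loglik = n_correct * eta - n_trials * np.logaddexp(0.0, eta)
    post = prior * np.exp(loglik - loglik.max())
    post /= np.trapezoid(post, eta)
    p = expit(eta)
    mean_p = float(np.trapezoid(p * post, eta))
    cdf = np.concatenate(
        [[0.0], np.cumsum((post[1:] + post[:-1]) / 2.0 * np.diff(eta))]
    )
    cdf /= cdf[-1]
    tail = (1.0 - interval_mass) / 2.0
    lo = float(expit(np.interp(tail, cdf, eta)))
    hi = float(expit(np.interp(1.0 - tail, cdf, eta)))
    return mean_p, lo, hi


def enumerate_chance_level(n_behaviors: int, n_matches: int) -> float:
    """Chance success rate by brute force over all response tuples."""
    outcomes = list(itertools.product(range(n_behaviors), repeat=n_matches))
    target = 0  # uniform guessing: any fixed target behavior
    hits = sum(all(r == target for r in tup) for tup in outcomes)
    return hits / len(outcomes)


def binomial_tail_at_least(n: int, k: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), as an explicit mass sum."""
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))
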