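"""Random-walk Metropolis reference sampler.

A deliberately plain MCMC implementation targeting the posterior
(likelihood times uniform prior).  It exists as an independent
cross-check of the nested-sampling posterior — the two methods share
nothing but the likelihood — and mirrors the classical comparison of
nested sampling against MCMC on low-dimensional curve-fitting problems.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .core import PriorSpec

__all__ = ["metropolis_reference_sampler", "chain_summary"]


def metropolis_reference_sampler(
    loglike: Callable[[np.ndarray], float],
    prior: PriorSpec,
    n_steps: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    step_frac: float = 0.1,
    theta0: np.ndarray | None = None,
    adapt_burn: int | None = None,
) -> np.ndarray:
    """Random-walk Metropolis chain targeting posterior ∝ likelihood × prior.

    Gaussian proposals with per-dimension scale ``step_frac`` times the
    prior width; proposals outside the prior box are rejected (uniform
    prior mass is zero there).  During the first ``adapt_burn`` steps
    (default ``n_steps // 5``) the scale is adapted toward ~30%
    acceptance; those steps are *included* in the returned chain, so
    discard them before computing summaries.

    Returns the chain as an array of shape ``(n_steps, d)``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if adapt_burn is None:
        adapt_burn = n_steps // 5
    width = prior.upper - prior.lower
    theta = prior.sample(rng) if theta0 is None else np.asarray(theta0, dtype=float)
    if not prior.contains(theta):
        raise ValueError("theta0 outside the prior support")
    logl = float(loglike(theta))
    # start from a finite-likelihood point so acceptance ratios are defined
    tries = 0
    while not np.isfinite(logl):
        theta = prior.sample(rng)
        logl = float(loglike(theta))
        tries += 1
        if tries > 1000:
            raise RuntimeError("could not find a finite-likelihood starting point")
    scale = step_frac
    chain = np.empty((n_steps, prior.dim))
    accepted_window = 0
    for i in range(n_steps):
        prop = theta + scale * width * rng.standard_normal(prior.dim)
        if prior.contains(prop):
            logl_prop = float(loglike(prop))
            if np.log(rng.random()) < logl_prop - logl:
                theta = prop
                logl = logl_prop
                accepted_window += 1
        chain[i] = theta
        if i < adapt_burn and (i + 1) % 100 == 0:
            rate = accepted_window / 100.0
            scale *= np.exp(2.0 * (rate - 0.3))
            scale = float(np.clip(scale, 1e-4, 2.0))
            accepted_window = 0
    return chain


def chain_summary(chain: np.ndarray, burn: int = 0, n_batches: int = 20):
    """Means, SDs and batch-means standard errors of a chain.

    Batch means give a standard error that accounts for autocorrelation
    without estimating the correlation time explicitly.

    Returns ``(mean, sd, se_mean)`` arrays of length d.
    """
    kept = chain[burn:]
    mean = kept.mean(axis=0)
    sd = kept.std(axis=0, ddof=1)
    usable = (len(kept) // n_batches) * n_batches
    batches = kept[:usable].reshape(n_batches, -1, kept.shape[1]).mean(axis=1)
    se = batches.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return mean, sd, se
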