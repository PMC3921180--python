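"""The nested-sampling engine.

Maintains a set of N "live" points drawn from the prior, repeatedly
withdraws the one with the lowest likelihood and replaces it with a fresh
draw from the prior *constrained* to exceed that likelihood.  The
withdrawn (dead) points, ordered by likelihood, turn the evidence
integral Z = ∫ L(θ) π(θ) dθ into a one-dimensional quadrature over prior
mass X: the i-th dead point is assigned the deterministic shrinkage
X_i = exp(-i/N) and a trapezoidal width, and

    Z ≈ Σ_i L_i w_i          (accumulated in log space throughout).

Constrained replacement uses a random-walk Metropolis move in the unit
cube with a hard likelihood constraint (accept only moves with
logL > logL*), reflecting at the cube boundary, with the step size
adapted toward ~50% acceptance.  The run terminates once the evidence
still locked up in the live set — at most L_max · X_i — could raise the
accumulated log-evidence by less than ``tol``.

The information H = E_posterior[log(L/Z)] gives the standard error
estimate on log Z of sqrt(H/N).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import Dataset, PriorSpec, log_likelihood, prior_transform
from .models import ModelSpec

__all__ = [
    "NSRun",
    "run_nested_sampling",
    "make_loglike",
    "check_termination",
    "assign_log_widths",
    "initialize_live_points",
    "ConstrainedWalker",
]

logger = logging.getLogger(__name__)

_INIT_RETRY_FACTOR = 200  # retries per live point before giving up


def make_loglike(model: ModelSpec, data: Dataset) -> Callable[[np.ndarray], float]:
    """Bind a model to a dataset as a ``theta -> logL`` callable."""
    predictor = model.bind(data)

    def loglike(theta: np.ndarray) -> float:
        return log_likelihood(data, predictor(theta))

    return loglike


@dataclass
class NSRun:
    """Result of one nested-sampling run.

    ``dead_*`` arrays are ordered by iteration (hence non-decreasing in
    log-likelihood); ``live_*`` hold the final live set, each member
    carrying an equal share of the residual prior mass.  ``samples``
    concatenates dead then live points — the posterior modules consume
    that view.
    """

    param_names: tuple[str, ...]
    dead_theta: np.ndarray        # (n_dead, d)
    dead_logl: np.ndarray         # (n_dead,)
    dead_logx: np.ndarray         # (n_dead,)
    dead_logw: np.ndarray         # (n_dead,)
    live_theta: np.ndarray        # (N, d)
    live_logl: np.ndarray         # (N,)
    live_logw: np.ndarray         # (N,)
    logz: float
    logz_err: float
    h: float
    n_live: int
    n_like_evals: int
    n_iterations: int
    converged: bool
    seed: int | None
    settings: dict

    # -- combined views -----------------------------------------------
    @property
    def theta(self) -> np.ndarray:
        return np.vstack([self.dead_theta, self.live_theta])

    @property
    def logl(self) -> np.ndarray:
        return np.concatenate([self.dead_logl, self.live_logl])

    @property
    def logw(self) -> np.ndarray:
        return np.concatenate([self.dead_logw, self.live_logw])

    @property
    def n_samples(self) -> int:
        return len(self.dead_logl) + len(self.live_logl)

    def summary(self) -> dict:
        return {
            "logZ": self.logz,
            "logZ_err": self.logz_err,
            "H": self.h,
            "N": self.n_live,
            "n_iterations": self.n_iterations,
            "n_like_evals": self.n_like_evals,
            "converged": self.converged,
            "seed": self.seed,
            **{k: v for k, v in self.settings.items()},
        }

    def save(self, outdir: str | Path) -> None:
        """Write posterior samples (CSV) and a run summary (JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frame = pd.DataFrame(self.theta, columns=list(self.param_names))
        frame["logL"] = self.logl
        frame["logw"] = self.logw
        frame.to_csv(outdir / "samples.csv", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(self.summary(), indent=2, default=float)
        )


def assign_log_widths(n_dead: int, n_live: int) -> tuple[np.ndarray, float]:
    """Quadrature widths for dead points under deterministic shrinkage.

    X_i = exp(-i/N).  Interior dead points get the trapezoidal width
    (X_{i-1} - X_{i+1})/2; the first point also absorbs the boundary
    strip between X_0 = 1 and the first trapezoid so that dead widths
    plus the residual live mass telescope to exactly 1.  Returns
    ``(log widths, log residual mass)``; the residual is shared equally
    by the final live points.
    """
    if n_dead < 1:
        return np.empty(0), 0.0
    N = n_live
    i = np.arange(1, n_dead + 1, dtype=float)
    x_prev = np.exp(-(i - 1) / N)
    x_next = np.exp(-(i + 1) / N)
    w = 0.5 * (x_prev - x_next)
    # boundary correction: first point takes 1 - (X_1 + X_2)/2
    w[0] = 1.0 - 0.5 * (np.exp(-1.0 / N) + np.exp(-2.0 / N))
    residual = 0.5 * (np.exp(-n_dead / N) + np.exp(-(n_dead + 1) / N))
    return np.log(w), float(np.log(residual))


def check_termination(logz_accum: float, logl_max_live: float,
                      logx_current: float, tol: float) -> bool:
    """True when the live set can no longer move log Z by more than tol.

    The evidence still held by the live set is at most L_max * X_i.
    """
    if not np.isfinite(logz_accum):
        return False
    gain = np.logaddexp(logz_accum, logl_max_live + logx_current) - logz_accum
    return bool(gain < tol)


def initialize_live_points(
    n_live: int,
    prior: PriorSpec,
    loglike_u: Callable[[np.ndarray], float],
    rng: np.random.Generator,
    model_name: str = "model",
) -> tuple[np.ndarray, np.ndarray]:
    """Draw N live points from the prior, redrawing -inf likelihoods.

    Returns unit-cube coordinates and log-likelihoods.  Raises if a
    point cannot find a finite-likelihood draw within the retry cap
    (the prior is then essentially entirely infeasible for the model).
    """
    if n_live < 2:
        raise ValueError("n_live must be at least 2")
    d = prior.dim
    live_u = np.empty((n_live, d))
    live_logl = np.empty(n_live)
    for j in range(n_live):
        for _attempt in range(_INIT_RETRY_FACTOR):
            u = rng.random(d)
            ll = loglike_u(u)
            if np.isfinite(ll):
                live_u[j] = u
                live_logl[j] = ll
                break
        else:
            raise RuntimeError(
                f"initialization for {model_name!r} failed: could not find a "
                f"finite-likelihood prior draw in {_INIT_RETRY_FACTOR} attempts"
            )
    return live_u, live_logl


class ConstrainedWalker:
    """Random-walk Metropolis in the unit cube under a hard logL floor.

    The walk starts from a uniformly chosen survivor, takes ``n_walk``
    Gaussian steps reflected at the cube boundary, and accepts a step
    only if the proposed point beats the current likelihood floor — for
    a uniform prior on the cube this is exactly Metropolis sampling of
    the constrained prior.  One scalar step size is shared across the
    run and nudged toward ~50% acceptance (expand on mostly-accepts,
    shrink on mostly-rejects).
    """

    def __init__(self, dim: int, n_walk: int):
        self.dim = dim
        self.n_walk = n_walk
        self.scale = 0.1

    def __call__(self, live_u, live_logl, logl_star, loglike_u, rng):
        idx = rng.integers(len(live_u))
        u = live_u[idx].copy()
        logl = live_logl[idx]
        accepted = 0
        rejected = 0
        for _ in range(self.n_walk):
            prop = u + self.scale * rng.standard_normal(self.dim)
            # reflect into [0, 1]
            prop = np.abs(prop) % 2.0
            prop = np.where(prop > 1.0, 2.0 - prop, prop)
            logl_prop = loglike_u(prop)
            # hard constraint logL > logL*; on an exact plateau (constant
            # likelihood) allow diffusion at equal level instead of freezing
            if logl_prop > logl_star or (logl_prop == logl_star == logl):
                u = prop
                logl = logl_prop
                accepted += 1
            else:
                rejected += 1
        if accepted > rejected:
            self.scale *= np.exp(1.0 / max(accepted, 1))
        else:
            self.scale /= np.exp(1.0 / max(rejected, 1))
        self.scale = min(self.scale, 1.0)
        if accepted == 0:
            warnings.warn(
                "constrained walk accepted no moves; returning a live-point copy",
                RuntimeWarning,
                stacklevel=2,
            )
        return u, logl, accepted


def run_nested_sampling(
    loglike: Callable[[np.ndarray], float] | None = None,
    prior: PriorSpec | None = None,
    *,
    model: ModelSpec | None = None,
    data: Dataset | None = None,
    n_live: int = 1000,
    tol: float = 0.5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_walk: int | None = None,
    max_iter: int = 200_000,
    shrinkage: str = "deterministic",
) -> NSRun:
    """Run nested sampling and return an :class:`NSRun`.

    Parameters
    ----------
    loglike
        ``theta -> log-likelihood``.  May be omitted if ``model`` and
        ``data`` are given, in which case the Gaussian-error likelihood
        is built automatically.
    prior
        Independent uniform prior bounds (required).
    n_live
        Number of live points N.  Larger N refines the shrinkage
        quadrature: the log-evidence error scales as sqrt(H/N).
    tol
        Termination tolerance on the remaining log-evidence gain.
    n_walk
        Metropolis steps per constrained replacement; default ``20 * d``.
    shrinkage
        ``"deterministic"`` (X_i = exp(-i/N)) or ``"stochastic"``
        (X_i = X_{i-1} t_i with t_i ~ Beta(N, 1)), the latter for
        quadrature-uncertainty experiments.
    """
    if prior is None:
        raise ValueError("a PriorSpec is required")
    if loglike is None:
        if model is None or data is None:
            raise ValueError("provide either loglike or (model, data)")
        loglike = make_loglike(model, data)
    if n_live < 2:
        raise ValueError("n_live must be at least 2")
    if shrinkage not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown shrinkage scheme {shrinkage!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    d = prior.dim
    if n_walk is None:
        n_walk = 20 * d

    n_evals = 0

    def loglike_u(u: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        return float(loglike(prior_transform(u, prior)))

    # -- step 1: initial live set from the prior ----------------------
    model_name = getattr(model, "name", "model")
    live_u, live_logl = initialize_live_points(n_live, prior, loglike_u, rng, model_name)

    walker = ConstrainedWalker(d, n_walk)
    dead_u: list[np.ndarray] = []
    dead_logl: list[float] = []
    log_shrink = 0.0  # running log X under stochastic shrinkage
    dead_logx: list[float] = []

    logz_dead = -np.inf  # evidence accumulated in dead points (running)
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        worst = int(np.argmin(live_logl))
        logl_star = float(live_logl[worst])
        if shrinkage == "deterministic":
            logx = -it / n_live
        else:
            log_shrink += np.log(rng.beta(n_live, 1.0))
            logx = log_shrink
        dead_u.append(live_u[worst].copy())
        dead_logl.append(logl_star)
        dead_logx.append(logx)
        # running trapezoidal width for the termination bookkeeping
        logw_run = logx + np.log(0.5 * (np.exp(1.0 / n_live) - np.exp(-1.0 / n_live)))
        logz_dead = np.logaddexp(logz_dead, logl_star + logw_run)
        # step 4: replace under the hard constraint
        u_new, logl_new, accepted = walker(live_u, live_logl, logl_star, loglike_u, rng)
        live_u[worst] = u_new
        live_logl[worst] = logl_new
        if check_termination(logz_dead, float(np.max(live_logl)), logx, tol):
            converged = True
            break
    else:
        logger.warning("nested sampling hit max_iter=%d before termination", max_iter)
    if it >= max_iter and not converged:
        logger.warning("returning non-converged run for %r", model_name)

    # -- final quadrature over all samples ----------------------------
    n_dead = len(dead_logl)
    dead_logl_arr = np.array(dead_logl)
    dead_logx_arr = np.array(dead_logx)
    if shrinkage == "deterministic":
        dead_logw, log_residual = assign_log_widths(n_dead, n_live)
    else:
        x = np.exp(dead_logx_arr)
        x_prev = np.concatenate([[1.0], x[:-1]])
        x_next = np.concatenate([x[1:], [x[-1] * np.exp(-1.0 / n_live)]])
        w = 0.5 * (x_prev - x_next)
        w[0] = 1.0 - 0.5 * (x[0] + (x[1] if n_dead > 1 else x[0] * np.exp(-1.0 / n_live)))
        dead_logw = np.log(np.maximum(w, 1e-300))
        log_residual = float(np.log(0.5 * (x_prev[-1] + x_next[-1])))
    live_order = np.argsort(live_logl, kind="stable")
    live_logw = np.full(n_live, log_residual - np.log(n_live))

    all_logl = np.concatenate([dead_logl_arr, live_logl[live_order]])
    all_logw = np.concatenate([dead_logw, live_logw])
    logz = float(logsumexp(all_logl + all_logw))
    p = np.exp(all_logl + all_logw - logz)
    with np.errstate(invalid="ignore"):
        h_terms = np.where(p > 0, p * (all_logl - logz), 0.0)
    h = float(np.sum(h_terms))
    logz_err = float(np.sqrt(max(h, 0.0) / n_live))

    dead_theta = (
        prior_transform(np.array(dead_u), prior) if n_dead else np.empty((0, d))
    )
    live_theta = prior_transform(live_u[live_order], prior)

    return NSRun(
        param_names=prior.names,
        dead_theta=dead_theta,
        dead_logl=dead_logl_arr,
        dead_logx=dead_logx_arr,
        dead_logw=dead_logw,
        live_theta=live_theta,
        live_logl=live_logl[live_order],
        live_logw=live_logw,
        logz=logz,
        logz_err=logz_err,
        h=h,
        n_live=n_live,
        n_like_evals=n_evals,
        n_iterations=it,
        converged=converged,
        seed=seed,
        settings={
            "tol": tol,
            "n_walk": n_walk,
            "shrinkage": shrinkage,
            "model": model_name,
        },
    )
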