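"""Posterior summaries from a nested-sampling run.

Each nested-sampling sample contributes to the evidence an amount
L_i w_i; normalising by Z turns those contributions into posterior
weights p_i = L_i w_i / Z.  Summary statistics are always computed on
the weights; "staircase" (systematic) resampling converts the weighted
set into equally-weighted draws for plotting and downstream use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ns import NSRun

__all__ = ["WeightedPosterior", "posterior_weights", "weighted_mean_sd", "staircase_resample"]


@dataclass(frozen=True)
class WeightedPosterior:
    """Weighted posterior samples tied to the run's log-evidence."""

    param_names: tuple[str, ...]
    samples: np.ndarray   # (n, d)
    weights: np.ndarray   # (n,), non-negative, sums to 1
    logz: float
    converged: bool = True

    def __post_init__(self):
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1")

    @property
    def ess(self) -> float:
        """Kish effective sample size 1 / sum(p^2)."""
        return float(1.0 / np.sum(self.weights**2))

    def column(self, name: str) -> np.ndarray:
        return self.samples[:, self.param_names.index(name)]

    def mean_sd(self, name: str) -> tuple[float, float]:
        return weighted_mean_sd(self, name)

    def summary_frame(self) -> pd.DataFrame:
        rows = [(n, *weighted_mean_sd(self, n)) for n in self.param_names]
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd"])


def posterior_weights(run: NSRun) -> WeightedPosterior:
    """Normalised posterior weights p_i = exp(logL_i + logw_i - logZ)."""
    if not np.isfinite(run.logz):
        raise ValueError("run has non-finite logZ; cannot form posterior weights")
    if not run.converged:
        warnings.warn(
            "posterior weights from a non-converged run", RuntimeWarning, stacklevel=2
        )
    logp = run.logl + run.logw - run.logz
    w = np.exp(logp)
    w = w / w.sum()  # remove residual quadrature round-off
    return WeightedPosterior(
        param_names=tuple(run.param_names),
        samples=run.theta,
        weights=w,
        logz=run.logz,
        converged=run.converged,
    )


def weighted_mean_sd(posterior: WeightedPosterior, name: str) -> tuple[float, float]:
    """Evidence-weighted mean and standard deviation of one parameter.

    mu = sum p_i theta_i;  sd = sqrt(sum p_i theta_i^2 - mu^2).
    """
    x = posterior.column(name)
    p = posterior.weights
    if np.count_nonzero(p) < 2:
        warnings.warn(
            f"all posterior weight on one sample for {name!r}; sd is 0",
            RuntimeWarning,
            stacklevel=2,
        )
    mu = float(np.dot(p, x))
    var = float(np.dot(p, x**2) - mu**2)
    return mu, float(np.sqrt(max(var, 0.0)))


def staircase_resample(
    posterior: WeightedPosterior, n_out: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Equally-weighted posterior draws by systematic (staircase) resampling.

    A single uniform offset u is drawn; output k selects the sample whose
    cumulative weight first exceeds (k + u) / n_out.  Compared with
    multinomial resampling this keeps the stratification of the weight
    staircase and has lower variance.  With equal input weights and
    ``n_out`` equal to the sample count, every sample is selected exactly
    once.
    """
    if n_out < 1:
        raise ValueError("n_out must be at least 1")
    if rng is None:
        rng = np.random.default_rng()
    cum = np.cumsum(posterior.weights)
    cum[-1] = 1.0
    u = rng.random()
    targets = (np.arange(n_out) + u) / n_out
    idx = np.searchsorted(cum, targets, side="left")
    return posterior.samples[idx]


def resampled_frame(posterior: WeightedPosterior, n_out: int,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Staircase draws as a DataFrame, one parameter per column."""
    draws = staircase_resample(posterior, n_out, rng)
    return pd.DataFrame(draws, columns=list(posterior.param_names))


def save_equal_weight_samples(posterior: WeightedPosterior, path: str | Path,
                              n_out: int = 3000,
                              rng: np.random.Generator | None = None) -> None:
    resampled_frame(posterior, n_out, rng).to_csv(path, index=False)
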