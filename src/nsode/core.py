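"""Priors, datasets and the Gaussian-error log-likelihood.

The inference machinery works on three small containers:

* :class:`PriorSpec` — independent uniform priors, one ``(lower, upper)``
  interval per named parameter.  The sampler explores the unit hypercube
  and :func:`prior_transform` maps cube points to parameter vectors.
* :class:`Dataset` — observed ``(time, variable, value, sigma)`` records,
  i.e. sparse noisy time courses, possibly covering several state
  variables of a model.
* :func:`log_likelihood` — independent Gaussian errors per point,
  including the normalisation constant, so that absolute log-evidences
  are well defined and comparable across noise levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PriorSpec",
    "Dataset",
    "prior_transform",
    "inverse_prior_transform",
    "log_likelihood",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors over a named parameter vector.

    Parameters
    ----------
    entries
        Sequence of ``(name, lower, upper)`` tuples, one per parameter,
        in the order used by every parameter vector of the problem.
    """

    entries: tuple[tuple[str, float, float], ...]

    def __init__(self, entries: Iterable[tuple[str, float, float]]):
        entries = tuple((str(n), float(lo), float(hi)) for n, lo, hi in entries)
        if len(entries) < 1:
            raise ValueError("prior must have at least one parameter")
        names = [e[0] for e in entries]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate parameter names in prior: {names}")
        for name, lo, hi in entries:
            if not lo < hi:
                raise ValueError(f"prior for {name!r} needs lower < upper, got [{lo}, {hi}]")
        object.__setattr__(self, "entries", entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    @property
    def lower(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries])

    @property
    def upper(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries])

    @property
    def dim(self) -> int:
        return len(self.entries)

    @property
    def log_volume(self) -> float:
        """Log of the prior hyper-volume (the Occam factor's numerator)."""
        return float(np.sum(np.log(self.upper - self.lower)))

    def contains(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Draw ``size`` parameter vectors (or one, if ``size`` is None)."""
        if size is None:
            return prior_transform(rng.random(self.dim), self)
        u = rng.random((size, self.dim))
        return self.lower + u * (self.upper - self.lower)

    @classmethod
    def from_dict(cls, bounds: dict[str, Sequence[float]]) -> "PriorSpec":
        """Build from a ``{name: [lower, upper]}`` mapping (config files)."""
        return cls([(k, v[0], v[1]) for k, v in bounds.items()])


def prior_transform(u: np.ndarray, prior: PriorSpec) -> np.ndarray:
    """Map a unit-cube point to parameter space under independent uniforms.

    ``theta_i = lower_i + u_i * (upper_i - lower_i)``; bijective on the cube.
    """
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != prior.dim:
        raise ValueError(f"unit-cube point has dimension {u.shape[-1]}, prior has {prior.dim}")
    if np.any(u < 0.0) or np.any(u > 1.0):
        raise ValueError("unit-cube coordinates must lie in [0, 1]")
    return prior.lower + u * (prior.upper - prior.lower)


def inverse_prior_transform(theta: np.ndarray, prior: PriorSpec) -> np.ndarray:
    """Inverse of :func:`prior_transform` (parameter space back to the cube)."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape[-1] != prior.dim:
        raise ValueError(f"parameter vector has dimension {theta.shape[-1]}, prior has {prior.dim}")
    return (theta - prior.lower) / (prior.upper - prior.lower)


class Dataset:
    """Observed time-course points with per-point Gaussian noise SDs.

    Thin wrapper around a tidy DataFrame with columns
    ``time, variable, value, sigma``.  Rows are kept in input order;
    within each variable the times must be non-decreasing.  ``metadata``
    records generation provenance (seed, noise recipe) for synthetic data.
    """

    COLUMNS = ("time", "variable", "value", "sigma")

    def __init__(self, frame: pd.DataFrame, metadata: dict | None = None):
        frame = frame.copy().reset_index(drop=True)
        missing = [c for c in ("time", "variable", "value") if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset missing required columns: {missing}")
        if "sigma" not in frame.columns:
            frame["sigma"] = np.nan
        frame = frame[list(self.COLUMNS)]
        if len(frame) < 1:
            raise ValueError("dataset must contain at least one point")
        sig = frame["sigma"].to_numpy(dtype=float)
        if np.any(np.isfinite(sig) & (sig <= 0)):
            raise ValueError("all sigma values must be positive")
        for var, grp in frame.groupby("variable", sort=False):
            t = grp["time"].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                raise ValueError(f"times for variable {var!r} must be non-decreasing")
        self.frame = frame
        self.metadata = dict(metadata or {})

    # -- array views ---------------------------------------------------
    @property
    def times(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy(dtype=float)

    @property
    def sigmas(self) -> np.ndarray:
        return self.frame["sigma"].to_numpy(dtype=float)

    @property
    def variables(self) -> tuple[str, ...]:
        """Variable names in order of first appearance."""
        seen: dict[str, None] = {}
        for v in self.frame["variable"]:
            seen.setdefault(str(v))
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.frame)

    def with_sigma(self, sigma: float | np.ndarray) -> "Dataset":
        """Return a copy with the sigma column replaced (scalar broadcast)."""
        frame = self.frame.copy()
        frame["sigma"] = sigma
        return Dataset(frame, self.metadata)

    def has_sigma(self) -> bool:
        return bool(np.all(np.isfinite(self.sigmas)))

    # -- I/O -----------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the points as CSV; provenance goes to a JSON side-file."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        if self.metadata:
            side = path.with_suffix(path.suffix + ".meta.json")
            side.write_text(json.dumps(self.metadata, indent=2, default=float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        frame = pd.read_csv(path)
        side = path.with_suffix(path.suffix + ".meta.json")
        metadata = json.loads(side.read_text()) if side.exists() else {}
        return cls(frame, metadata)


def log_likelihood(data: Dataset, predicted: np.ndarray) -> float:
    """Gaussian-error log-likelihood of model values against a dataset.

    ``sum_k [ -0.5*((D_k - M_k)/sigma_k)^2 - log(sigma_k*sqrt(2*pi)) ]``.

    Any non-finite prediction (a failed ODE solve, overflow, ...) yields
    ``-inf``: the point is simply excluded by the sampler rather than
    raising, so likelihood evaluation never aborts a run.
    """
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != (len(data),):
        raise ValueError(
            f"predicted has shape {predicted.shape}, expected ({len(data)},)"
        )
    if not np.all(np.isfinite(predicted)):
        return -np.inf
    sigma = data.sigmas
    if not np.all(np.isfinite(sigma)):
        raise ValueError("dataset has no sigma column; set one with Dataset.with_sigma")
    resid = (data.values - predicted) / sigma
    return float(-0.5 * np.dot(resid, resid) - np.sum(np.log(sigma)) - len(data) * _LOG_SQRT_2PI)
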