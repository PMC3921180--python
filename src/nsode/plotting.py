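"""Quick-look figures for posterior samples.

Marginal histograms and pairwise densities from equally-weighted
(staircase-resampled) draws, for eyeballing which parameters the data
constrain and how they correlate.  Matplotlib's non-interactive Agg
backend is forced so the helpers work headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .posterior import WeightedPosterior, staircase_resample

__all__ = ["plot_marginals", "plot_pairwise"]


def plot_marginals(posterior: WeightedPosterior, path: str | Path | None = None,
                   n_draws: int = 3000, bins: int = 40,
                   rng: np.random.Generator | None = None):
    """One histogram per parameter from equal-weight posterior draws."""
    draws = staircase_resample(posterior, n_draws, rng)
    names = posterior.param_names
    ncol = min(4, len(names))
    nrow = int(np.ceil(len(names) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow),
                             squeeze=False)
    for ax in axes.ravel()[len(names):]:
        ax.set_visible(False)
    for j, name in enumerate(names):
        ax = axes.ravel()[j]
        ax.hist(draws[:, j], bins=bins, density=True, color="#4477aa")
        mu, sd = posterior.mean_sd(name)
        ax.axvline(mu, color="k", lw=1)
        ax.set_title(f"{name}: {mu:.3g} ± {sd:.2g}", fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_pairwise(posterior: WeightedPosterior, names: tuple[str, str],
                  path: str | Path | None = None, n_draws: int = 3000,
                  rng: np.random.Generator | None = None):
    """2D histogram of one parameter pair (joint posterior density)."""
    draws = staircase_resample(posterior, n_draws, rng)
    i, j = (posterior.param_names.index(n) for n in names)
    fig, ax = plt.subplots(figsize=(4, 3.4))
    ax.hist2d(draws[:, i], draws[:, j], bins=40, cmap="viridis")
    ax.set_xlabel(names[0])
    ax.set_ylabel(names[1])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
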