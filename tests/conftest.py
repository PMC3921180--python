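"""Shared fixtures: small analytic problems and cached sampler runs.

Expensive nested-sampling runs are session-scoped so several tests can
interrogate the same run (weights, summaries, invariants) without
re-sampling.
"""

from __future__ import annotations

import numpy as np
import pytest

from nsode import PriorSpec, run_nested_sampling
from nsode.synthetic import generate_curve_data

GAUSS_MU, GAUSS_SD = 0.5, 0.05


def gauss1d_loglike(theta):
    """N(0.5, 0.05) likelihood on [0, 1]; evidence is ~1 (log Z ~ 0)."""
    z = (theta[0] - GAUSS_MU) / GAUSS_SD
    return -0.5 * z * z - np.log(GAUSS_SD * np.sqrt(2 * np.pi))


@pytest.fixture(scope="session")
def unit_prior_1d():
    return PriorSpec([("x", 0.0, 1.0)])


@pytest.fixture(scope="session")
def gauss1d_run(unit_prior_1d):
    """One converged run on the 1D Gaussian toy problem."""
    return run_nested_sampling(
        gauss1d_loglike, unit_prior_1d, n_live=400, seed=101
    )


@pytest.fixture(scope="session")
def tanh_data():
    return generate_curve_data(seed=7)


@pytest.fixture(scope="session")
def tanh_run(tanh_data):
    from nsode.models import default_prior, get_model

    model = get_model("tanh")
    prior = default_prior(model)
    return run_nested_sampling(
        prior=prior, model=model, data=tanh_data, n_live=300, seed=11
    )
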