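"""Seeded synthetic time-course generation.

Every dataset used by the bundled experiments is generated here, from
the ground-truth repressilator configuration or from an algebraic test
curve, so the whole pipeline runs without external data.  Each generator
is a pure function of its recipe (seed included) and records full
provenance in ``Dataset.metadata``.

Noise convention: Gaussian, with SD either absolute (``noise_sd``) or a
fraction of the range of the noise-free observed trace
(``noise_frac``, the default 0.10 — "10% of the range").  Amplitude
normalisation (used by the model-comparison experiments so mechanistically
different models see comparable scales) divides each variable's noisy
values by that variable's maximum absolute value, and co-scales the
per-point sigmas so the likelihood is consistent.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core import Dataset
from .models import (
    REPRESSILATOR_TRUE_ICS,
    REPRESSILATOR_TRUE_PARAMS,
    get_model,
)

__all__ = [
    "GenerationRecipe",
    "generate",
    "generate_repressilator_course",
    "generate_comparison_course",
    "generate_two_variable_course",
    "generate_curve_data",
    "generate_resolution_series",
    "TRUE_TANH_PARAMS",
]

# tanh test curve y = theta1 * tanh(theta2 * x): amplitude ~5 reached
# slowly over x in [0, 10], against unit-SD observation noise
TRUE_TANH_PARAMS = {"theta1": 5.0, "theta2": 0.25}


@dataclass(frozen=True)
class GenerationRecipe:
    """Full description of one synthetic dataset.

    ``noise_frac`` is interpreted as a fraction of the range of the
    noise-free trace (per variable); ``noise_sd`` as an absolute SD.
    Exactly one of the two should be set; both None means noise-free.
    """

    model: str
    true_params: dict[str, float]
    times: tuple[float, ...]
    variables: tuple[str, ...]
    noise_frac: float | None = None
    noise_sd: float | None = None
    normalize: bool = False
    seed: int | None = None
    true_ics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.noise_frac is not None and self.noise_sd is not None:
            raise ValueError("set noise_frac or noise_sd, not both")
        for v in (self.noise_frac, self.noise_sd):
            if v is not None and v <= 0:
                raise ValueError("noise SD must be positive when noise is enabled")


def _clean_trace(recipe: GenerationRecipe) -> dict[str, np.ndarray]:
    """Noise-free model values per observed variable at the recipe times."""
    times = np.asarray(recipe.times, dtype=float)
    if recipe.model in ("tanh", "linear", "quadratic", "sigmoid"):
        model = get_model(recipe.model)
        theta = np.array([recipe.true_params[p] for p in model.param_names])
        frame = pd.DataFrame(
            {"time": times, "variable": "y", "value": 0.0, "sigma": 1.0}
        )
        vals = model.predict(theta, Dataset(frame))
        return {"y": vals}
    model = get_model(recipe.model, fixed_ics=dict(recipe.true_ics))
    theta = np.array([recipe.true_params[p] for p in model.param_names])
    sol = model.simulate(theta, times)
    if not sol.success:
        raise RuntimeError(f"true-parameter solve failed for {recipe.model}")
    return {v: sol.state(v).copy() for v in recipe.variables}


def generate(recipe: GenerationRecipe) -> Dataset:
    """Materialise a recipe: simulate, add seeded noise, normalise.

    The noise stream draws each variable's deviates in the order the
    variables are listed, so a multi-variable recipe reproduces the
    single-variable dataset for its first variable at the same seed.
    """
    rng = np.random.default_rng(recipe.seed)
    clean = _clean_trace(recipe)
    times = np.asarray(recipe.times, dtype=float)
    frames = []
    for var in recipe.variables:
        y = clean[var]
        rng_draw = rng.standard_normal(len(y))
        if recipe.noise_frac is not None:
            sd = recipe.noise_frac * (y.max() - y.min())
        elif recipe.noise_sd is not None:
            sd = recipe.noise_sd
        else:
            sd = 0.0
        noisy = y + sd * rng_draw
        sigma = sd if sd > 0 else np.nan
        if recipe.normalize:
            scale = np.max(np.abs(noisy))
            noisy = noisy / scale
            sigma = sigma / scale if sd > 0 else np.nan
        frames.append(
            pd.DataFrame(
                {"time": times, "variable": var, "value": noisy, "sigma": sigma}
            )
        )
    meta = {"recipe": asdict(recipe)}
    return Dataset(pd.concat(frames, ignore_index=True), meta)


def _repressilator_recipe(times, variables, seed, noise_frac, normalize) -> GenerationRecipe:
    return GenerationRecipe(
        model="repressilator",
        true_params=dict(REPRESSILATOR_TRUE_PARAMS),
        true_ics=dict(REPRESSILATOR_TRUE_ICS),
        times=tuple(times),
        variables=tuple(variables),
        noise_frac=noise_frac,
        normalize=normalize,
        seed=seed,
    )


def generate_repressilator_course(seed: int | None = 0,
                                  noise_frac: float = 0.10) -> Dataset:
    """cI-protein observations for the parameter-inference experiment.

    26 points at two-minute intervals over 50 minutes, Gaussian noise
    with SD equal to 10% of the range of the noise-free trace.
    """
    times = np.arange(0.0, 50.0 + 1e-9, 2.0)
    return generate(_repressilator_recipe(times, ("p_cI",), seed, noise_frac, False))


def generate_comparison_course(seed: int | None = 0, n_points: int = 25,
                               t_max: float = 50.0,
                               noise_frac: float = 0.10) -> Dataset:
    """One-variable dataset for model comparison: 25 noisy cI points,
    amplitude-normalised so the maximum absolute value is exactly one."""
    times = np.linspace(0.0, t_max, n_points)
    return generate(_repressilator_recipe(times, ("p_cI",), seed, noise_frac, True))


def generate_two_variable_course(seed: int | None = 0, n_points: int = 25,
                                 t_max: float = 50.0,
                                 noise_frac: float = 0.10,
                                 second_variable: str = "p_lacI") -> Dataset:
    """Two repressilator variables, 25 points each, shared noise stream.

    The first variable's noise deviates are drawn first, so its values
    are identical to :func:`generate_comparison_course` at the same seed
    (one seed, no fresh stream for the second variable — avoiding a
    noise-realisation bias between the one- and two-variable studies).
    """
    times = np.linspace(0.0, t_max, n_points)
    return generate(
        _repressilator_recipe(times, ("p_cI", second_variable), seed, noise_frac, True)
    )


def generate_curve_data(seed: int | None = 0, noise_sd: float | None = 1.0,
                        x_start: float = 0.0, n_points: int = 21,
                        spacing: float = 0.5) -> Dataset:
    """Noisy points from the tanh test curve.

    21 x-values spaced 0.5 apart with standard-Gaussian noise by
    default; pass ``noise_sd=None`` for the noise-free curve.
    """
    x = x_start + spacing * np.arange(n_points)
    recipe = GenerationRecipe(
        model="tanh",
        true_params=dict(TRUE_TANH_PARAMS),
        times=tuple(x),
        variables=("y",),
        noise_sd=noise_sd,
        seed=seed,
    )
    ds = generate(recipe)
    if noise_sd is None:
        ds = ds.with_sigma(1.0)  # unit-SD error model for the noiseless variant
    return ds


def generate_resolution_series(point_counts=(25, 100, 500), t_max: float = 50.0,
                               sigma_frac: float = 0.10,
                               variables=("p_cI",)) -> list[Dataset]:
    """Noise-free datasets of increasing density for the
    evidence-versus-data-quantity experiment.

    Each member has ``n`` points with time gap ``t_max / n`` starting at
    zero (the densest default: 500 points, gap 0.1).  Values lie exactly
    on the true normalised trajectory; the likelihood still needs an
    error scale, so sigma is set to ``sigma_frac`` of each variable's
    range after normalisation, matching the noisy experiments' policy.
    """
    out = []
    for n in point_counts:
        gap = t_max / n
        times = gap * np.arange(n)
        ds = generate(_repressilator_recipe(times, tuple(variables), None, None, True))
        frame = ds.frame.copy()
        for var, grp in frame.groupby("variable", sort=False):
            vals = grp["value"].to_numpy()
            frame.loc[grp.index, "sigma"] = sigma_frac * (vals.max() - vals.min())
        meta = dict(ds.metadata)
        meta["sigma_policy"] = f"{sigma_frac} * range (noise-free data)"
        out.append(Dataset(frame, meta))
    return out
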