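"""Evidence-based model comparison.

Given a shared dataset, each candidate model gets its own nested-sampling
run; the resulting log-evidences are ranked and turned into pairwise
log-Bayes factors log B_12 = log Z_1 - log Z_2.  Equal model priors are
assumed throughout, so the Bayes factor equals the posterior odds.
Qualitative labels follow the Kass-Raftery 2 ln B scale.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Dataset, PriorSpec
from .models import ModelSpec, default_prior
from .ns import NSRun, run_nested_sampling

__all__ = [
    "log_bayes_factor",
    "interpret_kass_raftery",
    "ComparisonTable",
    "run_comparison",
    "evidence_vs_quantity_experiment",
    "derive_model_seed",
]

# Kass-Raftery bands on |2 ln B|
_KR_BANDS = (
    (2.0, "barely worth mentioning"),
    (6.0, "positive"),
    (10.0, "strong"),
    (np.inf, "very strong"),
)


def log_bayes_factor(logz1: float, logz2: float) -> float:
    """log B_12 = log Z_1 - log Z_2 (equal model priors assumed)."""
    if not (np.isfinite(logz1) and np.isfinite(logz2)):
        raise ValueError("log-evidences must be finite")
    return float(logz1) - float(logz2)


def interpret_kass_raftery(log_bf: float) -> str:
    """Qualitative evidence label for a log-Bayes factor.

    The Kass-Raftery scale grades |2 ln B|: [0, 2) barely worth
    mentioning, [2, 6) positive, [6, 10) strong, >= 10 very strong.
    A negative log_bf favours the second model; the label is prefixed
    with the direction when the evidence is not negligible.
    """
    if not np.isfinite(log_bf):
        raise ValueError("log-Bayes factor must be finite")
    two_ln_b = 2.0 * abs(log_bf)
    for edge, label in _KR_BANDS:
        if two_ln_b < edge:
            break
    if label == "barely worth mentioning":
        return label
    direction = "for model 1" if log_bf > 0 else "for model 2"
    return f"{label} ({direction})"


def derive_model_seed(master_seed: int, model_name: str) -> int:
    """Stable per-model seed from a master seed and the model name."""
    return (master_seed * 100_003 + zlib.crc32(model_name.encode())) % (2**31 - 1)


@dataclass
class ComparisonTable:
    """Ranked log-evidences with pairwise log-Bayes factors.

    ``table`` rows are sorted by logZ descending.  Models whose
    log-evidence gap is within the combined run errors are flagged
    ``tied_with_next`` — their order is statistically indistinguishable.
    """

    table: pd.DataFrame          # model, logZ, logZ_err, rank, converged, tied_with_next
    log_bf: pd.DataFrame         # pairwise log Bayes factors, antisymmetric
    labels: pd.DataFrame         # Kass-Raftery labels for each ordered pair
    runs: dict[str, NSRun]

    @property
    def ranking(self) -> tuple[str, ...]:
        return tuple(self.table["model"])

    def best(self) -> str:
        return self.table.iloc[0]["model"]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.table.to_csv(path, index=False)
        side = {
            "log_bayes_factors": {
                m1: {m2: float(self.log_bf.loc[m1, m2]) for m2 in self.log_bf.columns}
                for m1 in self.log_bf.index
            },
            "interpretation": {
                m1: {m2: self.labels.loc[m1, m2] for m2 in self.labels.columns}
                for m1 in self.labels.index
            },
        }
        path.with_suffix(".json").write_text(json.dumps(side, indent=2))


def run_comparison(
    models: list[ModelSpec],
    data: Dataset,
    priors: dict[str, PriorSpec] | None = None,
    *,
    n_live: int = 1000,
    tol: float = 0.5,
    n_walk: int | None = None,
    master_seed: int = 0,
    max_iter: int = 200_000,
    prior_context: str = "comparison",
    normalize_output: bool | None = None,
) -> ComparisonTable:
    """Nested-sampling evidence for every model on shared data.

    Each model runs with a seed derived from ``master_seed`` and its
    name, with its documented default prior unless ``priors`` overrides
    it.  Non-converged members are flagged in the table rather than
    silently ranked.

    ``normalize_output`` controls scale-free fitting: each ODE model's
    predicted trace is amplitude-normalised per variable, mirroring the
    normalisation applied to the data.  The default (None) switches it
    on exactly when the dataset's provenance says the data were
    normalised.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    if normalize_output is None:
        normalize_output = bool(
            data.metadata.get("recipe", {}).get("normalize", False)
        )
    runs: dict[str, NSRun] = {}
    for model in models:
        if model.is_ode and normalize_output:
            model = model.with_options(normalize_output=True)
        prior = (priors or {}).get(model.name) or default_prior(model, prior_context)
        runs[model.name] = run_nested_sampling(
            prior=prior,
            model=model,
            data=data,
            n_live=n_live,
            tol=tol,
            n_walk=n_walk,
            seed=derive_model_seed(master_seed, model.name),
            max_iter=max_iter,
        )
    return build_table(runs)


def build_table(runs: dict[str, NSRun]) -> ComparisonTable:
    """Assemble a ranked comparison table from finished runs."""
    rows = sorted(runs.items(), key=lambda kv: kv[1].logz, reverse=True)
    names = [m for m, _ in rows]
    table = pd.DataFrame(
        {
            "model": names,
            "logZ": [r.logz for _, r in rows],
            "logZ_err": [r.logz_err for _, r in rows],
            "rank": np.arange(1, len(rows) + 1),
            "converged": [r.converged for _, r in rows],
        }
    )
    tied = []
    for i in range(len(rows)):
        if i + 1 < len(rows):
            gap = rows[i][1].logz - rows[i + 1][1].logz
            err = np.hypot(rows[i][1].logz_err, rows[i + 1][1].logz_err)
            tied.append(bool(gap <= err))
        else:
            tied.append(False)
    table["tied_with_next"] = tied
    bf = pd.DataFrame(
        [[runs[m1].logz - runs[m2].logz for m2 in names] for m1 in names],
        index=names,
        columns=names,
    )
    labels = pd.DataFrame(
        [[interpret_kass_raftery(bf.loc[m1, m2]) for m2 in names] for m1 in names],
        index=names,
        columns=names,
    )
    return ComparisonTable(table=table, log_bf=bf, labels=labels, runs=runs)


def evidence_vs_quantity_experiment(
    models: list[ModelSpec],
    datasets: list[Dataset],
    *,
    n_live: int = 1000,
    tol: float = 0.5,
    n_walk: int | None = None,
    master_seed: int = 0,
    priors: dict[str, PriorSpec] | None = None,
) -> pd.DataFrame:
    """Log-evidence of each model across datasets of increasing density.

    Returns a tidy frame (model, n_points, logZ, logZ_err, converged);
    used to study how evidence — and the model ranking — changes as the
    time-course resolution improves.
    """
    records = []
    for ds in datasets:
        n_points = len(ds)
        normalized = bool(ds.metadata.get("recipe", {}).get("normalize", False))
        for model in models:
            if model.is_ode and normalized:
                model = model.with_options(normalize_output=True)
            prior = (priors or {}).get(model.name) or default_prior(model, "comparison")
            run = run_nested_sampling(
                prior=prior,
                model=model,
                data=ds,
                n_live=n_live,
                tol=tol,
                n_walk=n_walk,
                seed=derive_model_seed(master_seed + n_points, model.name),
            )
            records.append(
                {
                    "model": model.name,
                    "n_points": n_points,
                    "logZ": run.logz,
                    "logZ_err": run.logz_err,
                    "converged": run.converged,
                }
            )
    return pd.DataFrame.from_records(records)
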