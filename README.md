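# nsode

Nested sampling for Bayesian parameter inference and evidence-based
model comparison of dynamical-systems models.

Systems biologists fitting ODE models to sparse, noisy time courses face
two coupled questions: *what are the parameters* (with honest
uncertainty), and *which of several mechanistically different models
best explains the data*.  `nsode` answers both with one algorithm.
Nested sampling converts the evidence integral

    Z = ∫ L(θ) π(θ) dθ

into a one-dimensional quadrature over prior mass X by maintaining N
"live" points under an ever-rising likelihood floor: at iteration i the
worst point is withdrawn with prior mass `X_i = exp(−i/N)` and replaced
by a constrained prior draw, so

    Z ≈ Σ_i L_i w_i ,   w_i = (X_{i−1} − X_{i+1}) / 2 .

The discarded points, weighted by `p_i = L_i w_i / Z`, are posterior
samples — so parameter estimates and the model-comparison currency
(log Z, and Bayes factors `B_12 = Z_1/Z_2`) come from the same run.
The error on log Z is `sqrt(H/N)` with H the information.

The package ships the model bank used in the bundled experiments — the
Elowitz repressilator gene circuit, Lotka-Volterra, Goodwin and
Schnakenberg oscillators, plus algebraic curve models — a seeded
synthetic-data module (no downloads), posterior utilities (weighted
summaries, staircase resampling), a reference Metropolis sampler for
cross-checks, and a small CLI.

## Worked example

Infer the repressilator's transcription rate α and protein/mRNA decay
ratio β from 26 noisy observations of a single protein (cI), with the
five other initial conditions unknown:

```python
import numpy as np
from nsode import run_nested_sampling, posterior_weights
from nsode.models import get_model, default_prior
from nsode.synthetic import generate_repressilator_course

data = generate_repressilator_course(seed=1)          # 26 points, 10%-range noise
model = get_model("repressilator", fixed_ics={"p_cI": 15.0})
prior = default_prior(model, "inference")             # alpha~U(0,250), beta~U(0,10), ICs~U(0,50)

run = run_nested_sampling(prior=prior, model=model, data=data,
                          n_live=250, n_walk=40, seed=7)
post = posterior_weights(run)
print(f"logZ = {run.logz:.2f} +/- {run.logz_err:.2f}")
for p in ("alpha", "beta"):
    mu, sd = post.mean_sd(p)
    print(f"{p}: {mu:.2f} +/- {sd:.2f}")
```

Output from this exact invocation:

```
logZ = -97.41 +/- 0.22
alpha: 126.33 +/- 7.00
beta: 2.06 +/- 0.06
```

The data were generated with α = 125, β = 2: both are recovered within
one posterior SD, and the posterior widths (≈7 on α, ≈0.06 on β) show α
and β are sharply constrained even though the five unknown initial
conditions are not — the repressilator's limit cycle makes the dynamics
insensitive to them.

Model comparison uses the same machinery per model and ranks by log Z
(`run_comparison`), reporting pairwise log-Bayes factors with
Kass-Raftery labels; with data from *two* observed variables the true
model wins decisively over all three rivals.  From the shell:

```
nsode simulate --recipe recipe.yaml --out data.csv
nsode fit --model repressilator --data data.csv --out rundir/
nsode compare --models lotka_volterra,repressilator,schnakenberg,goodwin \
    --data data.csv --out table.csv
```

See `docs/methods.md` for the model definitions, prior and noise
conventions, quadrature details and known limitations.

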