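# Methods

## Problem setting

`nsode` performs Bayesian inference for dynamical-systems models fitted
to sparse, noisy time courses, with the *evidence* (marginal likelihood)

    Z = ∫ L(θ) π(θ) dθ

as the central quantity: it normalises the posterior for parameter
inference and, as a ratio between models (the Bayes factor), drives
model comparison.  The bundled experiments revolve around the
repressilator — a three-gene cyclic-repression circuit with one mRNA and
one protein species per gene — observed through one or two protein
variables, and three rival oscillators (Lotka-Volterra, Goodwin,
Schnakenberg) that could in principle explain the same data.

## Likelihood

Observation errors are independent Gaussians per point:

    log L(θ) = Σ_k [ −½ ((D_k − M_k(θ)) / σ_k)² − ln(σ_k √(2π)) ].

The normalisation constant is included so absolute log-evidences are
well defined and comparable across noise models; it cancels exactly in
Bayes factors computed on shared data.  σ is per-point when the dataset
carries a `sigma` column, otherwise a scalar from config.  A failed or
non-finite model evaluation returns −∞ rather than raising: the sampler
treats such parameter points as excluded regions.

## Priors

Only independent uniform priors are supported (all the experiments
need).  The sampler works on the unit hypercube and maps points through
`θ_i = lo_i + u_i (hi_i − lo_i)`.  Default bounds are a documented,
reproduction-sensitive choice:

| model | bounds |
|---|---|
| repressilator | α ~ U(0, 250) (spans stable and oscillatory regimes), β ~ U(0, 10), inferred initial conditions U(0, 50) |
| Lotka-Volterra, Schnakenberg, Goodwin | every rate and initial condition U(0, 10) |
| curve models | per-parameter boxes wide enough to contain the fitted scales (see `models.py`) |

## Nested sampling

The engine is Skilling-style nested sampling: N live points drawn from
the prior; each iteration withdraws the lowest-likelihood point as a
"dead" point, assigns it prior mass `X_i = exp(−i/N)` (deterministic
shrinkage; a stochastic `t_i ~ Beta(N, 1)` scheme is available for
quadrature-uncertainty experiments) and replaces it with a draw from the
prior constrained to exceed the withdrawn likelihood.  Evidence is
accumulated in log space as `logsumexp(logL_i + logw_i)`.

Quadrature widths are trapezoidal, `w_i = (X_{i−1} − X_{i+1})/2`, with
two boundary conventions chosen so the widths plus the residual live
mass telescope to exactly 1: the first dead point absorbs the strip
between X = 1 and the first trapezoid, and after termination the N live
points share `(X_M + X_{M+1})/2` equally.  This makes the evidence of a
constant likelihood exact for any N and seed — a useful structural
check.

*Constrained replacement* is a random-walk Metropolis move in the unit
cube: start from a uniformly chosen survivor, take `n_walk` Gaussian
steps (default `20·d`) reflected at the cube boundary, accept only moves
that beat the likelihood floor.  For a uniform prior this is exact
Metropolis sampling of the constrained prior.  One scalar step scale is
shared across the run and nudged toward ~50% acceptance.  If a whole
walk accepts nothing the survivor copy is returned with a warning — a
documented degradation that leaves duplicate live points rather than
aborting.  On exact likelihood plateaus, moves at equal level are
allowed so the walker can still diffuse; note that genuinely
discrete/plateau likelihoods violate the shrinkage quadrature's no-ties
assumption and are outside the supported class (the analytic test suite
uses a steep logistic "top-hat" rather than a true two-level plateau for
this reason).

*Termination* follows the remaining-evidence rule: stop when
`ln(Z + L_max X_i) − ln Z < tol`, default `tol = 0.5` (runs at 0.1
differ negligibly on the bundled problems, which the suite checks).
The error estimate is the standard `sqrt(H/N)` with information
`H = Σ p_i (logL_i − logZ)`.

All randomness flows from one seeded NumPy generator recorded in the
run; ties in logL break by insertion order (stable argmin).

## Posterior summaries

Each sample's posterior weight is `p_i = L_i w_i / Z`.  Summary
statistics (weighted mean and SD) are always computed on the weights.
Equal-weight draws for plotting use *staircase* (systematic) resampling
— a single uniform offset against the cumulative weight staircase —
which has lower variance than multinomial resampling and selects each
sample exactly once when weights are already equal.

A plain random-walk Metropolis sampler (`nsode.mcmc`) targeting the same
posterior serves as an independent cross-check; on the tanh-curve
problem its means and SDs agree with the nested-sampling summaries
within combined Monte-Carlo errors.

## Model bank and ODE solving

The four ODE systems are the standard literature forms:

* repressilator: `dm_i/dt = −m_i + α/(1 + p_j^n) + α₀`,
  `dp_i/dt = −β(p_i − m_i)` with cyclic repression lacI→tetR→cI→lacI and
  fixed structural constants n = 2, α₀ = 0;
* Lotka-Volterra: `x' = x(a − by)`, `y' = −y(c − dx)`;
* Goodwin: `x' = a/(1 + z^h) − bx`, `y' = cx − dy`, `z' = ey − fz`.  The
  Hill exponent is **fixed at h = 2 by default** (`hill_free=True`
  restores a free exponent).  The classical loop has no limit cycle for
  h ≤ 8, so this model contributes damped, often sign-crossing
  transients to the comparison — the behaviour that makes it the
  decisively worst explanation of oscillatory data.  With h free to
  reach ~10 it becomes a competent oscillator and the comparison
  degenerates; states are not clipped at zero, and the Hill input is
  floored at zero so negative z is simply "no repression" rather than a
  complex power;
* Schnakenberg: `u' = τ(a − u + u²v)`, `v' = τ(b − u²v)`, with an
  inferred time-scale τ because the natural period of the (a, b) limit
  cycle cannot otherwise reach the ~11-unit data period inside U(0, 10).

Initial conditions are model parameters unless pinned via `fixed_ics`;
the generating truth for all synthetic data is α = 125, β = 2 with
initial state (m = 0, 0, 0; p = 5, 0, 15), which sits inside the limit
cycle's basin and oscillates sustainedly.

Integration uses a numba-compiled embedded Dormand-Prince 5(4) pair with
adaptive steps (defaults rtol 1e−6, atol 1e−8), stepping exactly onto
every observation time.  It is validated against tight-tolerance LSODA
solutions (≤1e−4 relative on the repressilator truth trajectory) and a
tolerance-refinement check guards evidence values against solver noise.
A solve that exhausts its step budget (20 000 steps), leaves |y| = 1e8
or goes non-finite sets the failure flag → −∞ likelihood; stiff corners
of the prior are thereby excluded rather than crashing, the same
contract as any failed solve.

## Synthetic data

Generators are pure functions of a `GenerationRecipe` (seed included)
and stamp full provenance into the dataset metadata:

* *inference course*: 26 cI-protein points at 2-minute intervals over
  [0, 50], Gaussian noise with SD = 10% of the noise-free trace's range
  (σ in the likelihood equals the noise actually added);
* *comparison course*: 25 evenly spaced points of one variable, same
  noise policy, then amplitude-normalised (divided by the max |noisy
  value|, with σ co-scaled).  Observation times for this dataset, and
  its noise level, are assumptions (evenly spaced on the same window;
  10% of range) — the source experiments do not pin them;
* *two-variable course*: 25 points each of cI and lacI protein; one
  noise stream draws the first variable's deviates first, so the first
  variable reproduces the one-variable dataset at the same seed;
  normalisation is per variable;
* *tanh curve*: 21 points of `θ₁ tanh(θ₂ x)` (truth θ₁ = 5, θ₂ = 0.25,
  x = 0…10 in steps of 0.5) with unit-SD noise;
* *resolution series*: noise-free normalised datasets at increasing
  density (densest: 500 points, gap 0.1), with σ set by the same
  10%-of-range policy.

What the generator does *not* emulate: real measurement error structure
(correlated or signal-proportional noise), unknown detection offsets or
drifts, and model misspecification — in every experiment some candidate
model is literally true.  Passing tests therefore demonstrate the
machinery (evidence estimation, Occam trade-offs, posterior summaries),
not robustness to the ways real assay data deviate from the model.

## Scale-free comparison fits

When comparing mechanistically different oscillators on
amplitude-normalised data, each ODE model's predicted trace is also
normalised per variable (divided by its own max |value| at the observed
times).  Without this, a model's natural output scale — not its
dynamics — dominates the likelihood, and notably the repressilator
cannot fit data generated from itself: no admissible α produces a
max-1 trace with the data's ~200:1 peak-to-trough ratio.  Scale-free
fitting restores the intended question ("which dynamics explain the
waveform?") and reproduces the decisive two-variable selection of the
generating model.  `run_comparison` enables it automatically when the
dataset's provenance records amplitude normalisation.

## Model comparison conventions

Equal model priors throughout, so the Bayes factor equals the posterior
odds.  Qualitative labels follow the Kass-Raftery bands on |2 ln B|:
[0, 2) barely worth mentioning, [2, 6) positive, [6, 10) strong, ≥ 10
very strong.  Per-model seeds derive from a master seed plus a CRC of
the model name; rankings whose log-evidence gap is within the combined
run errors are flagged statistically indistinguishable.

## Problem sizes and numerical choices

Headline-scale runs use N = 1000 live points (the library default).
The bundled test battery and the reproduction script scale N down
(120–500 depending on the experiment) and use walk lengths of 20–40
steps; these sizes are the package's own trade-off between Monte-Carlo
error (`sqrt(H/N)`, typically 0.15–0.35 in log-evidence here) and
runtime, and every tolerance is quoted at the scaled size.  Evidence
accumulation is logsumexp throughout; weights are renormalised once at
the end to remove quadrature round-off.

## Known limitations

* The constrained walker is a single-chain Metropolis move, not an
  ellipsoidal or clustering sampler: heavily multimodal posteriors in
  high dimension mix more slowly, and log-evidence scatter between
  seeds can exceed the nominal `sqrt(H/N)` at small N.
* Deterministic shrinkage ignores quadrature-width randomness; the
  stochastic-shrinkage option exists precisely to quantify it.
* Plateau (discrete-valued) likelihoods violate the shrinkage
  assumptions, as noted above.
* Published log-evidences for these experiments depend on prior bounds,
  noise seeds and σ conventions that are not recoverable from the
  source; absolute evidences here are internally consistent (and
  oracle-validated on analytic problems) but can differ from printed
  historical values by more than their Monte-Carlo error, whereas
  parameter-recovery results and the two-variable model ranking
  reproduce directly.
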