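# Methods

## Model and estimation

Each growth family describes the mean body weight W(t; θ) of an animal at
age t days through at most four parameters (asymptote α in kg, scale β,
rate k per day, shape m). Estimation is **pooled nonlinear least squares**:
all records of a group (all lambs, males, or females) enter one objective

    SSE(θ) = Σ_i (W_i − W(t_i; θ))²,

with no per-animal random effects. This matches the classical workflow of
growth-curve comparisons in sheep (a single `nls`-style fit per model and
group) and is what the goodness-of-fit battery below presupposes. The
consequence — residuals within an animal are correlated — is accepted as
part of the method, not modelled away.

### Self-starting values

Nonlinear fits live or die by their starting point. `initial_values`
derives one deterministically from the data:

1. Candidate asymptotes α₀ = c·max(W) over the ladder
   c ∈ {1.05, 1.2, 1.5, 2, 3}. The ladder matters because a measurement
   window ending mid-growth (e.g. 140 days for a breed maturing near 2
   years) can hide an asymptote several times the heaviest observed weight.
2. For each candidate, the remaining parameters come from linearising the
   mean curve on the age-binned mean weights: Gompertz
   ln(−ln(W̄/α₀)) = ln β − kt, Brody ln(1 − W̄/α₀) = ln β − kt, Logistic
   ln(α₀/W̄ − 1) = ln β − kt, negative exponential the Brody form through a
   zero intercept. Bins within 10% of α₀ are excluded (the transforms blow
   up there) whenever at least three informative bins remain.
3. MMF and Weibull start β₀ from the earliest-age mean weight (W(0) = β
   for MMF, α − β for Weibull) and search a coarse grid m ∈ {0.5, 0.75, …,
   3.0} × 60 log-spaced k values.
4. The candidate with the smallest SSE on the binned means wins.

Constant weights (no growth signal) raise a degenerate-data error; fewer
than three distinct ages an insufficient-data error.

### Optimiser

`fit` minimises the SSE by Levenberg–Marquardt damped least squares
(`scipy.optimize.least_squares`, method `lm`) on **log-transformed
parameters**, which enforces positivity by construction without bound
handling. Tolerances: relative SSE improvement 1e−10, parameter step
1e−8, up to 500 iterations worth of function evaluations. If the first
solve fails or ends worse than its start, the best of five deterministic
jittered restarts (log-normal jitter, SD 0.3, seeded) is kept — the MMF
and Weibull SSE surfaces are flat in (α, k, m) and can strand a single
start. Non-convergence is reported on the result object, never raised.
Records are sorted canonically (animal, age) before the objective is
assembled so that estimates are exactly invariant to input row order
(floating-point summation is not associative).

### Standard errors

Asymptotic Gauss–Newton errors: σ̂² = SSE/(n − p) times the diagonal of
(JᵀJ)⁻¹, with J the Jacobian of the mean curve in the natural parameters
at θ̂ (central finite differences, relative step 1e−6). J's columns differ
by five orders of magnitude (α in hundreds of kg, k in thousandths per
day), so J is column-equilibrated before inversion; only a genuinely
singular system (reciprocal condition below 1e−14) or vanishing degrees of
freedom (n ≤ p) yields "SE unavailable".

## Goodness of fit and ranking

For a converged fit with SSE, n records and p curve parameters:

* profile Gaussian log-likelihood  ℓ = −(n/2)(ln 2π + ln(SSE/n) + 1);
* `ml` convention (default): p_eff = p + 1 (the residual variance counts),
  AIC = −2ℓ + 2p_eff, BIC = −2ℓ + p_eff·ln n — the numbers R's
  `AIC()`/`BIC()` print for an `nls` fit;
* `sse` convention: AIC = n·ln(SSE/n) + 2p, BIC = n·ln(SSE/n) + p·ln n;
* RMSE = √(SSE/n) and adjusted R² = 1 − ((n−1)/(n−p))·SSE/SST, with SST
  about the group mean, are convention-free.

The two conventions differ by the constant n(ln 2π + 1) + 2 (for p = 3),
so within-group rankings agree; conventions are never mixed in one
comparison. Ranking is by ascending AIC; ties below 0.01 (equality at the
printed precision) break by BIC, then by fewer parameters, then model name.
A useful internal check on any published criteria table under the `ml`
convention: BIC − AIC = p_eff(ln n − 2), so the gap backs out the sample
size — consistency of that implied n across models of different p is a
strong sanity test, and `selection.infer_n_from_criteria` implements it.

## Growth-rate analysis

The AGR is the analytic first derivative of the mean curve (closed forms
for all six families). Peaks are taken from the closed-form inflection
when one exists inside (0, horizon]; the default horizon is 140 days, the
design's measurement window. For curves whose AGR is strictly decreasing
(negative exponential, Brody, shape families with m ≤ 1) no peak is
reported — the rate at t → 0⁺ is exposed separately as the *initial rate*
rather than dressed up as a maximum. At t = 0 the shape families need the
limit of t^(m−1): zero for m > 1, (α−β)k (MMF) or βk (Weibull) at m = 1,
and +∞ (flagged by a warning) for m < 1. Reported peaks round time to 0.1
day and rate to 2 decimals.

## Synthetic flocks

`simulate_flock` emulates the target design: 41 male and 44 female lambs,
weights at ages 0, 10, …, 140 days (15 scheduled records each, 1275 in
total). Defaults:

| parameter    | default | meaning |
|--------------|---------|---------|
| true_model   | gompertz | generating family |
| theta_male   | α=64.47, β=2.39, k=0.0156 | published male Gompertz means |
| theta_female | α=49.28, β=2.21, k=0.0181 | published female Gompertz means |
| animal_cv    | 0.10 | per-animal multiplicative spread of α |
| residual_sd  | 3.4 kg | homoscedastic Gaussian measurement error |
| missing_rate | 0.0 | records dropped completely at random (0.135 emulates a flock where ~1 in 7 weighings was missed, ≈1103 records) |

Each animal draws α_i = α(1 + cv·z_i); weights are mean curve plus noise,
truncated below at 0.25 kg; everything is reproducible from the seed.
Options exist for heteroscedastic noise (SD ∝ mean) and for varying all
parameters per animal, both off by default because the least-squares
criteria assume constant variance and the α-only structure is the simplest
one producing realistic between-animal spread.

What the generator does **not** emulate: litter size, dam and season
effects, weaning shock around day 80, non-random missingness. Passing
tests on simulated flocks therefore demonstrate estimator correctness and
calibration under the stated noise model, not robustness to those real-
world structures.

A calibration note: with residual SD 3.4 kg as the only noise source, a
per-sex fit returns RMSE ≈ 3.4 (band 3.1–3.7 across seeds). Two things
inflate it above that: the default per-animal α spread (within-animal
correlated deviations), and pooling both sexes into one fit (a single
curve fitted to two sex-specific curves absorbs the sex gap as lack of
fit). With defaults the pooled RMSE lands near 4.2–4.5 kg — the upper end
of what comparable field studies report — so the defaults are kept and
calibration is asserted per sex without animal-level spread.

## Numerical and design notes

* **Identifiability.** When the true asymptote lies far beyond the data
  window (Brody-type curves with α several times the heaviest observed
  weight), α and k are close to unidentified: the SSE surface is a flat
  valley, standard errors on α become enormous (tens of kg), and the
  sampling distribution of α̂ is heavy-tailed. Median bias at 200
  study-scale replicates stays below 5%, but estimates from any single
  flock deserve their SEs taken seriously.
* **Brody β ≤ 1.** β > 1 implies negative weight at birth; it is accepted
  with a warning (values slightly above 1 arise transiently during
  optimisation) rather than rejected.
* **Nesting.** The negative exponential is Brody with β = 1; the Brody fit
  can therefore never have a larger SSE on the same data, which the tests
  use as an oracle.
* **Record validation.** Duplicate (animal, age) rows are an error, never
  silently averaged; ages are integer days (no date arithmetic); sex codes
  M/F/male/female in any case are normalised.
* **Report rounding.** Parameters and SEs print at 4 significant figures,
  criteria at 2 decimals.
* **Problem sizes in the test-suite.** The simulation studies use 200
  replicate flocks for parameter recovery and 100 for model-selection
  frequency — enough for the median and proportion estimates they assert,
  while each individual fit (≈600–1300 records) runs in milliseconds.
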