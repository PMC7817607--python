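# Methods

## Model and criterion

Durations are ages at disease onset measured in years since the 50th
birthday.  The conditional hazard is Gompertz proportional-hazards,
`a(t|z) = a e^{β₁t} e^{β₂'z̃ + β₃ z_s}` with cumulative hazard
`A(t|z) = (a/β₁) e^{β₂'z̃+β₃z_s} (e^{β₁t} − 1)`, CDF `F = 1 − e^{−A}`
and density `f = a(t|z) e^{−A}`.  β₁ ≥ 0 is required; the β₁ = 0
exponential submodel is handled as a continuous limit (`A = a t e^{lp}`)
rather than excluded, because the preliminary cohort-only model is
exactly that submodel and the optimizer's box bound must be attainable.

Observation is doubly censored: a subject enters the study window at age
`50 + L` and exits at `50 + R` (end of study, death without disease, or
loss to follow-up).  Onset before entry yields a left-censored record
`(L, δ=−1)`, onset after exit a right-censored record `(R, δ=1)`, and
onset inside the window an exact record `(y*, δ=0)`; ties at the window
edges count as uncensored.  Each record contributes
`Ψ = 1{δ=0} log f + 1{δ=−1} log F + 1{δ=1} log(1−F)`; the total criterion
is the θ-carrying factor of the conditional likelihood, so the
(unmodelled) joint law of (L, R) and the covariate marginals affect
neither the maximizer nor — by the conditional information-matrix
equality below — the standard errors.

Identification under censoring rests on a Wald-type dominance argument:
over a compact rate interval [ε, 1/ε] the absolute exponential
log-likelihood ratio `|log(a/a₀) − (a−a₀)y|`, concave in `a`, is maximized
at one of three candidates (the two edges, or the interior stationary
point `1/y` when it falls inside the interval).  `wald_dominance_bound`
implements that envelope; the property suite verifies it dominates a
dense grid and is integrable against the true density, which is what
makes the convergence of the criterion uniform and the maximizer
consistent.  ε defaults to 0.1 and is configurable; any small positive
value defines a valid compact parameter space.

## Estimation and inference

`fit_cmle` maximizes the criterion with L-BFGS-B (analytic gradient, box
bound β₁ ≥ 0) and then polishes with Newton steps on a
central-difference Hessian of the analytic gradient until the score
sup-norm is below 1e-6·n (projected when the β₁ bound is active);
convergence is declared only after this ex-post check plus a
positive-definite average observed information Ĵ.  Starting values come
from the uncensored records alone: the exponential closed form
`â = n/Σy` is the inner start and β₁ is found by one-dimensional profile
maximization of the uncensored Gompertz likelihood on [0, 2]/yr (for
fixed β₁ the baseline MLE is `n β₁/Σ(e^{β₁yᵢ}−1)`, so the profile is
exact, not an approximation).  On very small samples the profiled β₁ can
be far from 0 even for exponential data — the three-observation profile
peaks near 1.2/yr — which is expected behaviour of a profile likelihood,
not a defect; with realistic n it concentrates near the truth.  If the
criterion is non-finite at the start (possible when prevalent records
meet an extreme start), a fixed fallback (a = 0.01, β₁ = 0.1) is used
and logged.

Standard errors are `se_k = sqrt([Ĵ⁻¹]_kk / n)` with
`Ĵ = −(1/n) Σ ∂²Ψᵢ/∂θ∂θ'` evaluated by central differences of the
analytic gradient (step `eps^{1/3} max(1, |θ_k|)`); 95 % intervals are
θ̂ ± 1.96·se.  For this criterion the outer-product information
`Î = (1/n) Σ (∂Ψᵢ/∂θ)(∂Ψᵢ/∂θ)'` estimates the same matrix, so the
sandwich collapses; `cime_diagnostic` returns (Ĵ, Î, ‖Î−Ĵ‖/‖Ĵ‖) so the
equality can be monitored — the suite checks the relative difference
falls below 0.05 at n = 10⁵ under the true model and stays bounded away
from zero when an exponential is forced onto strongly Gompertz data.
The cohort-only model is also available as independent per-cohort
exponential fits (`stratified_cohort`), which reproduce the joint fit
exactly because that criterion factorizes over strata.

Numerical care: `log F = log(1−e^{−A})` uses the complementary `expm1`
form; `A` is computed from `log A` and clipped at `e^{300}` so gradients
stay finite far from the optimum; `(e^{β₁y}−1)/β₁` and its β₁-derivative
switch to Taylor limits below |β₁| < 1e-8 (and the log-form is
sign-aware so finite-difference probes just below β₁ = 0 remain valid).
Prevalent records with y = 0 would contribute log F(0) = −∞; they are
dropped with a warning at dataset construction, since zero-exposure
prevalence carries no usable information.

## Synthetic claims-window generator

`gompcens.synthetic` emulates the observation scheme of a large
health-claims register: integer birth years 1900–1954 drawn from a
six-cohort mixture, uniform birth fraction within the year, a study
window opening 2004.0 and closing 2013.0, `L = max(0, 2004 − birth − 50)`
and `R` at end of study or an optional exponential loss to follow-up
(rate default 0 — no attrition value is published).  Onset ages are
drawn from the model itself by quantile inversion, so recovery tests
have exact ground truth.  Default parameters are the double-censoring
point estimates of the motivating dementia study
(a = 0.190×10⁻³, β₁ = 0.183, β₂ = (−2.095, −1.177, −0.441, 0.525,
1.342), β₃ = −0.039) with cohort weights (0.01, 0.03, 0.08, 0.22, 0.36,
0.30) — a 2004 cross-section is dominated by the post-1930 cohorts —
giving aggregate shares of roughly 4 % left-censored / 10 % uncensored /
86 % right-censored, close to the 4.5/14.6/80.9 split of the real
register.  What the generator deliberately omits: mortality (no
death-driven selection — that lives in the Markov simulator), within-year
birth seasonality, and the register's sampling weights; recovery tests
therefore demonstrate correctness of the estimator under the assumed
model, not robustness to those real-data features.

Time is continuous by default.  `discretize_times` optionally snaps
durations onto a reporting grid (events to mid-month or mid-quarter,
losses to quarter end) and applies the prevalence convention that a
diagnosis in the first two quarters of the opening year is reclassified
as left-censored at the entry age — the grid is an observation artifact,
not part of the model, hence opt-in.

For recovery and information-matrix checks at the θ used in the
acceptance suite (a = 0.02, β₁ = 0.15), the window is widened to open in
1970: under the 2004 window the pre-1930 cohorts are essentially all
prevalent with F(L) ≈ 1, their cohort coordinates carry vanishing
information and the observed information is numerically singular.  The
widened window keeps events in every cohort so all eight coordinates are
identified; it is a test-design choice, not a change to the generator's
defaults.  Confidence-interval coverage is measured on a three-parameter
configuration (baseline, age, sex; n = 2000, 1000 replications) where
every coordinate is well identified, so the nominal-coverage check is
sharp rather than trivially satisfied by inflated intervals.

## Healthy–ill–dead simulation and the truncation bias study

The Markov simulator draws, per individual, a 50th birthday uniform on
[1950, 2004], an exponential sojourn in Healthy with rate `a·e^{βz} + c`
(z = 1 for 50th birthdays from 1978 on, when a cohort effect β is
configured), a multinomial destination (Ill with probability
`a·e^{βz}/(a·e^{βz}+c)`, else Dead), and an Exp(b) residual from Ill to
Dead.  Defaults a = 1/35, b = c = 1/45.  Anyone dead before 2004.0 is
left-truncated (never sampled); among survivors, onset before 2004 gives
a left-censored record at the entry age, onset before min(death, 2014.0)
an exact record, otherwise right-censoring at death or end of
collection.  With b = c, survival to 2004 is independent of illness
history, which is exactly why keeping the prevalent cases removes the
truncation bias; the unequal-rates scenario is available but has no
canonical parameter values, so it ships configurable and without a
reference target.  An analytic cross-check integrates the closed-form
two-phase death CDF over the birth window (`truncation_probability`) and
matches the simulated truncation share.

`bias_study.run_scenario` repeats the pipeline (default 2000
replications — enough that Monte-Carlo SEs are a few tenths of a percent
on the relative bias, at desk-scale runtime; the published experiments
used 10 000), fits the constant hazard (plus the cohort dummy in the
cohort scenario) once keeping and once discarding left-censored records
on the *same* simulated populations, and reports per-(mode, N) mean
counts, bias B = mean(γ̂) − γ, relative bias rB = 100·B/γ and MC standard
errors.  Replication tolerance is max(3·MC-SE, 5 % of the reference
value).  Per-replication fit failures are logged and excluded; more than
1 % aborts the run.  Known limitation: with the homogeneous defaults the
ignored-mode relative bias and all count columns replicate the published
table, and the cohort scenario replicates its considered-mode rows and
count columns, but its ignored-mode bias magnitudes sit a few percent
above the published point values (≈0.93 vs 0.88 on the cohort effect);
the published ignored-mode rows are not internally consistent at the
stated replication count, so the harness reports its own MC-SEs and the
acceptance test documents the gap rather than retuning the simulator.

Estimator sanity floor: with the truncation year moved before the birth
window (no selection, no prevalence), the constant-hazard estimate is
unbiased up to the O(1/n) small-sample term of a censored exponential
MLE, and the test allows exactly that term beyond 3 MC-SEs.
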