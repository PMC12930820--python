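# Methods

## Trial model

`generate_trial` simulates a two-stage, two-treatment SMART in which only
non-responders to stage 1 are re-randomised. Baseline `O1 ~ N(0,1)`;
`A1 = ±1` with probability 0.5; intermediate outcome
`O2 ~ N(0.5·O1 + 0.5·I(A1=−1), 1)`; responder status `R = I(O2 ≤ 0)`
(the probability-zero tie `O2 = 0` is classified responder, fixed by
convention); stage-2 treatment `A2 = ±1` with probability 0.5 for
non-responders only; outcome
`Y = 1 + O1 + O2 + A1(δ + O1) + I(O2>0)(δ/2)A2 + ε` with `ε ~ N(0,1)`.
The treatment-effect magnitude δ defaults to 0.1 at both stages.
Treatments are coded −1/+1 throughout; the CSV reader rejects 0/1 coding
rather than silently recoding. A responder's `A2` is a *structural*
not-applicable marker (NaN with missingness indicator 0), never conflated
with dropout missingness.

Each simulated dataset derives its RNG stream from
`SeedSequence(master_seed, spawn_key=(cell, replicate))`, so replicates
are reproducible independently, in any order, and under any worker count.
One deliberate consequence: stage-2 assignments are drawn for all
participants from a single stream position and blanked for responders,
keeping the stream layout independent of the realised responder pattern.

## Truth values

The MSM `E[Y(d)] = β0 + β1·A1 + β2·A2` has three coefficients for four
regimen means, so the estimand is the least-squares projection of the
cell means onto `(1, A1, A2)`. Replication plus design weighting gives
every `(A1, A2)` cell equal total weight, so the projection is the
orthogonal-contrast one. The exact cell means are

    E[Y(a1, a2)] = 1 + μ(a1) + δ·a1 + (δ/2)·a2·Φ(μ(a1)/√1.25),
    μ(a1) = 0.5·I(a1 = −1),

where Φ(μ/√1.25) is the non-responder probability — `O2` has *marginal*
variance 1.25 given the arm, since the `O1` contribution adds 0.25 to the
unit conditional variance. At δ = 0.1:
`β* = (1.25, −0.15, 0.02932)`, `θ* = Cβ* = (1.1293, 1.0707, 1.4293,
1.3707)`. `monte_carlo_truth` recovers the same values through the full
estimation pipeline on complete data (the package's acceptance run uses
200 datasets of 10,000 participants, which resolves each coefficient to a
Monte Carlo error of about 0.0016); both routes agree within Monte Carlo
error, and the analytic values serve as the oracle everywhere
performance is summarised.

## Missingness mechanisms and calibration

Four scenarios, monotone by construction (`M_O2 = 1 ⇒ M_A2 = M_Y = 1`;
`M_A2 = 1 ⇒ M_Y = 1`; `O1`, `A1` always observed):

1. `logit P(M_Y) = α0` — outcome missing completely at random.
2. `logit P(M_Y) = α0 + α1·O2 + α2·I[A2 = 1]` — the stage-2 indicator
   contributes 0 for responders, who have no stage-2 randomisation.
3. `logit P(M_O2) = α0 + α1·O1 + α2·I[A1 = 1]`; `A2` and `Y` are erased
   wherever `O2` is, and `R` is blanked with `O2` (it is a deterministic
   function of it).
4. `logit P(M_A2) = α0 + α1·O2`, evaluated for **all** participants (the
   continuous `O2` term automatically makes non-responders more likely to
   drop); `Y` is erased wherever the event fires, and for responders the
   event erases `Y` only. A config flag
   (`scenario4_nonresponders_only`) restricts the model to non-responders
   instead.

Slopes are `log(OR)` with OR 1.6 (weak) or 3.0 (strong). The intercept
is calibrated by Brent root-finding of
`mean(expit(α0 + lp)) = target` on one frozen simulated dataset of 10⁶
participants — the expected proportion given the frozen covariates, which
is monotone and noise-free in α0 — rather than re-simulating Bernoulli
draws per iterate. Scenario 1 uses the closed form `α0 = logit(target)`.
The calibration denominator is the full sample of n participants
(the scenario's driving indicator: `M_Y` for 1–2, `M_O2` for 3, `M_A2`
for 4); "20% or 40% missingness" is read as a marginal proportion. On a
fresh dataset of 10⁵ the achieved proportion matches the target to well
within one percentage point (binomial noise ≈ 0.13–0.16 points).

## Estimation

`replicate_and_weight` duplicates each responder's row with `A2 = −1` and
`A2 = +1` (weight 2 each) and keeps non-responders once (weight 4); total
weight is exactly 4n. Weights are derived in code as reciprocal products
of the design randomisation probabilities so the construction stays
visible. `fit_msm` solves the weighted normal equations directly —
identical to the independence-working-correlation estimating equations,
with no iterative machinery; a `(A1, A2)` cell with zero total weight
raises a named singularity error. Clustering of a responder's two pseudo-
rows affects only variances, never the point estimate; a cluster-robust
sandwich covariance (`cluster_robust_cov`) is exposed for diagnostics and
Rubin within-imputation variances.

Reported model-based standard errors come from a cluster bootstrap
(`bootstrap_se`, default B = 200) that resamples *participants* with
replacement before replication, so a responder's two rows always travel
together, and re-runs the configured missing-data handler inside every
resample. Singular resamples (possible at small n after complete-case
filtering) are redrawn up to 50 times per slot and counted in the
diagnostics. For MI the bootstrap re-imputes each resample with a reduced
imputation count (default m = 5) for tractability; a `rubin` mode instead
pools per-imputation sandwich variances by Rubin's rules with
Barnard–Rubin small-sample degrees of freedom, and the mode used is
recorded with the results so coverage is always attributable to a stated
procedure.

## Missing-data handlers

**Complete case analysis** keeps exactly the participants with
`M_O2 = M_A2 = M_Y = 0`; a responder's structurally absent `A2` never
causes exclusion.

**Multiple imputation** is chained equations with, per cycle, the order
`O2 → (R recomputed passively) → A2 (logistic, only for records whose
current O2 > 0) → Y`, matching the monotone dropout structure. The
conditional models are `Y | O1, A1, A2, O2`, `O2 | O1, A1, A2, Y`
(Bayesian linear regression: scaled inverse-χ² draw of σ², normal draw of
the coefficients, then residual noise) and `A2 | O1, A1, O2, Y` (logistic
with asymptotic-normal coefficient draws; separation falls back to a
weakly ridge-penalised fit, logged). `A1` appears as a regressor in the
pooled variant and as the stratification factor in the default within-arm
variant. Initial values are draws from the observed
marginals; chains use independent substreams of the imputation seed;
observed cells are never altered. `R` is never imputed directly — it is
the deterministic sign rule applied to the current `O2` — and responders
never receive an imputed `A2`; where `A2` predicts another variable, the
structural state is zero-coded. The number of imputations defaults to 20
at 20% missingness and 40 at 40%, with 5 cycles.

**Within-arm imputation (design choice).** By default every imputation
model is fitted separately within each stage-1 arm
(`ImputationSpec.stratify_by_stage1 = True`). The outcome surface
contains the interaction `A1·O1` with coefficient 1 — in the `A1 = +1`
arm the baseline enters `Y` with slope 2, in the other arm with slope 0 —
so a single pooled main-effects imputation model is incompatible with the
data model: in simulation it leaves systematic bias of roughly ±0.2 in
the DTR means under scenarios 2–4 even though the missingness is MAR.
Within an arm each stated conditional model is (essentially) exactly
specified, and MI then behaves as multiple imputation theory predicts:
near-unbiased wherever missingness depends only on observed quantities.
The pooled variant remains available for sensitivity analyses. One
residual approximation either way: for records whose imputed `O2 ≤ 0`
(imputed responders), `Y` is imputed from the same linear model with the
zero-coded `A2` convention.

## Performance evaluation and the experiment grid

`summarize` reports, per parameter (β0, β1, β2, θ1–θ4): signed bias and
absolute bias (plots use signed bias with a zero reference line),
empirical SE (SD across replicates), model-based SE (mean of per-replicate
bootstrap SEs), and coverage of nominal 95% intervals
(normal-quantile with bootstrap SEs; t-based when Rubin pooling supplies
degrees of freedom), each with its Monte Carlo standard error
(`empSE/√n`, `empSE/√(2(n−1))`, `√(cov(1−cov)/n)`).

`run_experiment` covers the factorial grid 4 scenarios × {20%, 40%} ×
{weak, strong} × {CCA, MI} (32 cells; defaults: n = 400 participants,
1000 replicates, B = 200). Calibrated intercepts are computed once per
(scenario, strength, proportion, δ) and shared between methods so the
CCA/MI comparison faces identical mechanisms. Failed replicates are
recorded with their seeds, never silently dropped; a cell aborts if more
than 1% fail. Results are written as a tidy CSV from which the plotting
command regenerates bias/SE/coverage panels.

The package's own checks run everything at reduced scale — 200–500
replicates per cell, truth at 200 × 10,000, bootstrap inside roughly 10⁵
resample fits — chosen so the full suite completes in a couple of minutes
while keeping Monte Carlo errors small relative to every tolerance
asserted.

## What the simulation does and does not show

The generator reproduces the stylised trial exactly: Gaussian outcomes,
a single baseline covariate, 0.5/0.5 randomisation, a small treatment
effect (δ = 0.1), and missingness that is logistic in at most two
observed or partially observed variables. Passing tests therefore
demonstrate correctness of the estimator, the calibration, and the
handlers *under this model* — they say nothing about non-monotone
patterns, outcome-dependent (MNAR) missingness, auxiliary-variable
gains, imbalanced randomisation, more than two stages, or non-Gaussian
outcomes, none of which are modelled.

Two structural findings from this implementation deserve note when
comparing against published summaries of similar designs. First, under
the scenario-2 mechanism as literally specified (missingness of `Y`
increasing in `O2` for everyone), complete-case selection depletes
non-responders in *every* treatment cell; because responders' outcomes
are systematically lower, all four DTR means — not only those of the
`A2 = +1` regimens — are biased. A pattern in which the `A2 = −1`
regimens stay unbiased arises only if responders and `A2 = −1`
non-responders are exempt from differential missingness. Second, with
compatible (within-arm) imputation models, MI is near-unbiased under
scenario 3 as well, since that mechanism is MAR given the always-observed
`O1` and `A1`; residual MI bias there is a symptom of an incompatible
pooled imputation model, not of the missingness mechanism.

## Known limitations

- MI inside the bootstrap is computationally heavy (B × m model fits per
  replicate); the reduced within-bootstrap m = 5 trades some SE accuracy
  for tractability, and the Rubin mode is the cheap alternative.
- The logistic imputation model can separate in very small resamples; the
  penalised fallback keeps chains running but slightly shrinks draws.
- Calibration targets the marginal proportion; mechanisms targeting
  conditional proportions (e.g. 20% among non-responders) are available
  only for scenario 4 via its restriction flag.
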