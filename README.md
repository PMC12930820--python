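# smartmiss

Simulation toolkit for studying **missing data in two-stage SMARTs**
(sequential multiple assignment randomised trials) when the mean outcomes
of the embedded **dynamic treatment regimens (DTRs)** are estimated by
**inverse probability weighting (IPW)**. It is aimed at trial
statisticians and methods researchers who want to compare complete case
analysis (CCA) with multiple imputation by chained equations (MI) under
explicit, calibrated missingness mechanisms.

## The design and the estimand

Participants are randomised at stage 1 to `A1 ∈ {−1, +1}`. An
intermediate outcome `O2` classifies them: non-responders (`O2 > 0`) are
re-randomised to `A2 ∈ {−1, +1}`, responders continue on their stage-1
treatment. Four DTRs `(a1, a2)` are embedded. The data-generating model
is

```
O1 ~ N(0, 1)                       P(A1 = ±1) = 1/2
O2 ~ N(0.5·O1 + 0.5·I(A1 = −1), 1) P(A2 = ±1 | O2 > 0) = 1/2
Y  = 1 + O1 + O2 + A1(δ + O1) + I(O2 > 0)(δ/2)A2 + ε,   ε ~ N(0,1),  δ = 0.1
```

The analysis model is the marginal structural model (MSM)

```
E[Y(d_k)] = β0 + β1·A1 + β2·A2
```

fitted on a *replicated* dataset: each responder, being consistent with
both stage-2 options of their arm, contributes two rows (`A2 = −1` and
`A2 = +1`) with IPW weight `1/0.5 = 2` each; each non-responder keeps one
row with weight `1/(0.5·0.5) = 4`. Weighted least squares on
`(1, A1, A2)` solves the independence-working-correlation estimating
equations exactly. The DTR means are the contrasts
`θ = C β`, `C = [[1,1,1],[1,1,−1],[1,−1,1],[1,−1,−1]]`, with true values
`β* ≈ (1.25, −0.15, 0.029)` and `θ* ≈ (1.129, 1.071, 1.429, 1.371)`.

Missingness is imposed by logistic models on the complete data under four
scenarios (outcome missing completely at random; outcome missing given
`O2` and `A2`; dropout after stage 1 erasing `O2`, `A2`, `Y` given `O1`
and `A1`; dropout before stage 2 erasing `A2` and `Y` given `O2`), with
odds-ratio slopes 1.6 (weak) or 3.0 (strong) and intercepts calibrated so
the marginal missingness proportion hits 20% or 40%. Standard errors come
from a cluster bootstrap (participants resampled before replication,
B = 200); MI pools by Rubin's rules.

## Worked example

```python
import numpy as np
import smartmiss as sm
from smartmiss.missingness import calibrated_config, impose_missingness
from smartmiss.handlers import complete_case, mice_impute, ImputationSpec

trial = sm.generate_trial(sm.SimulationParams(n_participants=400, delta=0.1, seed=29))
fit = sm.fit_msm(sm.replicate_and_weight(trial))
print("complete data  theta:", np.round(sm.theta_from_beta(fit).theta, 3))

cfg = calibrated_config(scenario=2, strength="strong", target_proportion=0.4)
inc = impose_missingness(trial, cfg, seed=11)

cc = complete_case(inc)
fit_cc = sm.fit_msm(sm.replicate_and_weight(cc))
print("CCA            theta:", np.round(sm.theta_from_beta(fit_cc).theta, 3))

betas = [sm.fit_msm(sm.replicate_and_weight(d)).beta
         for d in mice_impute(inc, ImputationSpec(m=40, seed=13))]
print("MI (m=40)      theta:", np.round(sm.CONTRAST_MATRIX @ np.mean(betas, 0), 3))
print("truth          theta:", np.round(sm.analytic_truth(0.1).theta, 3))
```

prints

```
complete data  theta: [1.116 1.051 1.402 1.336]
CCA            theta: [0.063 0.575 0.471 0.982]
MI (m=40)      theta: [1.071 1.022 1.351 1.302]
truth          theta: [1.129 1.071 1.429 1.371]
```

With ~40% of outcomes missing dependent on `O2` and `A2`, dropping
incomplete participants wrecks every DTR mean (complete cases
over-represent responders, whose outcomes are systematically lower),
while imputation conditional on the observed history recovers the truth
to within sampling noise of this single n = 400 trial.

The full factorial experiment (4 scenarios × 2 proportions × 2 strengths
× 2 methods) runs from the command line:

```
smartmiss run --scenario 2 --method cca --method mi --nsim 200 --boot 0 --out results/
smartmiss plot results/results.csv --measure bias --out bias.png
```

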