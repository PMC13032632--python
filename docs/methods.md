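# Methods

## Model structure

The evaluation is a cohort model: a decision tree over diagnostic
outcomes feeding stage-specific Markov chains, run once per decision
branch and combined by branch weight (the model is linear in the
cohort, so mixing branches after the fact is exact).

**Decision tree.** For histopathology: true-positive limited
((1−fn_p)·p_lim), true-positive advanced, and a false-negative branch
(fn_p) whose patients start treatment after a delay, represented
entirely by assigning them advanced-stage survival and costs — no
calendar offset is applied, since no delay duration is available for
discounting purposes. For liquid biopsy: the analogous true-positive
branches with its own stage mix, plus a false-negative subtree that is
the *entire* histopathology tree scaled by fn_l, with the liquid test
cost carried along. By default the subtree retains the pathology
false-negative rate (so fn_l·fn_p of the liquid cohort are doubly
missed); `DiagnosticParams.fn_recursive=False` switches to treating all
liquid false negatives as correctly diagnosed by pathology. A second
switch, `fn_stage_policy="retain"`, lets false negatives keep the
presenting stage mix instead of advancing (the staging scenario).

**Markov chain.** Four states: on-treatment (first 3 months),
post-treatment (to month 24, the disease-risk window), post-disease,
dead. Within the window, per-cycle death probabilities are conditional
Weibull probabilities `1 − S(t_{k+1})/S(t_k)`, so the survivor product
telescopes to S(horizon) for any cycle grid. All deaths inside the
window are attributed to disease: the fitted curve is all-cause, and
background mortality at ages 10–12 is negligible beside it. After the
window only background mortality applies, by constant-hazard conversion
of the life-table annual probability, until age 100 (which exhausts the
fixture table; residual occupancy there is ~1e-4 and is truncated).
A half-cycle correction is used throughout: person-time per cycle is
the mean of start- and end-of-cycle occupancy, and deaths are timed at
cycle midpoints for discounting.

**Cycle grids.** The base cycle is 3 months. The short-cycle scenario
uses calendar weeks (7/365.25 years, i.e. ≈0.22998 months) over the
disease window; 24 months is not an integer number of such weeks, so
the engine closes the window with an explicitly flagged truncated final
cycle (`RunSettings.allow_partial_final_cycle`). Without the flag,
validation enforces exact divisibility. Post-disease cycles are always
quarterly.

## Outcomes

DALYs = YLL + YLD, discounted at 5%/year (separately overridable for
costs and outcomes, which the one-way analysis uses).

* **YLL** per death at age a: `(1 − e^{−r·e(a)})/r` with e(a) the
  life-table remaining life expectancy — continuous discounting, which
  reproduces the ~19.2 discounted YLL for a death at age 10 with 65
  remaining years. The annuity (discrete) form differs only in the
  third significant figure. Deaths at later cycles are additionally
  discounted to model start by `(1+r)^{−t_mid}`.
* **YLD**: state weight × person-time × discount. On-treatment uses the
  active-disease weight (0.288), post-treatment 0.049; each disease
  death adds the terminal weight (0.540) for its cycle. The age-band
  background weight accrues in *all* alive states (background morbidity
  applies to everyone; `background_yld_all_states=False` restricts it
  to post-disease). Background deaths accrue YLL but no terminal weight
  and no end-of-life cost.

## Costs

TZS throughout; USD only at reporting (2595 TZS/USD). Diagnosis costs
fall at time 0, undiscounted. Treatment (stage-specific drug + non-drug
chemotherapy + expected adverse-event cost) is incurred by the whole
branch cohort in the first cycle and discounted at its midpoint
regardless of cycle length (the difference from literal time-0
accounting is <0.6% of the component). Follow-up accrues per alive
patient at the quarterly rate of the year containing the cycle
midpoint — quarters 1–4, 5–8, 9–20, zero after year 5 — counted from
model entry. End-of-life care (166,380 TZS) attaches to each disease
death in its cycle.

Overheads (20%) apply to treatment, adverse events, follow-up and
end-of-life care but **not** to the diagnosis unit costs: treating the
published microcosted unit costs as already fully loaded reconciles the
incremental cost to within ~1%, whereas re-applying overheads to them
overshoots by ~15%. `EconParams.overhead_on_diagnosis=True` restores
the literal "overheads on all medical costs" reading.

Liquid-biopsy unit costs depend on sequencing throughput. Only the
900 samples/year tier (1,308,450 TZS) is published directly; the
300/year tier used for NNT 2–3 (1,558,645 TZS) and the 180/720 tiers
used for 20%/80% availability (2,161,219 / 1,437,378 TZS) are derived
defaults, backed out of the published scenario-table rows and stored
with provenance comments. Off-tier throughputs resolve to the nearest
tier with a logged warning. The 40%/60% availability rows of the
published table are internally inconsistent and were not used.

## Survival estimation

`fit_weibull_ph` maximises the right-censored log-likelihood of the PH
parameterisation directly (L-BFGS-B with analytic gradients; standard
errors from the inverse numerical Hessian at the optimum). The test
suite cross-checks it against an independent route — a Weibull AFT fit
converted to PH (β = −ρ·a, γ = ρ) — and verifies parameter recovery on
simulated cohorts at n ∈ {86, 500-scale, 2000} within three standard
errors, plus the closed-form exponential special case and the 1/√2
standard-error scaling under record duplication.

## Sensitivity analyses

* **One-way**: explicit published ranges for the discount rates
  (3.5–10%, costs and outcomes separately), overheads (15–25%), the
  false-negative probabilities and the pathology-arm stage mix (their
  95% CIs); ±20% for unit costs. The liquid-arm stage mix is explored
  exclusively by its dedicated sweep (0.40–0.80), which is where it
  crosses the 3×GDP threshold — folding it into the tornado would
  contradict the one-way summary that no parameter range does.
* **PSA** (1000 iterations, seeded): proportions and disability weights
  ~ Beta by method of moments; costs ~ Gamma (shape (m/s)², "±20%"
  items use s = 0.2m); survival coefficients ~ independent Normal (no
  covariance is published; correlated draws can be injected by
  replacing `draw_psa_params`). NNT, discount, overheads, availability
  and the life table are fixed. Standard errors for the proportions are
  derived from published 95% CIs (width/3.92) and, for the liquid-arm
  stage mix, from its stated 0.4–0.8 range. Confidence intervals for
  ΔC and ΔE are 2.5/97.5 percentiles of the draws; no interval is put
  on the ICER itself — the CE plane and CEAC carry that uncertainty.
  The CEAC evaluates net benefit on a $0–5000 grid in $10 steps.
* **Scenarios**: NNT 2–6 (throughput-matched unit costs), availability
  20–100% (proportional blend of arm results with throughput-adjusted
  liquid cost), disease-risk window 36/48/60 months (extra deaths carry
  terminal weight and end-of-life cost), false-negative stage
  retention, 1-week cycles, the stage-shift sweep, and parameter hooks
  for rituximab-free or subgroup survival coefficients (those
  coefficients are not published, so the hooks take user-supplied
  `SurvivalParams` and cost overrides).

## Synthetic stand-ins

* **Life table + background weights** (`make_life_table_fixture`): the
  published analysis used GBD Tanzania mortality and eastern-SSA
  background morbidity, which are not reproduced here. The fixture is
  an abridged schedule — infant/child mortality, a low young-adult
  plateau, Gompertz tail `0.003·e^{0.09(a−30)}` — scaled by a single
  root-found factor so e(10) = 65 years, the one anchor treated as
  binding. Background disability weights rise monotonically from 0.035
  (infancy) to 0.29 (95+), shaped like all-cause per-capita YLD rates.
  Packaged as `data/life_table.csv` (a test asserts the CSV equals the
  generator output); any user table with the same columns can replace
  it.
* **Adverse-event table**: defaults to empty — AE costs hit both arms
  and only the stage mix differs, so the incremental effect is
  second-order. A nominal stub exercises the code path.
* **Patient records** (`simulate_patients`): inverse-transform Weibull
  event times by stage, uniform early dropout over 72 months plus
  administrative censoring at 24 — matching the two-year analysis
  window without claiming the study's actual censoring pattern, so
  parameter-recovery tests assert statistical, not numeric, fidelity.

## What the tests do and do not show

With the stand-ins above, the engine reproduces the published headline
results to within a few percent (incremental cost $1977 vs $1978; DALYs
averted 1.17 vs 1.11; ICER $1695 vs $1778; scenario ICERs uniformly
~5% low), and the property backbone — mass conservation to 1e-12,
telescoping survival under cycle refinement, agreement with an
independent scalar-loop re-implementation to 1e-9, seeded PSA
reproducibility — pins the mechanics. What passing does **not** show:
fidelity of the background mortality/morbidity schedule to real GBD
data (only its e(10) anchor is calibrated), adverse-event economics,
treatment abandonment or pre-diagnosis attrition (excluded by design),
or the rituximab-free and Tanzania-only results, which need unpublished
coefficients.

## Numerical choices and problem sizes

Quarterly cycles to age 100 give 368 cycles per branch and at most
eight branches per arm; a full base case runs in ~50 ms and the
1000-iteration PSA in a couple of seconds, so all defaults are run at
full size. Occupancy updates are multiplicative with deaths taken as
differences, making conservation exact to float precision. Degenerate
inputs are handled explicitly: zero-SE parameters are held fixed in the
PSA, draws producing non-positive Weibull shapes are resampled (and
counted), S(t) reaching zero mid-window raises, ages beyond the life
table clamp to the last band with a warning, and a zero DALY difference
yields an infinite-ICER sentinel rather than a division error.
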