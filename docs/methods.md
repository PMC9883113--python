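# Methods

This note documents the model, its parameters and defaults, the numerical
conventions, and the design choices made where the published description of
the decision problem leaves the structure open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Cohort model

Three mutually exclusive states — failure-free survival (FFS), progressive
survival (PS, pooling biochemical recurrence and clinical metastasis), and
death — propagated by per-cycle row-stochastic matrices over a 15-year
horizon. The cohort starts entirely in FFS. Transitions:

| from | to | probability per cycle |
|---|---|---|
| FFS | PS | `1 − S_f(t+1)/S_f(t)` from the FFS→PS Weibull |
| FFS | death | 0.0003 (background, constant) |
| PS | death | `1 − S_p(t+1)/S_p(t)` from the PS→death Weibull |
| death | death | 1 (absorbing) |

Both Weibulls use the rate parameterization `S(t) = exp(−λ t^γ)`; a
conversion helper to the scale parameterization is provided. The per-cycle
exit probability `1 − exp[λ t^γ − λ (t+1)^γ]` is the conditional
probability of the event in `(t, t+1]` given survival to `t`; the product
of per-cycle staying probabilities therefore telescopes exactly to `S(T)`
(asserted to 1e-12 in the tests).

**Cycle length.** Default 1 year (15 cycles). The published model indexes
integer cycles and anchors all survival at annual milestones, so a 1-year
cycle is the smallest structural assumption consistent with it; the setting
accepts any length that divides the horizon evenly (monthly cycles are
tested).

**Competing risks within a cycle.** FFS exits are additive
(`1 − p_prog − p_bg` stays), with clipping and a warning if the sum would
exceed 1. This matches the simple decision-tree structure of the problem;
a cause-specific hazard conversion is deliberately not applied. A
consequence verified in the tests: FFS occupancy equals the exact product
`Π(1 − p_prog,k − p_bg)`, which differs from the multiplicative
approximation `S(k)·(1−p_bg)^k` only at the 1e-4 relative level for these
magnitudes.

**Background mortality.** 0.0003 is read as a per-cycle probability. With
annual cycles, per-cycle and per-annum coincide; for other cycle lengths
the value is applied per cycle as configured (the setting is explicit, so a
user can rescale it when changing the cycle length).

**No tunnel states.** The PS→death clock runs on model time, not time since
PS entry; a 3-state cohort model cannot condition on entry time, and no
tunnel structure is part of the problem definition.

## Survival models

* **Two-point calibration** (`calibrate_weibull`) solves
  `γ = ln(ln S1/ln S2)/ln(t1/t2)`, `λ = −ln S1/t1^γ` exactly, reproducing
  both milestones to machine precision.
* **Curve fitting** (`fit_weibull`) is deterministic least squares on the
  complementary log-log linearization `ln(−ln S) = ln λ + γ ln t` of
  Kaplan–Meier step points, with R² and residual diagnostics. Points with
  survival exactly 0 or 1 (or t = 0) carry no information on that scale and
  are dropped with a warning; fewer than two usable points is an error.
  The linearization is chosen over maximum likelihood because the intended
  inputs are digitized curve points without event counts; it is exact on
  noiseless data and carries a small finite-sample bias (order 1/n,
  measured at roughly one third of the estimator's Monte-Carlo standard
  deviation at n = 500) on sampled curves.

### Fixture calibration

The built-in configuration anchors the FFS→PS model at the trial-reported
5-year failure-free survival of 84 % (identical in both arms). A second
milestone is required for two-point calibration and the trial's long-term
extrapolation values were never published, so the fixture uses an
**illustrative default of S(15) = 0.60** — explicitly not a reported
number, and exposed as an argument of `study_fixture`. The PS→death model
is an exponential (`γ = 1`, the single free scalar) whose rate is solved by
root bracketing so that the modeled cohort's 5-year overall survival equals
the reported 96 % (CRT) / 94 % (UHRT) exactly.

## Valuation

QALYs: `Σ_k df(k) · c · (FFS_k·u_FFS + PS_k·u_PS)` with
`df(k) = (1+r)^(−k·c)`, start-of-cycle occupancy, r = 3 %/year default.
Half-cycle correction (averaging adjacent boundary occupancies) is
available but **off by default**: the original analysis gives no indication
of it and the published worked arithmetic is plain.

Costs (2020 USD): one-time entry charges (radiotherapy course, diagnostic
work-up, urinary-toxicity cost scaled by its 2 %/6 % incidence) plus
discounted per-cycle charges (FFS follow-up, PS care, androgen deprivation
therapy (ADT) for its fixed duration weighted by FFS occupancy).

The published tables itemize unit costs but never print the per-arm cost
composition, so the composition rules are this package's own documented
defaults (all configurable):

* **Radiotherapy course** — shared planning/simulation items (oncologist
  consult, planning CT, mask, body membrane, body frame, real-time
  monitoring, X-ray simulation, treatment planning system) plus
  technique-specific delivery: 39 × the IMRT per-fraction fee for CRT;
  X-knife + image-guided radiotherapy for UHRT with the published
  first-session fee once and the subsequent-session fee × 6 (honouring the
  first/subsequent split in the cost table, whose X-knife/IGRT rows are
  blank for CRT). Transport accrues per fraction (39 vs 7) and
  hospitalization per treatment day (57 vs 16).
* **FFS follow-up** — PSA test, digital rectal exam, routine and
  biochemistry blood panels on a semi-annual schedule (2 visits/year
  default).
* **ADT** — goserelin + bicalutamide monthly for 24 months, charged to FFS
  occupancy.
* **PS care** — monthly supportive treatment plus a configurable drug mix
  (defaults: docetaxel 0.25, abiraterone 0.25, cabazitaxel 0.05 of
  patient-months), 12 × monthly per annual cycle. The original trial
  applied no second/third-line proportions, so this mix is irreducibly a
  modelling choice.
* **Progressive-state utility** — the registry carries both the direct
  `u_ps = 0.61` (mean, 0.49–0.73, beta) and its composition from the
  biochemical-recurrence (0.74) and clinical-metastasis (0.25) utilities
  with back-solved weight `w_br = 0.36/0.49 ≈ 0.7347`. The **direct mode is
  the default** — the published one-way analysis varies U_PS itself — and a
  `composed` mode derives it from the components instead; in direct mode
  the component parameters legitimately show zero tornado spread.

## Sensitivity analysis

* **Ranges.** Printed cost ranges equal base ± 20 % (the stated one-way
  convention) and are transcribed verbatim; utilities and the discount rate
  (0–8 %) use their printed ranges.
* **Distributions.** Beta for utilities/discount rate, gamma for costs, by
  method of moments with `SE = (high − low)/3.92` (range read as a central
  95 % interval — the dominant convention when only mean and range are
  printed; the divisor is configurable, with 4 and 2√3 as the usual
  alternatives). Construction happens before any sampling, so infeasible
  moments fail fast. Beta draws are clipped to [0, 1] — a no-op for exact
  beta sampling, retained as a guard because two utility ranges print 1 as
  their upper bound. Draws are truncated at [0, 1] only, not at the printed
  ranges.
* **PSA.** Each draw samples every distributed parameter once and applies
  it to both arms (shared unit costs, u_PS and the discount rate are
  thereby correlated across arms; the arm-specific toxicity-inclusive FFS
  utilities are separate parameters and hence independent). The survival
  dynamics are structural, not sampled, so the cohort traces are computed
  once and reused across draws; the valuation layer is re-run in full per
  draw. Default 1,000 draws, always seeded.
* **CEAC.** Probability that the reference arm has the higher net monetary
  benefit at each willingness-to-pay value; exact ties count 0.5 (unbiased
  under exchangeability; the convention is documented because the source
  analysis is silent).
* **Threshold search.** Plain bisection on the sign of the incremental net
  monetary benefit to an interval below 1e-6 in the knob's units; a
  constant sign is reported as a no-crossover result, not an exception.
  Because NMB is linear in WTP at fixed increments, the WTP crossover
  equals the deterministic ICER exactly (asserted to 1e-6).

## Synthetic data

`simulate_event_times` draws Weibull event times by inverse transform
(`T = (−ln U/λ)^{1/γ}`), applies independent exponential censoring
(default hazard 0.05/year — mild loss-to-follow-up typical of a
radiotherapy trial population) and administrative censoring at 15 years,
and `km_from_times` summarizes the cohort by the product-limit estimator
(lifelines). This emulates exactly the statistical structure the fitting
stage assumes: a noisy, right-censored step estimate of a true Weibull
curve. It does **not** emulate curve-digitization error (pixel quantization,
operator tracing), informative censoring, or covariate-driven
heterogeneity — so passing recovery tests demonstrate correctness of the
estimation pipeline under its own assumptions, not robustness to real
digitized-figure artefacts.

## Problem sizes and numerical conventions

The test and acceptance workloads use: 50,000 individuals for the
microsimulation cross-check (3 binomial-SE agreement per cycle and state),
200 replicates at n = 500 for pipeline parameter recovery (agreement
within 3 Monte-Carlo SDs of the estimator, with the replicate ensemble
estimating that SD), 5,000 draws for PSA mean checks and 1,000 for the
acceptability curve. Telescoping and conservation identities are asserted
at 1e-12 absolute; calibration plug-backs at 1e-9 or better. All
randomness flows through `numpy.random.default_rng` with explicit seeds.

Degenerate inputs are defined behaviour: λ = 0 is a valid no-event model;
zero-width parameter ranges degrade to point masses in both DSA and PSA;
equal-effectiveness comparisons return an undefined ICER with an explicit
flag rather than a division error; dominance (cheaper **and** more
effective) is flagged and never reported as a bare ratio.

## Known limitations

* The published headline outcomes (2.32 vs 2.14 QALYs; $34,411.85 vs
  $30,160.81; PSA acceptability 57.7 %) are **not** quantitatively
  reproduced: the original fitted Weibull parameters, cycle length, and
  per-arm cost composition were never printed, and the 15-year QALY totals
  imply occupancy or utility handling that cannot be derived from the
  printed inputs. The fixture reproduces the decision structure (UHRT
  cheaper, CRT more effective, crossover at the model's own ICER) rather
  than the absolute levels.
* Background mortality is age-independent; no life-table integration.
* Two arms only; no efficiency frontier over >2 strategies, no value-of-
  information analysis, no parameter correlation beyond the shared-draw
  structure.
* Currency handling is a single scalar; no inflation indexing.
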