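# Methods

This note documents the models implemented in `mcrc_cea`, their assumptions,
the default parameters and the numerical choices, in the package's own
words.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic trial emulator

The analysis is anchored to a two-arm first-line mCRC trial of adoptive
cellular immunotherapy (ACI) + XELOX/bevacizumab vs XELOX/bevacizumab for
which only summary statistics are public: median PFS 14.8 vs 9.9 months
(HR 0.60), control median OS 25.6 months (HR 0.57) with the ACI OS median
not reached, grade ≥3 AE incidence 20.0% vs 23.5%, subsequent-therapy uptake
56.0% vs 64.7%, and arm sizes 100/102.  The emulator generates pseudo-IPD
with exactly this structure.

**Survival law.** Weibull proportional hazards: control
S_c(t) = exp(−(t/λ)^k), treatment S_c(t)^HR.  An exponential law cannot
satisfy both printed medians together with the hazard ratio (under
exponential PH the median ratio must equal 1/HR, and 14.8/9.9 ≠ 1/0.60), so
the shape is calibrated in closed form from the PFS medians and HR:

    k = ln(1/HR) / ln(m_t/m_c) ≈ 1.2704,   λ = m_c / (ln 2)^{1/k} ≈ 13.21 mo.

Both medians are recovered from the calibrated law to 1e−9 relative error
(tested).  **OS shape:** the ACI OS median is not reached, so OS admits no
two-median calibration; the OS law reuses the PFS shape with its scale
solved from the control OS median (λ_OS ≈ 34.16 mo).  Any shape would
reproduce the control median; sharing the PFS shape keeps the two endpoints
on a common hazard geometry and, combined with the follow-up assumption
below, leaves the ACI OS median unobserved at trial scale.

**Censoring.** Uniform-accrual administrative censoring,
C = max_followup − U(0, accrual_window), defaults 36 and 18 months.  The
trial's actual follow-up is unreported; the defaults are chosen so the
control OS median is observable while the ACI OS median typically is not.
This assumption is flagged in the config (`trial.censoring.assumed`).

**Units.** Months throughout the statistical layer; conversion to 21-day
cycles happens only in the cohort model (1 cycle = 21/30.4375 months).

## Pseudo-IPD reconstruction

`km.guyot_reconstruct` recovers event/censoring times from digitized
survival coordinates plus a numbers-at-risk table.  Between consecutive
risk-table times, an integer censoring count is adjusted iteratively
(Newton-style on the at-risk mismatch, then a feasibility scan) until
stepping the cohort through the digitized curve — events at each coordinate
estimated from the product-limit ratio and rounded — reproduces the
published number at risk.  On small intervals (≤ 15 at risk, ≤ 6
coordinates) an exact integer search refines the allocation to the minimum
achievable survival deviation, so that small instances provably attain the
optimum (tested against an independent exhaustive-search oracle).
Censoring times are spread uniformly in time within each interval.  No
published total event count is available for this trial, so the final
interval assumes no within-interval censoring and the residual cohort is
censored at the end of follow-up.

**Event placement.** Classic reconstruction places events at the digitized
coordinate times, which is correct when the digitization clicks sit on the
step corners.  When the coordinates are *uniform samples* of the step
function (as produced by `trial.emit_digitized_km`), a drop observed at
coordinate t_i actually occurred somewhere in (t_{i−1}, t_i]; placing all
events at t_i biases every reconstructed time rightward by about half a grid
step.  `event_placement="midgap"` places events at the gap midpoint instead,
removing that bias; corner-digitized inputs are unaffected by the option.
Reconstructed times are emitted with 4-decimal precision; the diagnostic
records the maximum absolute deviation between the reconstructed KM curve
and the input coordinates.  Note that a single 25-point digitization grid
quantizes any recovered quantile to roughly half a grid step (~0.75 months
over a 36-month axis), which bounds the attainable per-replicate median
accuracy; round-trip accuracy is therefore assessed over a battery of
replicates in the tests.

## Parametric survival models

Seven families are fitted by right-censored maximum likelihood through a
uniform interface (log-density + log-survival + parameter transform):
exponential, Weibull, Gompertz (positive shape), gamma, log-logistic,
log-normal, generalized gamma.  The generalized gamma uses the (μ, σ, Q)
parameterization with the |Q| < 1e−4 region evaluated by its log-normal
limit; Q = 1 reduces to the Weibull and both reductions are tested.
Optimization is multi-start (3 starts) L-BFGS on log-transformed positive
parameters with moment-based initial values; non-convergent fits are
reported and excluded from ranking.  Spline and fractional-polynomial
families are deliberately out of scope — their knot configurations are not
reproducible from the available information — but the family table accepts
plug-ins with the same interface.

Ranking is deterministic: AIC ascending, near-ties (ΔAIC < 2) broken by BIC,
residual ties by family name.  Visual inspection is out of automated scope;
`plots.km_overlay` exports the overlay for human review.  A fitted PFS/OS
pair must pass `screen_pair` (S_OS ≥ S_PFS − 1e−9 on the cycle grid) before
entering the cohort model.

## Cohort model

Three states — progression-free (PFS), progressive disease (PD), death — on
21-day cycles.  Default horizon 20 years → ceil(20 × 365.25/21) = 348
cycles.  (A published description of this model type mentions 374 cycles
together with a 20-year horizon; 374 × 21 d ≈ 21.5 y, so the two are
inconsistent.  The horizon is taken as authoritative and 374 is available
via `ModelSettings(n_cycles_override=374)`.)

Occupancy is the partitioned-survival identity evaluated at cycle
boundaries; the equivalent Markov chain sets p(exit PFS) and the overall
death probability from conditional survival ratios, allocates PFS exits to
death at the overall hazard (the remainder to PD), and solves PD→death each
cycle so cohort deaths track 1 − S_OS exactly.  No allocation rule for
competing exits within a cycle is identifiable from curve data alone; this
choice makes the chain reproduce the partitioned trace identically
(agreement ≤ 1e−6 is asserted, observed ~1e−13), and any residual
S_OS < S_PFS crossings are clamped and counted.  The partitioned path is the
base-case engine; the matrix path drives the cross-validation grid.

Discounting: 5% annual (guideline range 0–8%, enforced), applied per cycle
as (1.05)^(−21/365.25) ≈ 0.99720, so a year of cycles compounds to exactly
1/1.05.  No half-cycle correction by default — the simplest reproducible
reading — with `half_cycle_correction=True` averaging start/end occupancy.

## Economics

Per-cycle values at full occupancy:

* **PFS, cycles 1–6 (induction):** bevacizumab 7.5 mg/kg d1 + oxaliplatin
  130 mg/m² d1 + capecitabine 1,000 mg/m² twice daily d1–14 (28
  administrations/cycle, the standard XELOX reading of a 1,000 mg/m² dose;
  exposed as `doses_per_cycle`), plus the ACI infusion price (default
  $6,819.45/cycle) in the immunotherapy arm.
* **PFS, cycle 7+:** maintenance bevacizumab + capecitabine.
* **Cycle 1 additionally:** expected AE management cost Σ incidence × cost
  and a QALY decrement Σ incidence × disutility × duration (days/365.25) —
  AE burdens are front-loaded into the first cycle.
* **PD:** best supportive care + follow-up per cycle; a one-off
  subsequent-therapy cost on PD entry weighted by the uptake probability
  (0.560/0.647); regimen durations are unreported, so the lump-sum form is
  the default.
* **Death:** terminal-care cost charged once per incremental death.

Utilities: u_PFS arm-specific (0.82 ACI / 0.80 control — arm-specific
because on-treatment utility plausibly differs and the sensitivity analysis
treats them separately), u_PD = 0.58; one cycle contributes
u × 21/365.25 QALYs.  Body surface area is a config input (1.79 m²) rather
than recomputed from 165 cm/65 kg, since no standard BSA formula yields 1.79
from those measurements.  Only direct medical costs are modelled.

**Default parameter provenance.** The source analysis's unit costs and
utilities live in supplementary material that is not publicly available.
The shipped defaults (`config.default_econ_params`) are a plausible set at
Chinese-market magnitudes: post-negotiation biosimilar/generic drug prices
($/mg — bevacizumab 0.45, oxaliplatin 0.85, capecitabine 0.002), four
grade ≥3 AEs (anemia, neutropenia, leukopenia, thrombocytopenia) whose
per-arm incidences sum to the trial's overall 20.0%/23.5%, BSC $400 and
follow-up $150 per cycle, subsequent therapy $8,000, terminal care $2,000,
and the published mCRC utility range.  They were chosen once, are fully
overridable via YAML, and all tests that touch them are property-based
(orderings, invariances, memberships), never value-matching.

## Sensitivity analyses

OWSA: ±25% default bands; AE, BSC and terminal-care costs get ±30% ("higher
uncertainty" — no per-parameter assignment is derivable, so the wider band
goes to the care-cost items, overridable); discount rate spans 0–8%.  Each
row is exactly two full model evaluations; rows are sorted by ICER range.

PSA: 1,000 seeded Monte Carlo iterations; costs ~ gamma, utilities and
probabilities ~ beta, moment-matched from (mean, sd) with the beta
feasibility check sd² < mean(1 − mean).  Dispersions are unreported, so
sd = (high − low)/(2 × 1.96) ties the PSA spread to the OWSA bounds — one
coherent uncertainty description.  Survival-curve parameters are *not*
sampled (only cost/probability/utility distributions are described for this
analysis type); curve uncertainty is addressed by the cross-validation grid.
The CEAC is computed by counting, and with distributions centred on base
values the acceptability at a WTP equal to the base-case ICER sits near 50%
(asserted as a 20–80% band).

## Price inversion

Incremental cost is affine in the ACI per-cycle price with slope equal to
the discounted PFS occupancy over the six induction cycles; incremental
QALYs are price-free.  The maximum price satisfying ICER ≤ WTP is therefore
closed-form, p* = (WTP·ΔE − ΔC₀)/slope floored at 0; the iterative
"re-run until ICER meets WTP" procedure is retained as a bisection
cross-check and must agree to $0.01.  WTP thresholds are multiples 1.5,
1.94 and 3 of per-capita GDP ($12,240.62), stored once and derived to avoid
rounding drift ($18,360.93 / $23,746.80 / $36,721.86 per QALY).

## Scenarios

Horizons 10/15/20 years re-run the full base case with everything else
fixed; because the immunotherapy arm's incremental QALYs accrue late while
its incremental costs are front-loaded, the ICER declines as the horizon
grows (asserted).  The cross-validation grid evaluates every screened
control × treatment curve-set pair through the transition-matrix path and
reports the ICER distribution and the cost-effective fraction at the WTP.
The published screening that produced 72 control and 34 treatment
combinations is not derivable from the available information, so
`make_crossval_fixture` anchors the 72 × 34 = 2,448 shape with a
deterministic grid of Weibull-parameter perturbations (±10% shape, ±8%
scale on PFS; OS at the calibrated law) — a synthetic stand-in for the
screened fit sets, which the grid operation equally accepts from real fits.

## What the synthetic data do and do not show

The emulator reproduces the published survival structure (medians, hazard
ratios, proportional hazards, administrative censoring) and makes every
pipeline stage testable end to end.  It does not reproduce: non-proportional
hazards, per-patient covariates, informative censoring, digitization noise
(coordinates are exact step-function samples; the isotonic preprocessing
that would absorb noise is tested separately), or the source analysis's
actual cost/utility inputs.  Passing tests therefore demonstrate
correctness of the machinery and calibration — not agreement with any
particular published monetary result.

## Problem sizes

Defaults used by the test and acceptance runs, chosen as routine desk-scale
sizes for this kind of analysis: 200,000 subjects per arm for median
calibration; 50,000 per arm for the Cox hazard-ratio recovery; 102-subject
round trips (trial scale) over a 10-seed battery; 1,000 PSA iterations; the
full 2,448-pair cross-validation grid at 348 cycles.
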