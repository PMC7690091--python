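# Methods

## The decision problem

Relapsed/refractory peripheral T-cell lymphoma (R/R PTCL) has no standard
salvage therapy; pralatrexate monotherapy showed a median overall survival
(OS) of 15.24 months against 4.07 months under conventional chemotherapy
(CC) in a propensity-matched historical comparison of 80 patients per arm.
The package estimates the incremental cost per life-year (LY) and per
quality-adjusted life-year (QALY) of pralatrexate from a societal
perspective over a 15-year horizon, with all costs in 2019 US dollars.

## Survival evidence and its synthetic stand-in

The comparative OS evidence exists publicly only as Kaplan–Meier figures.
The standard workflow — digitize the curves, reconstruct pseudo individual
patient data (IPD), fit parametric models, extrapolate — is implemented in
full, and a synthetic-evidence module replaces the unavailable figures.

`synthetic_data.generate_ipd` draws event times from a named parametric
family, applies per-subject uniform random censoring with probability
`censor_rate` (default 0.2) over the follow-up window and administrative
censoring at `max_followup` (default ≈ 226 weeks, the ~52-month follow-up
of the source comparison). The truths are calibrated so their medians equal
the published ones, using the month↔week conversion
1 month = 365.25/12/7 ≈ 4.3482 weeks (15.24 mo → 66.27 wk, 4.07 mo →
17.70 wk); the conversion is itself a convention the source never states.
Truth shapes are fixed at generalized gamma (σ = 1, Q = 1) for the
pralatrexate-like arm and Gompertz (shape 0.05/week) for the comparator,
with the free scale solved from the target median in closed form.

`digitize_emulate` samples the exact KM step function at every drop time
plus a 1-week grid, optionally adds Gaussian extraction noise
(default σ = 0.005 survival units, a plausible hand-digitization error),
then restores validity by a monotone non-increasing clip and a [0, 1]
clamp. A numbers-at-risk table (subjects with observed time ≥ t at each
sampled time) can be attached.

Features of real digitized evidence that the generator does **not**
emulate: axis-calibration bias, unreadable plateau tails, censoring tick
marks, and the particular censoring pattern of the source study. Passing
tests therefore demonstrate correctness of the machinery under known
truth, not fidelity to the unpublished source curves.

The life table is an explicitly stylized Gompertz–Makeham construction
(annual hazard A + B·e^{C·age}, defaults A = 5e−4, B = 3e−5, C = 0.09,
converted to weekly probabilities via 1 − (1 − p_year)^{1/52.1}). Its
values are configuration of plausible high-income-country magnitude, not a
reproduction of the Korean national table used by the source analysis.

## Pseudo-IPD reconstruction

`reconstruct_ipd` inverts digitized coordinates under the product-limit
identity. At each coordinate drop, the integer event count d minimizing
|S_model − S_target| is round(n·(1 − S_target/S_model)) — exact because
the reconstructed survival is linear in d. With a risk table, the
censoring count per risk interval is the drop in numbers at risk net of
allocated events (negative counts raise an infeasibility error naming the
interval), and censorings are placed after the interval's last event,
which leaves the KM estimate at every drop time unchanged. Without a risk
table — the default, since the availability of at-risk rows to the
original reconstruction is unknown — no censoring is assumed before the
last coordinate, where every remaining subject is censored. Events plus
censorings always equal the arm's total n. Ties follow the standard KM
convention (events before censorings), on which the reconstruction
ordering depends.

Validation statistics use lifelines: KM estimation, the Cox
partial-likelihood hazard ratio with Breslow tie handling and Wald CI, and
the Grambsch–Therneau scaled-Schoenfeld test (rank time transform) whose
rejection motivates fitting each arm separately rather than through a
proportional-hazards model. Undefined medians (curves never reaching 0.5)
are returned as an explicit `None`, never a sentinel value.

## Parametric fitting and extrapolation

The right-censored log-likelihood Σ[event·log f(t) + (1−event)·log S(t)]
is maximized per family. The exponential rate has the closed form
events/exposure; the other families use a Nelder–Mead simplex from
moment-based starts followed by an L-BFGS-B polish (tolerance 1e−8 on the
log-likelihood). The generalized gamma uses the Prentice (μ, σ, Q)
parameterization — numerically stable and nesting Weibull, lognormal and
gamma — with a multi-start over Q ∈ {−1, 0.05, 1} against its flat
likelihood surface; |Q| < 1e−6 is evaluated as the lognormal limit. The
Gompertz shape may be negative, giving a defective (plateau) curve — a
plausible long-survivor tail — in which case the median may be undefined
(reported as infinity by `distributions.median`).

AIC = 2k − 2ℓ and BIC = k·ln n − 2ℓ with k the free-parameter count.
Selection takes the minimum criterion, breaking ties toward fewer
parameters; a visual override names an explicit family and is recorded in
the fit metadata. The base case uses the published visual-inspection
choices: generalized gamma (pralatrexate), Gompertz (comparator).

Weekly transition-to-death probabilities are p_w = 1 − S(w+1)/S(w),
clipped to [0, 1]; an exhausted curve (S = 0) yields p = 1 with a warning.
These satisfy the telescoping identity Π(1 − p_t) = S(T) exactly.

## Markov cohort model

States: initial treatment (weeks 1–14), treatment pause (15–22 and 36+),
subsequent treatment (23–35), SCT success, death; the three treatment
states nest CR/PR/SD/PD response compartments. Both arms share the
timeline skeleton (two 7-week pralatrexate cycles ≈ 4.67 three-week CC
cycles ≈ 14 weeks; 4.33 three-week cycles ≈ 13 weeks). The cohort enters
at age 48, split by the arm's initial response rates; pause composition is
frozen at the feeding phase's split. At week 20, fraction 0.529 of the
surviving CR+PR mass is transplanted and 0.663 of those succeed and move
to SCT success; CR remainders stay in pause permanently, PR remainders
and SD/PD proceed to subsequent treatment at week 23, re-splitting by the
post-subsequent response rates on entry to the second pause (week 36),
where a second transplant (probability 0.458, same success rate) occurs at
week 42. Horizon: 782 weekly cycles (365/7 × 15, truncated to a whole
cycle; 10- and 30-year variants use 521 and 1564 cycles).

Numerical and structural choices:

* The arm-level OS hazard applies uniformly to every living
  non-transplanted compartment (no response-specific mortality is
  published). Consequently model OS slightly exceeds the input curve,
  because SCT successes switch to the lighter general-population
  life-table hazard — a structural consequence of the "SCT success =
  general population" assumption, not a bug.
* Within-cycle order: death, then transplant transfer, then the phase
  transition at the cycle boundary — transplant candidates must survive
  the transplant week.
* Transplant failures carry no excess mortality; they remain in (or
  proceed from) their response compartment under arm mortality.
* PR patients failing the week-20 transplant are held in the first pause
  until the week-23 transition (the 2-week gap's state label is not
  specified by the source; pause is the conservative reading).
* No half-cycle correction; costs and utilities accrue on start-of-cycle
  occupancy. Mass conservation is asserted every cycle at 1e−9 and tested
  at 1e−12.
* Cohort age advances 1/52.1 years per week from 48; the life table and
  utility bands are looked up at the floored integer age.

## Costs, effects, discounting

Seven cost categories: initial/subsequent medication, concomitant drugs,
monitoring (each with first-cycle/other-cycle weekly variants — e.g.
pralatrexate concomitant $4/week during cycle 1, $3/week during cycle 2;
monitoring $106 then $17), adverse-event (AE) treatment, and the one-off
transplant cost ($27,343, charged to every transplanted patient, success
or failure, at weeks 20/42). Comparator weekly aggregates are taken as
printed; a provenance helper recomputes regimen-mix weighted means
(DHAP/ESHAP/ICE, plus BSC subsequently) when per-regimen costs are
supplied, but the base case does not use it. No cost is attached to pause
states (the source reports none).

AE probabilities are interpreted as **per-week** probabilities during
treatment-phase weeks. This is the single most consequential
under-specification in the source: a per-course reading yields AE costs
roughly fifty times smaller than the published category totals, while the
weekly reading reproduces their magnitude (CC initial phase:
$794.53/week expected × 14 weeks ≈ $11.1k before mortality weighting,
against a published $10.6k). The interpretation is a config switch
(`per_week` | `per_cycle` | `per_course`) with `per_week` as base case,
and a structural order-of-magnitude test documents the rationale.

Effects: LY = alive mass × 1/52.1 per cycle; QALYs weight compartments by
utility (CR 0.885, PR 0.784, SD 0.746, PD 0.567; SCT success by age band
0.976/0.971/0.966/0.936, clamped to the outer bands beyond 45–64) and
subtract the expected AE disutility (Σ prob × disutility) from
treatment-phase occupants, flooring at zero. Discounting is continuous in
weeks, (1.05)^(−week/52.1), applied from the start-of-cycle week; an
annual-step convention is available and differs by < 0.3% over 15 years.
ICERs are Δcost/Δeffect; zero effect differences yield explicit
undefined flags and dominance is reported when sign patterns warrant.

## Sensitivity analysis

One-way scenarios: (1) extrapolation-family swap — the full cartesian
grid of converged families per arm, reporting the extreme ICERs; (2–5)
each response-state utility at 95% CI bounds (the source CIs are not
printed, so bounds are config, defaulting to ±10% capped at 1.0 and
labelled non-reproducible); (6) SCT success 0.663 ± 10%; (7) comparator
dose −20% applied to CC medication costs wherever CC is given (comparator
initial phase and both arms' subsequent phases); (8) horizon 10 and
30 years. Runs never mutate the base configuration (verified bit-for-bit),
every perturbed value is logged in a provenance column, and a failing
scenario is recorded without aborting the batch. Tornado ordering sorts by
|ICER_high − ICER_low| with stable ties.

On the synthetic evidence the family-swap bar is consistently narrower
than the horizon bar: truths calibrated only to a median are close to
exponential, so all six fitted families nearly agree in the tail, unlike
the published curves whose heavy pralatrexate tail made the extrapolation
family the dominant uncertainty. This divergence is expected and
documented; it reflects the synthetic conditions, not the sensitivity
machinery.

## Problem sizes and determinism

Simulated checks use n = 80 (trial scale) for round-trip calibration
(averaged over small seeded replicate sets; a single n = 80 median has
~10–13% sampling sd), n = 2000 for large-sample recovery and model
selection (50 replicates for the AIC family-recovery rate), n = 5000 for
parameter-recovery bias, and 40 replicates at n = 300/arm for the PH-test
size/power simulations. All randomness flows through
`numpy.random.default_rng` seeds carried in the spec/config objects; one
root seed derives every substream, and identical seeds reproduce outputs
byte-for-byte.

## Known limitations

* Synthetic truths match the published medians but not the unpublished
  curve shapes, so absolute cost/QALY totals differ from the published
  base case; arithmetic identities among the published totals, round-trip
  calibration, structural invariants and directional results are what the
  suite verifies.
* Sub-year transplant failures, response migration outside the two
  re-split events, re-treatment after week 42, competing risks and
  probabilistic sensitivity analysis are out of scope.
* The printed AIC/BIC pair for the source fits (AIC > BIC at n = 80,
  k = 3) is inconsistent with the standard definitions used here; those
  printed values are treated as non-reproducible.
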