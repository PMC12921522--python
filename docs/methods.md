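# Methods

## The decision problem

`lupus_cea` implements a cost-utility analysis comparing two timing
strategies for intravenous belimumab in biologic-naive adults with
clinically active systemic lupus erythematosus (SLEDAI-2K > 0): *early*
initiation (within two years of diagnosis) versus *delayed* initiation
(after failure of standard immunosuppressants).  The analysis takes a US
payer perspective, values costs in 2024 USD, discounts costs and health
effects at 3% per year, and judges cost-effectiveness at a willingness-to-pay
(WTP) of $50,000 per QALY via the incremental net monetary benefit,
INMB = ΔQALY·WTP − ΔCost.  Early initiation with lower cost and higher
QALYs is *dominant*.

## Model structure

A Markov cohort model with monthly cycles over a 15-year base-case horizon.
Six reported health states: pretreatment, complete response (SRI-4),
partial response, nonresponse, no treatment, and death (absorbing).
Because a memoryless six-state chain cannot remember which biologic a
patient is on after a switch, the engine expands the internal state space
to health state × drug context (belimumab / anifrolumab / off treatment)
— ten internal sub-states — and collapses back to six for reporting.

Pathways: the whole cohort starts in pretreatment on belimumab, stays
there for the 4-month induction (subject only to death), then splits into
the three response states.  Responses move stepwise and bidirectionally
(complete ↔ partial ↔ nonresponse).  Nonresponders discontinue at a
monthly rate, splitting among restart (re-enter pretreatment), stop
(no-treatment state), and switch to anifrolumab.  Off-treatment patients
who suffer a severe flare initiate anifrolumab.  Anifrolumab carries its
own induction (geometric exit with mean equal to the induction length,
since switchers arrive at staggered times) and response split, attenuated
for biologic-experienced patients.

The two arms run on an identical parameter set and differ only through
(i) the early-initiation SRI-4 odds ratio, applied on the odds scale to
the complete-response induction probability (the partial probability is
rescaled to preserve the partial:non ratio among non-complete responders),
and (ii) a +10 mg/day baseline prednisone offset carried by the early
arm's pretreatment state.  With the OR forced to 1 and the offset to 0 the
arms are bitwise identical — a tested invariant that rules out hidden
code-path differences.

### Competing risks and cycle conventions

Mortality is applied first each cycle from every living state; the
remaining probability mass follows the disease transitions rescaled
proportionally.  The monthly death probability blends female and male
annual life-table hazards (−ln(1−qx), whole-year age lookup) at the
cohort's 91.2% female mix, after inflating each sex's hazard by an age-band
(< 40 / ≥ 40 years) standardized mortality ratio.  QALYs and costs are
credited with the state occupied at the beginning of each cycle; a
half-cycle correction (averaging adjacent occupancy rows) exists as a
settings flag and is off by default.  Annual probabilities convert to
monthly ones by the constant-hazard rule 1 − (1−p)^(1/12).

## Utilities and costs

State utilities are EQ-5D values parameterised as a complete-response
level plus ordered decrements (complete → partial → nonresponse), so the
ordering nonresponse ≤ partial ≤ complete survives any probabilistic draw.
A shared piecewise-constant time trend (anchored at model years) scales
all states.  A glucocorticoid disutility of 0.005 per mg/day of
prednisone-equivalent dose is subtracted, using state-specific doses and a
reference dose of zero (i.e., the decrement applies to the absolute dose;
an alternative reading applies it to cycle-over-cycle dose *changes* — we
use the level form, which penalises sustained exposure, and note that the
difference only shifts utility levels shared by both arms).  Utilities are
clamped to the EQ-5D range [−0.594, 1].

Costs per cycle combine drug acquisition and state-stratified secondary
costs (hospitalisations, outpatient care, emergency visits), the latter
parameterised as a complete-response level plus ordered increments.
Belimumab is dosed at 10 mg/kg rounded up to whole 400 mg vials (wastage,
no sharing) at the wholesale acquisition cost per vial; the every-4-weeks
schedule maps to 13/12 infusions per monthly cycle on average, with the
extra week-2 loading dose added to the first induction month.  Anifrolumab
is a fixed 300 mg dose per 4 weeks, same mapping, equal secondary costs
(no anifrolumab-specific claims data exist).  Off-treatment and dead
patients accrue no drug cost.  Infusion-visit fees are assumed inside the
claims-derived secondary costs.  Patient weight (default 70 kg) is a
ledger parameter varied in sensitivity analysis because per-vial pricing
needs a dose in mg.

## The parameter ledger

Every numeric input lives in a validated ledger of named entries carrying
base value, one-way range, distribution, units, optional time profile, and
provenance.  Distribution families follow the standard assignment: beta
for probabilities and utilities, log-normal for costs and ratio-type
parameters (odds ratios, SMRs), normal for continuous clinical parameters;
design constants are `fixed`.  Beta and log-normal specs are derived from
reported mean/SE by moment matching (beta: k = m(1−m)/se² − 1; log-normal:
σ² = ln(1+se²/m²), μ = ln m − σ²/2), with round trips exact to 1e-10.
When no published range exists the one-way range defaults to ±30% on the
natural scale, clipped to the parameter's support.  Parameters are sampled
independently (no correlation structure is modeled — an explicit
assumption); probability draws that escape [0,1] through floating-point
effects are clipped and *counted*, never silently accepted.

## Synthetic inputs and calibration

The study's supplementary parameter table is not available, so the package
generates a stand-in:

- **Life table** — Gompertz–Makeham hazards per sex
  (qx = 1 − exp(−(A + B·e^(γ·age))), female A=1.8e-4, B=2.0e-5;
  male A=3.0e-4, B=3.2e-5; γ=0.093), covering ages 0–100 with female
  mortality below male at all adult ages.  A loader for a real
  age/sex/qx CSV is provided.
- **Default ledger** — every engine-required name with plausible synthetic
  magnitudes.  Values printed in the article's main text are entered
  exactly and labelled as such: the 0.005/mg decrement, 3% discount rate,
  $50,000/QALY WTP, 4-month induction, start age 41, 91.2% female,
  +10 mg/day early prednisone offset, SRI-4 OR range 1.08–3.47 (base value
  1.94, the geometric mid of that range, with log-scale SD 0.298 from
  reading the range as a 95% CI), and the 15%/60% biosimilar discounts.
- **Calibration** — four free parameters (delayed-arm complete-response
  probability, nonresponse secondary-cost increment, complete-response
  utility level, drug-cost scalar; each dominantly steering one target)
  are fitted to the four published base-case totals: early
  $1,910,438.61 / 7.68 QALYs, delayed $2,036,775.73 / 7.38 QALYs.  The
  objective is the sum of squared *relative* residuals (so ~10⁶-dollar and
  ~10⁰-QALY targets weigh equally), minimised by bounded Powell search —
  derivative-free, deterministic from the ledger's base values.  The
  shipped defaults sit at the calibrated solution, so re-running the
  calibration verifies the targets and returns after zero improving steps;
  from a perturbed start the same routine recovers them (tested).
  Calibrated values always respect their declared bounds.

The calibrated ledger reproduces the printed totals to ~1e-10 relative,
hence ΔC = −$126,337.12, ΔQ = 0.30, ICER = −$421,123.73/QALY and
INMB = $141,337.12 at $50,000/QALY, with early initiation dominant.  It is
a stand-in that reproduces published *aggregate outputs*; it does not claim
to recover the study's true inputs.

## Sensitivity and scenario analyses

- **PSA** — Monte Carlo propagation (default 10,000 simulations) with one
  shared parameter draw applied to both arms per simulation (independent
  draws per arm would inflate incremental variance and contradict the
  paired design).  A master seed spawns one substream per draw
  (`numpy.random.SeedSequence`), so results are reproducible and
  independent of evaluation order.  95% uncertainty intervals are the
  2.5th/97.5th empirical percentiles with linear interpolation between
  order statistics (the numpy `linear` definition).  CEAC ties (INMB
  exactly 0) split 0.5/0.5.
- **One-way DSA** — full model re-runs at each parameter's bounds, INMB at
  the settings WTP; tornado entries sorted by descending bar width with
  name-stable ties.  The discount rate and time horizon are routed through
  the analysis settings under reserved parameter names; the horizon's DSA
  bounds are 1–25 years.
- **Horizon sweep** — one deterministic run per horizon, each with its own
  discounted totals.
- **Scenarios** — a lifetime horizon (run to the life table's end at age
  100) and biosimilar pricing: substitution at 15%/60% WAC discounts with
  equal efficacy, and market entry at years 1 and 5 applying a synthetic
  price-erosion multiplier (default 0.75; the underlying US erosion
  estimates are not printed in the main text) to both biologics from the
  entry year onward.  Scenario runs scale only drug-acquisition unit
  costs; efficacy, utility and secondary-cost parameters are untouched
  (asserted by test).

## What the synthetic conditions do and do not show

Passing tests demonstrate that the model mechanics are correct (matrix
row-stochasticity to 1e-10, cohort conservation to 1e-9 over 180 cycles,
monotone death occupancy, matrix-power equivalence to 1e-12, exact paired
null contrast) and that the calibrated ledger reproduces the published
base case and directional sensitivity patterns: INMB non-decreasing over
horizons 1→25 (the calibrated run gives ≈$12k at 1 year, ≈$74k at 5,
≈$141k at 15, ≈$156k at 25), higher SRI-4 OR ⇒ higher INMB, deeper WAC
discount ⇒ higher INMB.  They do *not* reproduce the published dispersion
results — the 65.3% southeast-quadrant share, 81.3% of simulations
favouring early initiation, or the published UI widths — because those
depend on per-parameter dispersion inputs available only in the
unavailable supplementary table; the synthetic distributions are narrower,
so the PSA concentrates more strongly in the southeast quadrant.  The
published tornado's exact endpoint values are likewise not asserted, only
their directions.  One documented direction difference: this model's INMB
*decreases* with the discount rate (both increments accrue late, so
discounting shrinks them), while the published analysis reports a higher
INMB at 5% — reproducing that sign would require front-loaded incremental
savings that the main text does not characterise.

## Numerical choices and degenerate inputs

Transition matrices are piecewise-constant over (whole-year age, time-
profile year, induction phase), so a 180-cycle run builds ~20 distinct
matrices; a 10,000-draw PSA completes in about a minute on one CPU.  Rows
failing non-negativity, unit sums (1e-10), or pre-death sums above 1 raise
errors naming the offending row.  A zero-cycle horizon yields a single
all-pretreatment trace row.  Time profiles are piecewise-constant between
anchors (no interpolation; anchors are reported at discrete follow-up
years).  Unit odds ratios short-circuit to the identity so the null
contrast is exact to the bit.  All machine outputs serialize at full
precision; rounding appears only in human-readable tables.

## Known limitations

No organ-damage state (damage is captured indirectly through prednisone
trajectories and the dose disutility); no microsimulation mode; no
indirect/productivity costs; no parameter correlation in the PSA; no
treatment discontinuation for sustained remission; restart after
discontinuation re-enters induction (the alternative — resuming prior
response — is not modeled); anifrolumab attenuation for
biologic-experienced patients is a synthetic ledger value.
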