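# Methods

## Problem and scope

The package audits two digital sepsis screens applied at
emergency-department triage — the Manchester Triage System (MTS)
*possible sepsis* discriminator and an EHR SIRS-based alert — against
the Sepsis-3 reference standard, on real extracts or on synthetic
cohorts.  The analysis unit is one triaged ED encounter with the
earliest recorded vitals, nurse checkboxes, order flags, SOFA
components and outcomes.

## Screening rules

* **qSOFA** counts three criteria: respiratory rate ≥ 22 breaths/min
  (inclusive), systolic blood pressure < 100 mmHg (strict), altered
  mentation (GCS < 15).  When GCS is unrecorded the nurse-entered
  altered-mental checkbox substitutes; GCS wins when both are present.
* **SIRS (local 3-item variant)** uses strict inequalities throughout:
  temperature < 36 °C or > 38 °C, heart rate > 90 beats/min,
  respiratory rate > 20 breaths/min.  Exactly 36.0 °C, 38.0 °C, 90 and
  20 do **not** meet their criterion.  The white-cell criterion is
  deliberately absent: the audited production form does not collect it.
* **MTS possible-sepsis discriminator**: positive at ≥ 1 qSOFA
  criterion.  In cohort evaluation, the MTS *screen* is the
  nurse-assigned category (the assignment fires the alert; the audited
  software never cross-checked vitals), while the rule output is kept
  separately for the over/undertriage audit.  A configuration enum
  allows counting red-category assignments as screen-positive too
  (`possible_sepsis_or_red`); the default (`alert_only`) matches the
  alert-level contingency counts.
* **SIRS digital alert**: nurse-documented suspicion of a *new*
  infection AND (altered-mental checkbox OR ≥ 2 SIRS criteria).
* **Combined alert**: the union of the two alert sources.
* **NEWS2** uses the published scale-1 bands; the on-oxygen SpO₂
  scale 2 is out of scope.  It serves only as a chart-review selection
  criterion (NEWS > 5), not as an evaluated screen.

**Missing data.** Two policies: `missing_normal` (default) treats an
absent input as *criterion not met*, which is how the production alert
behaved; `strict` marks any result whose deciding input is absent as
indeterminate, which is the right accounting when asking how often
qSOFA was incomputable.  Missing checkboxes are tri-state
(true/false/absent); absent counts as unchecked for the alerts but is
surfaced by the missingness report.  Indeterminate screen results are
resolved to negative before contingency tables are formed.

## Reference standard

Suspected infection = antibiotic or blood-culture orders.  SOFA is the
sum of the six component scores with absent components assumed normal
(0 points); a precomputed total column is honoured only when no
component is present.  Sepsis = suspected infection and SOFA ≥ 2.
Septic shock is operationalised per the Sepsis-3 consensus as sepsis
with vasopressor use and lactate strictly above 2 mmol/L; the lactate
threshold is a keyword argument because the source audit cites the
consensus without restating the rule.

## Statistics

All measures derive from the 2×2 table.  Interval methods were chosen
to match the behaviour of standard diagnostic-accuracy software:

* proportions (Se, Sp, accuracy, prevalence, correctly-triaged) —
  Clopper–Pearson exact intervals via beta-quantile inversion;
* likelihood ratios — Simel log method,
  exp(ln LR ± z·√((1−Se)/(Se·n₁) + Sp/((1−Sp)·n₀))) for LR⁺ and the
  analogous form for LR⁻;
* predictive values — Mercaldo standard-logit intervals (the variance
  of logit PPV expressed through Se, Sp and the stratum sizes).  A
  plain binomial logit interval does *not* reproduce the reference
  behaviour; the Mercaldo form does.  At a degenerate predictive value
  (0 or 1) a 0.5 continuity correction keeps the interval computable
  and the estimate is flagged;
* binary-test AUC = (Se+Sp)/2 with a delta-method interval, clipped to
  [0, 1].

Any measure with an empty denominator (or an LR at a boundary
proportion) is reported as an explicitly undefined estimate with a
note, never as a NaN.

Paired screens are compared with the exact McNemar test within a truth
stratum (diseased for sensitivities, non-diseased for specificities):
p = min(1, 2·P(Binomial(b+c, ½) ≤ min(b, c))), p = 1 when there are no
discordant pairs.

Reported percentages use decimal half-up rounding to one decimal
(ratios to one or two decimals), matching the conventional presentation.
One knowingly unresolved rounding edge: for the MTS screen
(90/189, 27845/28024) the computed AUC is 0.7349, which prints as 0.73;
some software half-rounds intermediate values and shows 0.74.  The
package always reports the value it computed.

The Buderer sample-size calculation uses the exact normal quantile
(z = 1.959964…); with typical inputs the ceiling absorbs the difference
from the textbook 1.96.  Prevalence 1 is allowed (case side only); the
control side is then reported as undefined.

Weighted kappa (linear default, quadratic selectable) is
1 − Σw·O / Σw·E over the shared ordered category set, with distance
weights |i−j| or (i−j)².  The rater-agreement scheme of the source
audit is unstated, so kappa values are never gated against it.

## Synthetic cohorts

### Exact replay

`derive_replay_margins` recovers the joint (MTS × SIRS × sepsis) cells
from the three screen-level 2×2 tables by per-stratum
inclusion–exclusion and refuses inconsistent inputs (negative cells,
mismatched totals, a stated both-alert overlap that disagrees with the
derived one).  `replay_cohort` then materialises one record per cell:

* vitals are drawn uniformly from just-past-threshold bands (e.g. RR
  22–32 when the qSOFA RR criterion must hold, temperature 38.3–40.0 °C
  plus heart rate 95–135 when two SIRS criteria are needed) or clearly
  normal bands otherwise — guaranteeing rule outcomes without modelling
  physiology;
* the possible-sepsis category is set from the MTS cell regardless of
  vitals, modelling nurse error exactly as the audited system allowed;
* SIRS-negative cells are made alert-proof through the suspicion
  checkbox, so qSOFA-relevant vitals can be varied freely (the
  undertriaged records get a low SBP — a vital invisible to the SIRS
  rule);
* altered-mental checkboxes are placed only on alert-positive records
  (the checkbox is an alert arm);
* missingness (SBP, mental status, temperature) is placed only on
  records whose cell outcome cannot depend on the missing field, so
  every margin survives; the SBP and mental-status sets are disjoint,
  making the strict-policy qSOFA-indeterminate count their sum;
* triage categories for MTS-negative records come from the configured
  category margins.  The shipped study margins allocate the 99
  MTS-negative sepsis cases as green 10 / yellow 51 / orange 38, which
  simultaneously reproduces the published per-category sepsis counts
  and the correctly-triaged proportion (128/189).  The source's
  category-margin table is internally inconsistent with its alert
  counts by a handful of patients; the alert counts win and the red
  category absorbs the difference.

Generation is a pure function of (margins, seed): identical seeds give
byte-identical CSV files.  The full 29,766-encounter replay plus
evaluation takes a few seconds on one CPU.

### Stochastic simulation

`simulate_cohort` draws sepsis status Bernoulli(prevalence), then
vitals from band probabilities specific to a latent two-class severity
mixture within each stratum (an overt/occult split for sepsis, an
infected/uninfected split for non-sepsis).  The mixture is what induces
the positive correlation between the two screens seen in real triage
data — with independent per-vital draws the union alert would be far
too sensitive.  The nurse category follows the discriminator applied to
the drawn vitals, flipped with a global overtriage rate (default 0.003:
assignment despite a negative rule) and undertriage rate (default 0.12:
no assignment despite a positive rule); missingness masks are applied
after the nurse decision (the nurse saw the patient, the extract did
not).

Defaults (n = 28,213, prevalence 0.0067, and the shipped band
probabilities) were calibrated analytically against the study's joint
screening margins so that the expected screen sensitivities land near
0.48 (MTS), 0.47 (SIRS) and 0.62 (combined).  The simulator
deliberately does **not** reproduce the study's specificities exactly:
with global (stratum-blind) error rates one cannot match a 0.6 %
MTS false-positive rate and a 47 % sensitivity at the same time — the
real nurses' errors correlate with patient severity beyond the recorded
vitals.  Exact margins are the replay generator's job; the simulator is
for sampling-variability and parameter-recovery work.

### What passing tests do and do not show

The generators emulate marginal and joint *counts*, not physiology:
vitals are band-uniform, uncorrelated beyond the severity classes, and
time-invariant; orders perfectly track the sepsis stratum in replay
mode.  Reproducing the published margins on replayed data validates the
pipeline's arithmetic and bookkeeping, not the clinical performance of
any screen on new patients.

## Problem sizes and tolerances

The test suite evaluates the full 28,213-encounter replay cohort once
(session fixture), 20 seeds × 28,213 stochastic encounters for
parameter recovery (pooled prevalence within 0.001; pooled combined
sensitivity within 5 points of 64 %), a 100,000-replicate bootstrap for
the LR interval cross-check, 2,000 draws for Clopper–Pearson coverage,
and exhaustive tail-inversion checks for n ≤ 50.  Exact-arithmetic
assertions use 1e-12 tolerances; Monte-Carlo comparisons use tolerances
sized to their simulation error.

## Known limitations

* The chart-review selection logic is verified by construction on
  synthetic cohorts only; the audited study's 725 reviewed charts
  depend on its hospital EHR and are not a package-reproducible number.
* Antibiotic timing, multi-visit linkage, HL7/FHIR ingestion and
  continuous-score ROC analysis are out of scope.
* SOFA components are consumed as scores; computing them from raw labs
  is not implemented.
* The stochastic generator's nurse-error model is intentionally simple
  (two global flip rates); see above for why that bounds its realism.
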