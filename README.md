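# triageaudit

Audit toolkit for **digital sepsis screening at emergency-department
triage**.

Hospitals embed sepsis screening rules into their triage software: the
Manchester Triage System (MTS) carries a dedicated *possible sepsis*
discriminator (triggered when a patient meets one or more qSOFA
criteria: respiratory rate ≥ 22 /min, systolic blood pressure
< 100 mmHg, Glasgow Coma Scale < 15), and many EHRs add a SIRS-based
alert (suspicion of a new infection together with an altered mental
state or ≥ 2 of: temperature < 36 °C or > 38 °C, heart rate > 90 /min,
respiratory rate > 20 /min).  How these digitalisations actually perform
against the Sepsis-3 reference standard (suspected infection + SOFA ≥ 2)
— and how often triage nurses apply the discriminator incorrectly — is
an empirical question this package lets you answer reproducibly.

`triageaudit` provides, for epidemiologists, ED quality teams and
methods researchers:

* **Rule engines** — qSOFA, the local 3-item SIRS variant, NEWS2
  (scale 1), the MTS possible-sepsis discriminator, the SIRS digital
  alert and their union, with explicit missing-data policies;
* **Sepsis-3 labelling** — suspected infection from antibiotic /
  blood-culture orders, SOFA with missing-assumed-normal, septic shock
  (vasopressors + lactate > 2 mmol/L);
* **A diagnostic-accuracy engine** — for a 2×2 table with TP/FP/FN/TN:
  Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV, NPV, LR⁺ = Se/(1−Sp),
  LR⁻ = (1−Se)/Sp, accuracy, prevalence and the binary-test
  AUC = (Se+Sp)/2, each with a 95 % CI (Clopper–Pearson exact for
  proportions, Simel log method for likelihood ratios, Mercaldo logit
  for predictive values), plus the exact paired McNemar test;
* **Audit procedures** — overtriage (possible-sepsis assignments with
  zero qSOFA criteria), undertriage (suspected infection with criteria
  but no assignment), chart-review selection, weighted kappa,
  missingness accounting;
* **Study design** — the Buderer sample-size calculation
  `n_cases = ⌈z²·Se(1−Se)/d²⌉`, scaled by prevalence;
* **Synthetic cohorts** — a stochastic generator with per-stratum
  vital-sign distributions and nurse triage-error rates, and an
  **exact-replay mode** that reconstructs an encounter-level cohort
  reproducing a full set of published screening margins cell for cell.

## Worked example

Replay the audited tertiary-care ED cohort (29,766 triaged encounters;
1,537 blue-category and 16 palliative exclusions leave 28,213 for
analysis) and evaluate all three screens:

```bash
triageaudit run-all --mode replay --seed 1 --out-dir results/
```

`results/report.md` then contains (excerpt):

```
Cohort: 29766 encounters, 1537 blue and 16 palliative excluded, 28213 analysed.
Sepsis-3 reference: 189 cases (0.7% prevalence); 1016 digital sepsis alerts.

| Measure      | MTS possible sepsis | 95% CI         | SIRS-based system | 95% CI          | MTS plus SIRS-based system | 95% CI         |
| Sensitivity  | 47.6%               | 40.3 to 55.0%  | 51.9%             | 44.5 to 59.2%   | 64.0%                      | 56.7 to 70.9%  |
| Specificity  | 99.4%               | 99.3 to 99.5%  | 97.0%             | 96.8 to 97.2%   | 96.8%                      | 96.6 to 97.0%  |
| AUC          | 0.73                | 0.70 to 0.77   | 0.74              | 0.71 to 0.78    | 0.80                       | 0.77 to 0.84   |

| Screen                     | TP  | FP  | FN | TN    | Alerts |
| MTS possible sepsis        | 90  | 179 | 99 | 27845 | 269    |
| SIRS-based system          | 98  | 831 | 91 | 27193 | 929    |
| MTS plus SIRS-based system | 121 | 895 | 68 | 27129 | 1016   |
```

Reading: the nurse-driven MTS discriminator finds fewer than half of
the 189 Sepsis-3 cases (Se 47.6 %) but almost never fires falsely
(Sp 99.4 %, LR⁺ 74.6); adding the vitals-driven SIRS alert lifts
sensitivity to 64.0 % at the cost of 895 false alerts among 1,016
(88.1 %).  The exact McNemar test on the 31 discordant sepsis cases
(all detected only by the combined alert) gives p < 0.0001.  The audit
section of the report shows 172 of 269 possible-sepsis assignments
(63.9 %) met no qSOFA criterion (overtriage) while 425
suspected-infection patients with criteria were not assigned
(undertriage).

The same pipeline runs on your own extract
(`triageaudit evaluate my_cohort.csv --out-dir results/`; one row per
encounter, columns documented in `triageaudit.cohort_io.COHORT_COLUMNS`),
and the other stages are independently invocable
(`generate`, `screen`, `audit`, `samplesize`).

Library use mirrors the CLI:

```python
from triageaudit import RunConfig, run_audit

result = run_audit(RunConfig(mode="replay", seed=1))
print(result.tables["combined"])   # TwoByTwo(tp=121, fp=895, fn=68, tn=27129)
print(result.reports["combined"].sensitivity.value)  # 0.6402...
```

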