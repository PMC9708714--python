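# hfref-cea

A Markov cohort cost-effectiveness model of adding empagliflozin (an SGLT2
inhibitor) to standard therapy for heart failure with reduced ejection
fraction (HFrEF), from the perspective of the Chinese health system. The
package is aimed at health-economics practitioners and students who want a
tested, scriptable version of a three-state decision model: the deterministic
base case, one-way and scenario sensitivity analyses, and a Monte-Carlo
probabilistic sensitivity analysis (PSA), plus a synthetic patient-level
trial generator that closes the loop from event counts back to transition
probabilities.

## The model

Patients occupy one of three states — **stable HF**, **hospitalized** (a
transitional state lasting at most one monthly cycle), and **dead**
(absorbing) — and move between them under per-cycle probabilities:

- stable → hospitalized: `p_sh` (arm-specific),
- stable → dead: `p_sc + p_ncv(age)` (cardiovascular plus age-banded
  background mortality),
- hospitalized → dead: `p_hc + p_ncv(age)`; survivors return to stable.

The cohort starts fully stable at age 67 and runs 240 monthly cycles
(20 years). Costs (monthly treatment plus a per-admission cost) and QALYs
(annual utilities 0.871 stable / 0.215 hospitalized) accrue with a
half-cycle correction and are discounted at 5%/year evaluated mid-cycle.
Cumulative probabilities convert to per-cycle ones through the constant
hazard relations `r = −ln(1−P)/T` and `p = 1 − e^{−rt}`. The decision
statistic is the incremental cost-effectiveness ratio
`ICER = ΔC/ΔE` (USD per QALY), judged against willingness-to-pay thresholds
of 1× and 3× China's 2021 per-capita GDP ($11,981 / $35,943). The PSA draws
probabilities and utilities from moment-matched Beta distributions and costs
from moment-matched Gamma distributions, and summarizes the draws as a
cost-effectiveness acceptability curve (CEAC) via the net monetary benefit
rule `NMB(λ) = λ·ΔE − ΔC`.

## Worked example

```python
import hfref_cea as h

params = h.base_case_parameters()
emp = h.run_arm(params, "empagliflozin")
std = h.run_arm(params, "standard")
res = h.icer(emp, std, params.econ.wtp_thresholds)
print(f"empagliflozin: ${emp.total_cost:.2f}, {emp.total_qalys:.2f} QALYs")
print(f"standard:      ${std.total_cost:.2f}, {std.total_qalys:.2f} QALYs")
print(f"ICER: ${res.icer:.2f}/QALY, cost-effective: {res.wtp_verdicts}")
```

prints

```
empagliflozin: $5956.65, 5.68 QALYs
standard:      $4932.21, 5.41 QALYs
ICER: $3700.50/QALY, cost-effective: {11981.0: True, 35943.0: True}
```

i.e. the empagliflozin arm costs $1,024.43 more per patient over 20 years,
gains 0.28 QALYs, and the ratio sits well below the 1×-GDP threshold, so the
addition of empagliflozin is cost-effective. The same pipeline is available
from the shell:

```bash
hfref-cea base-case --out results/base
hfref-cea tornado   --out results/tornado
hfref-cea scenarios --out results/scenarios
hfref-cea psa --n 1000 --seed 1 --out results/psa
hfref-cea simulate-trial --n-per-arm 1863 --months 16 --seed 1 --out results/trial
hfref-cea estimate --patients results/trial/patients.csv \
                   --events results/trial/events.csv --out results/estimates
```

Each command writes tidy CSVs plus a `manifest.json` recording the config
digest, package version and seed.

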