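# twovisit

Statistical toolkit for **two-visit (pre–post) chronic-disease monitoring
cohorts**: the kind of study in which patients in a primary-care
surveillance programme are measured at baseline and roughly one year
later, some of them additionally enrolled in a specialised care plan,
and the question is whether outcomes changed over time and whether the
specialised plan made a difference.

It is written for biostatisticians and epidemiologists who need to

* **analyse** such a cohort — random-intercept linear mixed models per
  outcome, Kruskal–Wallis and Pearson chi-square group comparisons,
  median/IQR descriptive tables, Benjamini–Hochberg FDR adjustment
  across outcomes;
* **plan** such a study — a Monte Carlo power engine with a closed-form
  analytic cross-check;
* **prototype** on realistic synthetic data — a generator that emulates
  a 124-subject type-2-diabetes monitoring cohort (91 patients in the
  regional care pathway "PDTA" alone, 33 also followed by a specialised
  diabetes centre "CAD"), with 17 clinical and lifestyle outcomes,
  configurable medians/IQRs, exact per-visit missingness counts and
  within-subject correlation.

## Model

For outcome value $y_{ij}$ of subject $i$ at visit $j \in \{0, 1\}$:

$$y_{ij} = \beta_0 + \beta_t\,t_{ij} + \beta_g\,g_i + \beta_{gt}\,g_i t_{ij} + u_i + \varepsilon_{ij}$$

with random intercept $u_i \sim N(0, \sigma_b^2)$ and residual
$\varepsilon_{ij} \sim N(0, \sigma_e^2)$, so repeated measures correlate
with ICC $\rho = \sigma_b^2/(\sigma_b^2+\sigma_e^2)$. Time $t$ is either
days from baseline (study analysis) or a 0/1 visit indicator (power
work); $g$ flags specialised-care enrollment. Variance components are
estimated by REML (or ML) via a profile likelihood over
$\sigma_b^2/\sigma_e^2$ with closed-form GLS fixed effects; inference is
two-sided Wald $z$. Model 1 fits time only; Model 2 adds the group and
group-by-time effects, whose interaction is the difference between
groups in mean change.

The power simulation draws cohorts from this model with
$\beta_0 = 51$, $\beta_t = \beta_g = \beta_{gt} = 2.6$ (glycated
haemoglobin, mmol/mol; a Cohen's $d$ of $2.6/3.3 \approx 0.8$), total
SD $3.3$, and tests both group terms at $\alpha = 0.05/17$.

## Worked example

```python
from twovisit import PowerConfig, analytic_power, run_power_simulation

config = PowerConfig(reps=500, seed=0)   # balanced 62/62, icc 0.55, alpha 0.05/17
result = run_power_simulation(config)
print(result.rejection_rate)             # {'group': 0.92, 'group:time': 0.932}
print(result.joint_rejection_rate)       # 0.854
print(analytic_power(config)["joint"])   # 0.8718904990091604
```

At a sample size of 124 subjects, about 87% of replications find both
the group effect and the group-by-time interaction significant — the
Monte Carlo estimate (0.854 ± 0.016 at 500 replications) agrees with
the exact bivariate-normal calculation (0.872).

The same from the shell, plus a synthetic cohort run through the full
analysis:

```bash
twovisit power --reps 500 --seed 0 --out power.csv
twovisit simulate-cohort --seed 9 --out cohort.csv
twovisit analyze --input cohort.csv --out-dir report/
```

`report/` then holds `table1.csv` (demographics by care group),
`table2.csv`/`table3.csv` (baseline and follow-up outcome summaries,
median (q1, q3) or count (%) with group-comparison p-values) and
`table4.csv` (per-outcome Model-1/Model-2 estimates, SEs, raw and
BH-adjusted p-values), with provenance in `run.json`.

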