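# Methods

## The model and what it assumes

All longitudinal analyses in this package use a Gaussian linear mixed
model with a single subject-level random intercept. For subject *i* at
visit *j*:

    y_ij = x_ij' beta + u_i + e_ij,
    u_i ~ N(0, sigma_b^2),   e_ij ~ N(0, sigma_e^2), independent.

With two visits this is the compound-symmetry model: the two
measurements of a subject correlate with intraclass correlation
ICC = sigma_b^2 / (sigma_b^2 + sigma_e^2). Assumptions worth keeping in
mind: Gaussian outcomes with homogeneous variance in both groups and at
both visits, a common ICC, linear (additive) effects, and missingness
ignorable given the model (missing at random). Subjects observed at
only one visit still contribute that observation; there is no listwise
deletion.

Two fixed-effect layouts are used. *Model 1* contains intercept and
time; *Model 2* adds the care-group main effect and the group-by-time
interaction. On complete balanced data Model 2 is saturated for the
2×2 cell means, so the interaction estimate is exactly the difference
between groups in mean change — the quantity a pre–post comparative
study is about.

Two time codings coexist deliberately. The study analysis codes time
as *days from baseline* (per-subject, median 370), so a time
coefficient is a per-day change; the power simulation codes time as a
*0/1 visit indicator*, so coefficients are per-follow-up changes on the
outcome scale. Mixing them up changes effect magnitudes by a factor of
~370 — the API makes the coding an explicit `ModelSpec`/generator
field rather than a convention.

Binary lifestyle indicators (current smoker; moderate-or-intense
physical activity) are fitted with the same Gaussian model on their 0/1
values — a linear probability approximation, chosen so every outcome
row of the report carries effects on one scale. Estimates remain
unbiased for the probability differences; their Wald p-values inherit
the usual caveats of linear probability models near the 0/1 boundary.

## Estimation and inference

The (restricted) log-likelihood is profiled over the variance ratio
lambda = sigma_b^2 / sigma_e^2. Given lambda, per-cluster inverses are
rank-one (Woodbury): (I + lambda J)^-1 = I − lambda/(1 + n_i lambda) J,
|I + lambda J| = 1 + n_i lambda, so GLS fixed effects and the residual
scale are closed-form. Sufficient statistics (per-cluster sums of the
design and outcome, grouped by cluster size) are accumulated once;
each objective evaluation afterwards costs O(p²) independent of sample
size, which is what makes 20,000-replication simulations cheap.

Numerical choices:

* lambda is optimised on the log scale over [1e-8, 1e8] with bounded
  Brent (absolute tolerance 1e-10 on log lambda); both interval
  endpoints are also evaluated and the best of the three is taken, so
  sigma_b^2 = 0 boundary solutions are accepted rather than flagged as
  failures.
* Zero residual variation (perfect within-subject fit) is reported as a
  boundary fit with a warning, not an exception.
* Wald inference uses the standard-normal reference, the common default
  for mixed models; no Satterthwaite/Kenward–Roger degrees-of-freedom
  correction is attempted. At this study's size (124 subjects) the z
  reference makes tail tests mildly anticonservative (observed null
  rejection ~0.0033–0.0039 at nominal 0.00294 over 20,000
  replications), which the test suite quantifies.
* REML is the default; ML is available. Fixed effects agree between the
  two on balanced designs; REML variance components are the larger.

Correctness is established two ways: exact small-sample identities
(difference-of-mean-changes interaction, location/scale equivariance)
and equivalence with independent implementations — R's lme4 to 1e-6
relative on estimates and standard errors (and on the REML
log-likelihood itself), statsmodels' MixedLM as a second, looser
cross-check.

## Group comparisons and multiplicity

Descriptive comparisons mirror standard clinical "table one" practice:
median (first, third quartile) with the Kruskal–Wallis rank test for
continuous variables (for two groups this is the large-sample Wilcoxon
rank-sum test, tie-corrected, chi-square reference); count (percent)
with Pearson's chi-square test for categorical ones. Two conventions
are pinned because they change printed p-values: **no** Yates
continuity correction, and **no** small-cell exclusion rule (expected
counts below 1 warn but are tested as-is — sparse treatment categories
such as insulin-only are genuinely tiny in cohorts like this).
Quartiles use linear interpolation of order statistics ("type 7"); the
convention is arbitrary and documented rather than load-bearing.

The 17 outcome p-values of each effect column (Model-1 time, Model-2
time, group, group-by-time) form separate Benjamini–Hochberg families
of m = 17. The step-up adjustment is the literal cumulative-minimum
definition, validated against a brute-force min-over-suffix loop and
statsmodels, and checked to control the family-wise false discovery
rate at its nominal level under a simulated global null.

## The power simulation

Each replication draws 124 subjects (62 per arm by default) from the
explicit generative model

    Y = 51 + 2.6·Time + 2.6·Group + 2.6·Time·Group + u + e,

with total SD 3.3 split by the ICC, fits Model 2 with visit coding and
REML, and records which Wald tests fall below alpha = 0.05/17 (0.05
shared across the 17 outcomes). The headline quantity is the *joint*
rate: both the group and the interaction term significant in the same
replication. Replication r uses the RNG substream seeded by
(seed, r), so any single replication is reproducible in isolation;
non-converged fits are excluded (more than 5% aborts the run).

Parameter defaults and why:

| parameter | default | rationale |
|---|---|---|
| beta0 | 51 mmol/mol | typical well-controlled HbA1c baseline |
| beta_time, beta_group, beta_interaction | 2.6 | Cohen's d = 2.6/3.3 ≈ 0.8, a large effect |
| sd_total | 3.3 | treated as a standard deviation — the d arithmetic above only works on the SD scale |
| icc | 0.55 | not identified by the published design; chosen because the analytic oracle puts joint power at ≈0.87 for the balanced 124-subject design, consistent with the study's reported operating characteristics. Exposed as a knob. |
| allocation | 62/62 | with the observed 91/33 split the group term's power caps near 0.82 under any ICC, so the planning simulation must have used a balanced allocation |
| reps | 500 | the planning convention; MC SE of a 0.87 rate is ±0.015 |
| alpha | 0.05/17 | Bonferroni sharing of 0.05 across the 17 monitored outcomes |

The analytic oracle uses the exact GLS sampling variances of the
saturated complete-data design — Var(group) = sd²(1/n_A + 1/n_B),
Var(interaction) = 2(1−icc)sd²(1/n_A + 1/n_B) — and integrates the
bivariate normal of the two Wald statistics, whose correlation is
−sqrt((1−icc)/2), over the four two-sided rejection quadrants. It
predicts 0.872 at the defaults; the simulation reproduces it within
Monte Carlo error. The oracle assumes known variances and complete
data, so it sits a whisker above the simulated rate at small n.

## The synthetic cohort generator

`generate_cohort` emulates the *marginal* structure of a two-visit
monitoring cohort: exact group sizes (91/33 by default), exact
per-visit non-missing counts per outcome (missing subjects sampled
without replacement — missingness completely at random within
outcome), continuous outcomes from a normal or log-normal family
matched to the target median and IQR (log-normal for skewed laboratory
values: HbA1c, microalbuminuria, triglycerides, cigarettes/day; normal
for pressures, weight, BMI and the zero-median alcohol intake),
categorical outcomes via a Gaussian copula with per-visit thresholds,
and within-subject correlation through a shared subject-level Gaussian
(default 0.55, matching the power module's ICC default).

What it does **not** emulate, hence what passing tests do not show
about real data: inter-outcome dependence (weight and BMI are drawn
independently), informative or visit-correlated missingness, group
differences in location or spread (both groups share each outcome's
marginal distribution), measurement rounding, or trajectories beyond
two visits. Analyses of real cohorts should expect all of these.

Degenerate inputs behave predictably: `baseline_spread = 0` pins every
value to the configured location (plus the follow-up shift); ICC = 1
designs are rejected (no residual variance to estimate); identical
configurations and seeds give bit-identical tables.

## Problem sizes used in the shipped checks

Convergence-style checks run at sizes chosen so Monte Carlo noise sits
well inside the asserted tolerance: 40,000 subjects for median/IQR
calibration (2% bands), 10,000 for correlation and change-variance
identities, 20,000 replications for null rejection rates, 500 for the
headline power figure, 200 simulated cohorts for bias/SE calibration.

## Known limitations

* Gaussian-only outcomes; no logistic or other generalized links for
  the binary indicators.
* No random slopes and no more than two visits.
* Normal-reference Wald tests; small-sample df corrections are out of
  scope, and the documented mild anticonservatism at n ≈ 124 is the
  price.
* The BH families are fixed per effect column; joint adjustment across
  columns is not offered.
* The generator's calibration is marginal, not joint (see above).
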