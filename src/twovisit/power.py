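"""Monte Carlo sample-size engine for the two-visit random-intercept design.

Each replication draws a cohort from the explicit pre-post model
(:func:`twovisit.cohort.generate_power_dataset`), fits the full model
(time + group + interaction, visit-indicator coding) and records which
Wald tests reject at the multiplicity-adjusted level.  The companion
:func:`analytic_power` computes the same quantities in closed form from
the exact GLS sampling variances, and is used to validate the engine.

With complete two-visit data the GLS estimator equals the cell-means
estimator, so

    Var(group)       = sd^2 (1/n_A + 1/n_B)            (baseline contrast)
    Var(group:time)  = 2 (1-icc) sd^2 (1/n_A + 1/n_B)  (difference of changes)

and the two Wald statistics are bivariate normal with correlation
-sqrt((1-icc)/2) (the subject effect cancels from the change score but
the baseline noise enters both contrasts with opposite signs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import PowerDesignConfig, generate_power_dataset
from .lmm import RandomInterceptLMM

__all__ = ["PowerConfig", "PowerResult", "run_power_simulation", "analytic_power", "cohens_d", "format_cohens_d"]

#: Default significance level: 0.05 Bonferroni-shared across the study's
#: 17 monitored outcomes.
DEFAULT_ALPHA = 0.05 / 17

TERM_NAMES = ("time", "group", "group:time")


@dataclass(frozen=True)
class PowerConfig:
    design: PowerDesignConfig = field(default_factory=PowerDesignConfig)
    reps: int = 500
    alpha: float = DEFAULT_ALPHA
    terms_of_interest: tuple[str, ...] = ("group", "group:time")
    seed: int = 0

    def validate(self) -> None:
        self.design.validate()
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        unknown = set(self.terms_of_interest) - set(TERM_NAMES)
        if unknown:
            raise ValueError(f"unknown terms of interest: {sorted(unknown)}")


@dataclass
class PowerResult:
    """Per-term and joint rejection rates with Monte Carlo uncertainty."""

    rejection_rate: dict
    joint_rejection_rate: float
    mc_standard_error: dict
    reps_converged: int
    reps_requested: int

    def __post_init__(self):
        assert self.joint_rejection_rate <= min(self.rejection_rate.values()) + 1e-12


def _mc_se(p: float, n: int) -> float:
    return math.sqrt(p * (1.0 - p) / n) if n > 0 else float("nan")


def run_power_simulation(config: PowerConfig) -> PowerResult:
    """Estimate rejection rates by simulation.

    Each replication r uses the independent RNG substream seeded by
    ``(config.seed, r)`` so any single replication can be reproduced in
    isolation.  Replications whose fit does not converge are excluded
    from the rates; more than 5% failures aborts the run.
    """
    config.validate()
    n_reps = config.reps
    reject = {t: np.zeros(n_reps, dtype=bool) for t in TERM_NAMES}
    ok = np.zeros(n_reps, dtype=bool)
    model = RandomInterceptLMM(method="reml")
    for r in range(n_reps):
        rng = np.random.default_rng([config.seed, r])
        d = generate_power_dataset(config.design, rng=rng)
        time = d["time"].to_numpy(dtype=float)
        cad = d["cad"].to_numpy(dtype=float)
        X = np.column_stack([time, cad, time * cad])
        fit = model.fit(X, d["y"].to_numpy(), groups=d["subject_id"].to_numpy())
        ok[r] = fit.converged_
        if fit.converged_:
            # pvalues_[0] is the intercept
            for i, t in enumerate(TERM_NAMES, start=1):
                reject[t][r] = fit.pvalues_[i] < config.alpha
    n_ok = int(ok.sum())
    if n_ok < 0.95 * n_reps:
        raise RuntimeError(f"{n_reps - n_ok}/{n_reps} replications failed to converge")
    rates = {t: float(reject[t][ok].mean()) for t in config.terms_of_interest}
    joint = np.ones(n_reps, dtype=bool)
    for t in config.terms_of_interest:
        joint &= reject[t]
    joint_rate = float(joint[ok].mean())
    ses = {t: _mc_se(p, n_ok) for t, p in rates.items()}
    ses["joint"] = _mc_se(joint_rate, n_ok)
    return PowerResult(
        rejection_rate=rates,
        joint_rejection_rate=joint_rate,
        mc_standard_error=ses,
        reps_converged=n_ok,
        reps_requested=n_reps,
    )


def _term_power(delta: float, zcrit: float) -> float:
    """Two-sided rejection probability of a Wald z with non-centrality delta."""
    return float(stats.norm.sf(zcrit - delta) + stats.norm.cdf(-zcrit - delta))


def analytic_power(config: PowerConfig) -> dict:
    """Closed-form per-term and joint power for the complete balanced design.

    Assumes every subject has both visits (the generator's case).  The
    joint probability integrates the bivariate normal of the group and
    interaction Wald statistics over the four two-sided rejection
    quadrants.
    """
    config.validate()
    des = config.design
    n_a, n_b = des.allocation
    inv_n = 1.0 / n_a + 1.0 / n_b
    sd2 = des.sd_total**2
    var = {
        # time coef = mean change in the reference arm (cell-means estimator)
        "time": 2.0 * (1.0 - des.icc) * sd2 / n_a,
        "group": sd2 * inv_n,
        "group:time": 2.0 * (1.0 - des.icc) * sd2 * inv_n,
    }
    beta = {"time": des.beta_time, "group": des.beta_group, "group:time": des.beta_interaction}
    zcrit = stats.norm.ppf(1.0 - config.alpha / 2.0)
    power = {t: _term_power(beta[t] / math.sqrt(var[t]), zcrit) for t in TERM_NAMES}

    d_g = beta["group"] / math.sqrt(var["group"])
    d_i = beta["group:time"] / math.sqrt(var["group:time"])
    rho = -math.sqrt((1.0 - des.icc) / 2.0)
    mvn = stats.multivariate_normal(mean=[d_g, d_i], cov=[[1.0, rho], [rho, 1.0]])
    big = 1e8

    def rect(lo1, hi1, lo2, hi2):
        c = lambda a, b: mvn.cdf([min(a, big), min(b, big)])
        return c(hi1, hi2) - c(lo1, hi2) - c(hi1, lo2) + c(lo1, lo2)

    tails = [(-big, -zcrit), (zcrit, big)]
    joint = sum(rect(*r1, *r2) for r1 in tails for r2 in tails)
    return {"per_term": power, "joint": float(max(0.0, min(1.0, joint))), "wald_correlation": rho}


def cohens_d(effect: float, sd: float) -> float:
    """Standardised effect size d = effect / sd."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return effect / sd


def format_cohens_d(effect: float, sd: float) -> str:
    """d rounded to one decimal, the conventional reporting precision."""
    return f"{cohens_d(effect, sd):.1f}"
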