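"""Synthetic two-visit cohort generation.

Two generators live here:

* :func:`generate_cohort` draws "study-like" cohorts whose marginal
  structure (group sizes, medians/IQRs, per-visit non-missing counts,
  within-subject correlation) is configured per outcome — the stand-in
  for the undeposited patient data.
* :func:`generate_power_dataset` draws a single continuous outcome from
  the explicit generative model used for sample-size work,

      Y_ij = b0 + bt*Time_ij + bg*Group_i + bgt*Time_ij*Group_i + u_i + e_ij,

  with a subject random intercept u_i ~ N(0, icc*sd^2) and residual
  e_ij ~ N(0, (1-icc)*sd^2), Time and Group coded 0/1.

Continuous study outcomes come from a location–scale family (normal or
log-normal per outcome) parameterised by the target median and IQR;
categorical outcomes use a Gaussian copula with per-visit thresholds so
the shared subject effect induces visit-to-visit persistence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import study

__all__ = [
    "OutcomeSpec",
    "CohortConfig",
    "PowerDesignConfig",
    "default_outcome_specs",
    "default_cohort_config",
    "generate_cohort",
    "generate_power_dataset",
]

_Z75 = stats.norm.ppf(0.75)  # 0.67449, quartile of the standard normal


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class OutcomeSpec:
    """Generative definition of one monitored outcome.

    Parameters
    ----------
    name : str
        Column name in the cohort table.
    scale : {"continuous", "binary", "categorical"}
    units : str
        Free-text measurement units.
    baseline_location : float
        Target baseline median (continuous) or success proportion
        (binary).  Ignored for categorical outcomes.
    baseline_spread : float
        Target baseline IQR width (q3 - q1) for continuous outcomes;
        must be >= 0.  ``0`` makes the outcome degenerate at the
        location.
    followup_shift : float
        Additive change in location (median or proportion) at follow-up.
    within_subject_corr : float
        Correlation of the latent subject-level Gaussian between the
        two visits, in [0, 1].
    family : {"normal", "lognormal"}
        Location–scale family for continuous outcomes.  Log-normal
        matches skewed laboratory values; it requires a positive median.
    categories, baseline_probs, followup_probs
        For categorical outcomes only: labels and per-visit category
        probabilities (each summing to 1).
    missing_baseline, missing_followup : int
        Exact number of subjects with a missing value at each visit.
    """

    name: str
    scale: str = "continuous"
    units: str = ""
    baseline_location: float = 0.0
    baseline_spread: float = 1.0
    followup_shift: float = 0.0
    within_subject_corr: float = 0.55
    family: str = "normal"
    categories: Optional[Sequence[str]] = None
    baseline_probs: Optional[Sequence[float]] = None
    followup_probs: Optional[Sequence[float]] = None
    missing_baseline: int = 0
    missing_followup: int = 0

    def validate(self, n_subjects: int) -> None:
        if self.scale not in ("continuous", "binary", "categorical"):
            raise ConfigurationError(f"{self.name}: unknown scale {self.scale!r}")
        if not 0.0 <= self.within_subject_corr <= 1.0:
            raise ConfigurationError(f"{self.name}: within_subject_corr outside [0, 1]")
        for label, count in (("baseline", self.missing_baseline), ("followup", self.missing_followup)):
            if not 0 <= count <= n_subjects:
                raise ConfigurationError(
                    f"{self.name}: missing_{label} count {count} outside [0, {n_subjects}]"
                )
        if self.scale == "continuous":
            if self.baseline_spread < 0:
                raise ConfigurationError(f"{self.name}: negative baseline_spread")
            if self.family not in ("normal", "lognormal"):
                raise ConfigurationError(f"{self.name}: unknown family {self.family!r}")
            if self.family == "lognormal" and (
                self.baseline_location <= 0 or self.baseline_location + self.followup_shift <= 0
            ):
                raise ConfigurationError(f"{self.name}: log-normal family needs positive medians")
        elif self.scale == "binary":
            if not 0.0 <= self.baseline_location <= 1.0:
                raise ConfigurationError(f"{self.name}: binary proportion outside [0, 1]")
        else:
            if not self.categories or self.baseline_probs is None or self.followup_probs is None:
                raise ConfigurationError(f"{self.name}: categorical outcome needs categories and probs")
            for probs in (self.baseline_probs, self.followup_probs):
                if len(probs) != len(self.categories) or abs(sum(probs) - 1.0) > 1e-8:
                    raise ConfigurationError(f"{self.name}: category probabilities must sum to 1")


def default_outcome_specs() -> list[OutcomeSpec]:
    """The 17 monitored outcomes with the study's calibration targets."""
    specs = []
    for name, units, family, med, q1, q3, fmed, n_b, n_f in study.CONTINUOUS_OUTCOMES:
        specs.append(
            OutcomeSpec(
                name=name,
                scale="continuous",
                units=units,
                family=family,
                baseline_location=med,
                baseline_spread=q3 - q1,
                followup_shift=fmed - med,
                missing_baseline=study.N_TOTAL - n_b,
                missing_followup=study.N_TOTAL - n_f,
            )
        )
    for name, cats, p_b, p_f, n_b, n_f in study.CATEGORICAL_OUTCOMES:
        specs.append(
            OutcomeSpec(
                name=name,
                scale="categorical",
                categories=tuple(cats),
                baseline_probs=tuple(p_b),
                followup_probs=tuple(p_f),
                missing_baseline=study.N_TOTAL - n_b,
                missing_followup=study.N_TOTAL - n_f,
            )
        )
    return specs


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a study-like synthetic cohort."""

    n_group_a: int = study.N_GROUP_A
    n_group_b: int = study.N_GROUP_B
    followup_days: tuple[float, float, float] = study.FOLLOWUP_DAYS  # median, q1, q3
    age_years: tuple[float, float, float] = study.AGE_YEARS
    male_proportion: float = study.MALE_PROPORTION
    treatment_props: dict = field(default_factory=lambda: dict(study.TREATMENT_PROPS))
    outcome_specs: tuple[OutcomeSpec, ...] = field(
        default_factory=lambda: tuple(default_outcome_specs())
    )
    seed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_group_a + self.n_group_b

    def validate(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ConfigurationError("both groups must be non-empty")
        if not 0.0 <= self.male_proportion <= 1.0:
            raise ConfigurationError("male_proportion outside [0, 1]")
        if abs(sum(self.treatment_props.values()) - 1.0) > 1e-8:
            raise ConfigurationError("treatment proportions must sum to 1")
        names = [s.name for s in self.outcome_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate outcome names")
        for spec in self.outcome_specs:
            spec.validate(self.n_total)


@dataclass(frozen=True)
class PowerDesignConfig:
    """Design of a power-study dataset drawn from the explicit pre-post model."""

    n_total: int = 124
    allocation: tuple[int, int] = (62, 62)
    beta0: float = 51.0
    beta_time: float = 2.6
    beta_group: float = 2.6
    beta_interaction: float = 2.6
    sd_total: float = 3.3
    icc: float = 0.55
    seed: int = 0

    def validate(self) -> None:
        if sum(self.allocation) != self.n_total:
            raise ConfigurationError("allocation must sum to n_total")
        if min(self.allocation) < 1:
            raise ConfigurationError("both arms must be non-empty")
        if self.sd_total <= 0:
            raise ConfigurationError("sd_total must be positive")
        if not 0.0 <= self.icc < 1.0:
            raise ConfigurationError("icc must lie in [0, 1): icc -> 1 leaves no residual variance")

    @property
    def sigma_b2(self) -> float:
        return self.icc * self.sd_total**2

    @property
    def sigma_e2(self) -> float:
        return (1.0 - self.icc) * self.sd_total**2


def _correlated_latent(rng: np.random.Generator, n: int, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Two standard-normal vectors with correlation rho via a shared subject effect."""
    b = rng.standard_normal(n)
    e0 = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    s, r = np.sqrt(rho), np.sqrt(1.0 - rho)
    return s * b + r * e0, s * b + r * e1


def _continuous_values(spec: OutcomeSpec, z: np.ndarray, location: float) -> np.ndarray:
    if spec.family == "normal":
        sigma = spec.baseline_spread / (2.0 * _Z75)
        return location + sigma * z
    # log-normal: median m, log-scale s chosen so the IQR width matches
    # m*(e^{z75 s} - e^{-z75 s}) = spread  =>  s = asinh(spread/2m)/z75
    m = spec.baseline_location
    s = np.arcsinh(spec.baseline_spread / (2.0 * m)) / _Z75
    scale = (location) / m  # median shift acts multiplicatively on the baseline median
    return m * scale * np.exp(s * z)


def _categorical_values(categories, probs, z: np.ndarray) -> np.ndarray:
    cuts = stats.norm.ppf(np.cumsum(probs[:-1]))
    idx = np.searchsorted(cuts, z, side="left")
    return np.asarray(categories, dtype=object)[idx]


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Generate a long-format two-visit cohort table.

    Returns one row per subject-visit with columns ``subject_id, group,
    visit, days_from_baseline, age, sex, treatment`` followed by one
    column per configured outcome.  Missing values are ``NaN`` and their
    per-visit counts are exact, with the affected subjects sampled
    without replacement.  Deterministic given ``config.seed`` (or the
    ``seed`` override).
    """
    config = config or default_cohort_config()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_total

    group = np.array([study.GROUP_A] * config.n_group_a + [study.GROUP_B] * config.n_group_b)
    subject_id = np.array([f"S{i + 1:04d}" for i in range(n)])

    med, q1, q3 = config.age_years
    age = np.round(med + (q3 - q1) / (2 * _Z75) * rng.standard_normal(n), 1)
    sex = np.where(rng.random(n) < config.male_proportion, "male", "female")
    treatments = list(config.treatment_props)
    treatment = rng.choice(treatments, size=n, p=[config.treatment_props[t] for t in treatments])

    med, q1, q3 = config.followup_days
    fup_days = np.maximum(1, np.round(med + (q3 - q1) / (2 * _Z75) * rng.standard_normal(n))).astype(int)

    base = {}
    fup = {}
    for spec in config.outcome_specs:
        z0, z1 = _correlated_latent(rng, n, spec.within_subject_corr)
        if spec.scale == "continuous":
            v0 = _continuous_values(spec, z0, spec.baseline_location)
            v1 = _continuous_values(spec, z1, spec.baseline_location + spec.followup_shift)
        elif spec.scale == "binary":
            p0 = spec.baseline_location
            p1 = min(max(p0 + spec.followup_shift, 0.0), 1.0)
            v0 = (z0 < stats.norm.ppf(p0)).astype(float)
            v1 = (z1 < stats.norm.ppf(p1)).astype(float)
        else:
            v0 = _categorical_values(spec.categories, np.asarray(spec.baseline_probs), z0)
            v1 = _categorical_values(spec.categories, np.asarray(spec.followup_probs), z1)
        if spec.scale == "categorical":
            v0, v1 = np.asarray(v0, dtype=object), np.asarray(v1, dtype=object)
            hole = None
        else:
            v0, v1 = np.asarray(v0, dtype=float), np.asarray(v1, dtype=float)
            hole = np.nan
        if spec.missing_baseline:
            v0[rng.choice(n, size=spec.missing_baseline, replace=False)] = hole
        if spec.missing_followup:
            v1[rng.choice(n, size=spec.missing_followup, replace=False)] = hole
        base[spec.name] = v0
        fup[spec.name] = v1

    def _visit_frame(visit: str, days: np.ndarray, values: dict) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": subject_id,
                "group": group,
                "visit": visit,
                "days_from_baseline": days,
                "age": age,
                "sex": sex,
                "treatment": treatment,
                **values,
            }
        )

    table = pd.concat(
        [
            _visit_frame(study.VISIT_BASELINE, np.zeros(n, dtype=int), base),
            _visit_frame(study.VISIT_FOLLOWUP, fup_days, fup),
        ],
        ignore_index=True,
    )
    return table.sort_values(["subject_id", "days_from_baseline"], kind="stable").reset_index(drop=True)


def default_cohort_config(seed: int = 0) -> CohortConfig:
    return CohortConfig(seed=seed)


def generate_power_dataset(
    config: PowerDesignConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw one two-visit dataset from the explicit random-intercept model.

    The single synthetic outcome column is ``y`` (glycated haemoglobin in
    the default parameterisation); ``time`` is the 0/1 visit indicator
    and ``cad`` the 0/1 group indicator.
    """
    config = config or PowerDesignConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_a, n_b = config.allocation
    n = n_a + n_b
    cad = np.concatenate([np.zeros(n_a), np.ones(n_b)])
    u = rng.normal(0.0, np.sqrt(config.sigma_b2), size=n)
    e = rng.normal(0.0, np.sqrt(config.sigma_e2), size=(n, 2))
    mean0 = config.beta0 + config.beta_group * cad
    mean1 = mean0 + config.beta_time + config.beta_interaction * cad
    y0 = mean0 + u + e[:, 0]
    y1 = mean1 + u + e[:, 1]

    subject = np.repeat(np.arange(1, n + 1), 2)
    return pd.DataFrame(
        {
            "subject_id": [f"P{i:04d}" for i in subject],
            "group": np.repeat(np.where(cad == 1, study.GROUP_B, study.GROUP_A), 2),
            "visit": [study.VISIT_BASELINE, study.VISIT_FOLLOWUP] * n,
            "time": np.tile([0, 1], n),
            "cad": np.repeat(cad, 2).astype(int),
            "y": np.column_stack([y0, y1]).ravel(),
        }
    )
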