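"""End-to-end study analysis: descriptive tables and the longitudinal report.

:func:`run_full_analysis` takes a long-format two-visit cohort (file or
frame) and produces

* ``table1`` – demographics and follow-up interval by care group,
* ``table2``/``table3`` – per-visit outcome summaries by care group,
* ``table4`` – the longitudinal report: for each of the 17 outcomes the
  time-only model (Model 1) and the full model with group and
  group-by-time interaction (Model 2), with raw and BH-adjusted Wald
  p-values per effect column.

Time enters the longitudinal models as exact per-subject days from
baseline.  Binary lifestyle indicators are fitted with the same
Gaussian random-intercept model on their 0/1 values (linear
probability), an explicit approximation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import study
from .descriptives import descriptive_table
from .lmm import EstimationError, ModelSpec, fit_random_intercept_lmm
from .multiplicity import bh_adjust

__all__ = ["run_full_analysis", "validate_cohort", "derive_indicators", "load_cohort"]

logger = logging.getLogger("twovisit")

REQUIRED_COLUMNS = ("subject_id", "group", "visit", "days_from_baseline")

#: Effect columns of the longitudinal report; each is its own BH family.
EFFECT_COLUMNS = ("m1_time", "m2_time", "m2_group", "m2_interaction")


def load_cohort(cohort) -> pd.DataFrame:
    """Read a cohort CSV (empty string = missing) or pass a frame through."""
    if isinstance(cohort, (str, Path)):
        return pd.read_csv(cohort, keep_default_na=True)
    return cohort.copy()


def derive_indicators(data: pd.DataFrame) -> pd.DataFrame:
    """Add the 0/1 lifestyle indicator columns analysed in the report.

    ``smoker_yes`` flags current smokers; the moderate-intense activity
    indicator flags the top two of the four activity levels.  Missing
    categorical records propagate to missing indicators.
    """
    data = data.copy()
    if "smoker_yes" not in data.columns and "smoke_habits" in data.columns:
        s = data["smoke_habits"]
        data["smoker_yes"] = np.where(s.isna(), np.nan, (s == "current").astype(float))
    if "physical_activity_moderate_intense" not in data.columns and "physical_activity" in data.columns:
        s = data["physical_activity"]
        data["physical_activity_moderate_intense"] = np.where(
            s.isna(), np.nan, s.isin(["moderate", "intense"]).astype(float)
        )
    return data


def validate_cohort(cohort) -> dict:
    """Schema and consistency checks; returns {'status', 'checks': [...]}.

    Each check is ``{"check", "status" (pass/warn/fail), "detail"}``.
    """
    data = load_cohort(cohort)
    checks = []

    def add(check, status, detail=""):
        checks.append({"check": check, "status": status, "detail": detail})

    missing_cols = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    add(
        "required columns",
        "fail" if missing_cols else "pass",
        f"missing: {missing_cols}" if missing_cols else "",
    )
    if missing_cols:
        return {"status": "fail", "checks": checks}

    counts = data.groupby("subject_id").size()
    over = counts[counts > 2]
    add(
        "at most two visits per subject",
        "fail" if len(over) else "pass",
        f"subjects with >2 visits: {list(over.index)}" if len(over) else "",
    )

    per_visit = data.groupby(["subject_id", "visit"]).size()
    dup = per_visit[per_visit > 1]
    add(
        "one row per subject-visit",
        "fail" if len(dup) else "pass",
        f"duplicated: {[f'{s}/{v}' for s, v in dup.index]}" if len(dup) else "",
    )

    is_base = data["visit"] == study.VISIT_BASELINE
    days = pd.to_numeric(data["days_from_baseline"], errors="coerce")
    bad_days = ((days == 0) != is_base) | days.isna() | (days < 0)
    add(
        "days_from_baseline is 0 exactly at baseline and positive at follow-up",
        "fail" if bad_days.any() else "pass",
        f"{int(bad_days.sum())} offending rows" if bad_days.any() else "",
    )

    n_missing_group = int(data["group"].isna().sum())
    if n_missing_group:
        add("group labels present", "warn", f"{n_missing_group} rows ({100 * n_missing_group / len(data):.0f}%) without a group label")
    else:
        add("group labels present", "pass")

    known = data["group"].dropna().isin(study.GROUP_LABELS)
    if not known.all():
        add("group labels recognised", "warn", f"unknown labels: {sorted(set(data['group'].dropna()[~known]))}")
    else:
        add("group labels recognised", "pass")

    varying = data.groupby("subject_id")["group"].nunique(dropna=True)
    bad = varying[varying > 1]
    add(
        "group constant within subject",
        "fail" if len(bad) else "pass",
        f"subjects: {list(bad.index)}" if len(bad) else "",
    )

    status = "fail" if any(c["status"] == "fail" for c in checks) else (
        "warn" if any(c["status"] == "warn" for c in checks) else "pass"
    )
    return {"status": status, "checks": checks}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _fit_row(data: pd.DataFrame, outcome: str, time_coding: str, estimation: str) -> dict:
    """Model 1 and Model 2 effect estimates for one outcome (NaNs on failure)."""
    row = {"outcome": outcome}
    blank = {f"{c}_{k}": np.nan for c in EFFECT_COLUMNS for k in ("ee", "se", "p")}
    row.update(blank)
    try:
        m1 = fit_random_intercept_lmm(
            data, ModelSpec(outcome=outcome, fixed_terms=("intercept", "time"), time_coding=time_coding, estimation=estimation)
        )
        m2 = fit_random_intercept_lmm(
            data,
            ModelSpec(
                outcome=outcome,
                fixed_terms=("intercept", "time", "group", "group:time"),
                time_coding=time_coding,
                estimation=estimation,
            ),
        )
    except EstimationError as exc:
        logger.warning("outcome %s could not be analysed: %s", outcome, exc)
        return row
    for key, fit, term in (
        ("m1_time", m1, "time"),
        ("m2_time", m2, "time"),
        ("m2_group", m2, "group"),
        ("m2_interaction", m2, "group:time"),
    ):
        row[f"{key}_ee"] = fit.estimates[term]
        row[f"{key}_se"] = fit.standard_errors[term]
        row[f"{key}_p"] = fit.p_values[term]
    row["n_obs"] = m2.n_observations
    row["converged"] = m1.converged and m2.converged
    return row


def run_full_analysis(
    cohort,
    out_dir=None,
    outcomes=None,
    time_coding: str = "days",
    estimation: str = "reml",
    adjust: bool = True,
    seed=None,
) -> dict:
    """Run the full descriptive + longitudinal analysis.

    Parameters
    ----------
    cohort : path or DataFrame
        Long-format two-visit cohort table.
    out_dir : path, optional
        If given, writes ``table1.csv`` … ``table4.csv``, a machine
        readable ``run.json`` and appends to ``run.log``.
    outcomes : list of (label, column), optional
        Override of the 17 analysed outcomes (defaults locked to the
        study's list).
    adjust : bool
        Apply the BH adjustment per effect column (set False to emit
        raw p-values only).
    seed : int, optional
        Recorded in the provenance block (the analysis itself is
        deterministic).

    Returns a dict with keys ``table1`` … ``table4``, ``validation``
    and ``metadata``.
    """
    data = load_cohort(cohort)
    n_read = len(data)
    malformed = data["subject_id"].isna() if "subject_id" in data.columns else pd.Series(False, index=data.index)
    if "visit" in data.columns:
        malformed |= ~data["visit"].isin([study.VISIT_BASELINE, study.VISIT_FOLLOWUP])
    if malformed.any():
        logger.warning("skipping %d malformed rows", int(malformed.sum()))
    data = data.loc[~malformed]
    validation = validate_cohort(data)
    if validation["status"] == "fail":
        raise ValueError(f"cohort failed validation: {validation['checks']}")
    data = derive_indicators(data)
    outcomes = list(outcomes or study.ANALYSIS_OUTCOMES)

    base = data[data["visit"] == study.VISIT_BASELINE]
    fup = data[data["visit"] == study.VISIT_FOLLOWUP]

    # table 1: subject-level demographics + follow-up interval
    subjects = base[["subject_id", "group"]].copy()
    for col in ("sex", "age", "treatment"):
        if col in base.columns:
            subjects[col] = base[col].to_numpy()
    subjects = subjects.merge(
        fup[["subject_id", "days_from_baseline"]].rename(columns={"days_from_baseline": "followup_days"}),
        on="subject_id",
        how="left",
    )
    t1_vars = [(c, k) for c, k in (("sex", "categorical"), ("age", "continuous"), ("treatment", "categorical"), ("followup_days", "continuous")) if c in subjects.columns]
    table1 = descriptive_table(subjects, t1_vars)

    visit_vars = [(name, "continuous") for name, *_ in study.CONTINUOUS_OUTCOMES if name in data.columns]
    visit_vars += [(name, "categorical") for name, *_ in study.CATEGORICAL_OUTCOMES if name in data.columns]
    table2 = descriptive_table(base, visit_vars)
    table3 = descriptive_table(fup, visit_vars)

    rows = []
    for label, column in outcomes:
        if column not in data.columns or data[column].notna().sum() == 0:
            logger.warning("outcome column %s absent or all-missing; emitting NA row", column)
            row = {"outcome": column, **{f"{c}_{k}": np.nan for c in EFFECT_COLUMNS for k in ("ee", "se", "p")}}
        else:
            row = _fit_row(data, column, time_coding, estimation)
        row["variable"] = label
        rows.append(row)
    table4 = pd.DataFrame(rows)
    for col in EFFECT_COLUMNS:
        table4[f"{col}_p_adj"] = bh_adjust(table4[f"{col}_p"]) if adjust else table4[f"{col}_p"]
    lead = ["variable"]
    stat_cols = [f"{c}_{k}" for c in EFFECT_COLUMNS for k in ("ee", "se", "p", "p_adj")]
    table4 = table4[lead + stat_cols + [c for c in ("n_obs", "converged") if c in table4.columns]]

    config = {
        "time_coding": time_coding,
        "estimation": estimation,
        "adjust": adjust,
        "outcomes": [c for _, c in outcomes],
    }
    metadata = {
        "n_subjects": int(base["subject_id"].nunique()),
        "n_rows_read": n_read,
        "n_rows_used": int(len(data)),
        "n_rows_skipped": int(malformed.sum()),
        "seed": seed,
        "config": config,
        "config_hash": _config_hash(config),
        "validation_status": validation["status"],
    }

    result = {
        "table1": table1,
        "table2": table2,
        "table3": table3,
        "table4": table4,
        "validation": validation,
        "metadata": metadata,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("table1", "table2", "table3", "table4"):
            result[name].to_csv(out_dir / f"{name}.csv", index=False)
        (out_dir / "run.json").write_text(json.dumps(metadata, indent=2, default=str) + "\n")
        logger.info("analysis written to %s (config %s)", out_dir, metadata["config_hash"])
    return result
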