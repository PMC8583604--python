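"""Synthetic cohort and power-dataset generators."""

import numpy as np
import pandas as pd
import pytest

from twovisit import study
from twovisit.cohort import (
    CohortConfig,
    ConfigurationError,
    OutcomeSpec,
    PowerDesignConfig,
    default_outcome_specs,
    generate_cohort,
    generate_power_dataset,
)


class TestStudyCohort:
    def test_default_cohort_shape_and_group_sizes(self):
        coh = generate_cohort()
        assert len(coh) == 248
        assert coh["subject_id"].nunique() == 124
        baseline = coh[coh["visit"] == "baseline"]
        assert baseline["group"].value_counts().to_dict() == {"PDTA": 91, "PDTA_CAD": 33}
        # two visits each, days 0 exactly at baseline
        assert (coh.groupby("subject_id").size() == 2).all()
        assert ((coh["days_from_baseline"] == 0) == (coh["visit"] == "baseline")).all()

    @pytest.mark.parametrize(
        "column, n_base, n_fup",
        [
            ("microalbuminuria", 111, 107),
            ("glycated_hemoglobin", 124, 123),
            ("cigarettes_per_day", 57, 57),
            ("smoke_habits", 122, 123),
        ],
    )
    def test_nonmissing_counts_are_exact(self, column, n_base, n_fup):
        coh = generate_cohort(CohortConfig(seed=5))
        base = coh[coh["visit"] == "baseline"]
        fup = coh[coh["visit"] == "followup"]
        assert int(base[column].notna().sum()) == n_base
        assert int(fup[column].notna().sum()) == n_fup

    def test_seed_determinism(self):
        a = generate_cohort(CohortConfig(seed=7))
        b = generate_cohort(CohortConfig(seed=7))
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(CohortConfig(seed=8))
        assert not a.drop(columns=["subject_id", "group", "visit"]).equals(
            c.drop(columns=["subject_id", "group", "visit"])
        )

    def test_degenerate_spread_pins_values_to_location(self):
        spec = OutcomeSpec(name="flat", baseline_location=50.0, baseline_spread=0.0, followup_shift=3.0)
        config = CohortConfig(outcome_specs=(spec,), seed=1)
        coh = generate_cohort(config)
        assert (coh.loc[coh["visit"] == "baseline", "flat"] == 50.0).all()
        assert (coh.loc[coh["visit"] == "followup", "flat"] == 53.0).all()

    def test_large_cohort_calibration_median_iqr(self):
        """Empirical medians/IQRs converge to the configured targets (2% relative).

        The cohort is large enough that even the most skewed outcome's
        median has a Monte Carlo SE well inside the 2% band.
        """
        config = CohortConfig(n_group_a=20000, n_group_b=20000, seed=3)
        coh = generate_cohort(config)
        base = coh[coh["visit"] == "baseline"]
        fup = coh[coh["visit"] == "followup"]
        for spec in config.outcome_specs:
            if spec.scale != "continuous" or spec.baseline_location == 0:
                continue
            q1, med, q3 = np.nanquantile(base[spec.name].astype(float), [0.25, 0.5, 0.75])
            assert med == pytest.approx(spec.baseline_location, rel=0.02), spec.name
            assert q3 - q1 == pytest.approx(spec.baseline_spread, rel=0.02), spec.name
            fmed = np.nanmedian(fup[spec.name].astype(float))
            assert fmed == pytest.approx(spec.baseline_location + spec.followup_shift, rel=0.02), spec.name
        # zero-median outcome checked absolutely
        alc = base["alcohol"].astype(float)
        assert np.nanmedian(alc) == pytest.approx(0.0, abs=0.3)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            OutcomeSpec(name="x", missing_baseline=200).validate(124)
        with pytest.raises(ConfigurationError):
            OutcomeSpec(name="x", scale="fancy").validate(124)
        with pytest.raises(ConfigurationError):
            CohortConfig(treatment_props={"a": 0.5, "b": 0.2}).validate()

    def test_default_specs_cover_seventeen_outcomes(self):
        specs = default_outcome_specs()
        assert len(specs) == 17
        assert sum(s.scale == "continuous" for s in specs) == 15
        assert sum(s.scale == "categorical" for s in specs) == 2
        names = {s.name for s in specs}
        for _, col in study.ANALYSIS_OUTCOMES:
            root = col.replace("smoker_yes", "smoke_habits").replace(
                "physical_activity_moderate_intense", "physical_activity"
            )
            assert root in names


class TestPowerDataset:
    def test_cell_means_follow_the_generative_model(self):
        """Mean of the exposed arm at follow-up is b0+bt+bg+bgt = 58.7 at large n."""
        d = generate_power_dataset(PowerDesignConfig(n_total=40000, allocation=(20000, 20000), seed=4))
        cad_fup = d[(d["cad"] == 1) & (d["time"] == 1)]["y"]
        assert cad_fup.mean() == pytest.approx(51 + 2.6 * 3, abs=0.1)
        ctl_base = d[(d["cad"] == 0) & (d["time"] == 0)]["y"]
        assert ctl_base.mean() == pytest.approx(51, abs=0.1)
        assert ctl_base.std() == pytest.approx(3.3, rel=0.02)

    def test_within_subject_correlation_matches_icc(self):
        d = generate_power_dataset(PowerDesignConfig(n_total=10000, allocation=(5000, 5000), icc=0.5, seed=9))
        wide = d.pivot(index="subject_id", columns="time", values="y")
        # remove the group/time mean structure before correlating
        cad = d.groupby("subject_id")["cad"].first()
        for t in (0, 1):
            wide[t] = wide[t] - wide.groupby(cad)[t].transform("mean")
        r = np.corrcoef(wide[0], wide[1])[0, 1]
        assert r == pytest.approx(0.5, abs=0.02)

    def test_change_score_variance_cancels_subject_effect(self):
        cfg = PowerDesignConfig(n_total=10000, allocation=(5000, 5000), icc=0.55, seed=2)
        d = generate_power_dataset(cfg)
        ctl = d[d["cad"] == 0].pivot(index="subject_id", columns="time", values="y")
        change = ctl[1] - ctl[0]
        assert change.var() == pytest.approx(2 * cfg.sigma_e2, rel=0.05)

    def test_zero_icc_gives_uncorrelated_visits(self):
        cfg = PowerDesignConfig(
            n_total=4000, allocation=(2000, 2000), icc=0.0,
            beta_time=0.0, beta_group=0.0, beta_interaction=0.0, seed=6,
        )
        wide = generate_power_dataset(cfg).pivot(index="subject_id", columns="time", values="y")
        assert abs(np.corrcoef(wide[0], wide[1])[0, 1]) < 0.05

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ConfigurationError):
            PowerDesignConfig(icc=1.0).validate()
        with pytest.raises(ConfigurationError):
            PowerDesignConfig(sd_total=0.0).validate()
        with pytest.raises(ConfigurationError):
            PowerDesignConfig(n_total=100, allocation=(62, 62)).validate()
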