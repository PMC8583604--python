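"""Random-intercept mixed model: identities, invariances, oracles."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twovisit.cohort import PowerDesignConfig, generate_power_dataset
from twovisit.lmm import (
    EstimationError,
    LmmFit,
    ModelSpec,
    RandomInterceptLMM,
    fit_random_intercept_lmm,
    wald_p,
)

from conftest import design_from


def _full_spec(time_coding="visit", estimation="reml"):
    return ModelSpec(
        outcome="y",
        fixed_terms=("intercept", "time", "group", "group:time"),
        time_coding=time_coding,
        estimation=estimation,
    )


class TestClosedFormIdentities:
    def test_interaction_equals_difference_of_mean_changes(self, balanced_two_period):
        """On complete balanced two-period data the GLS interaction estimate
        is the between-group difference of mean change scores."""
        fit = fit_random_intercept_lmm(balanced_two_period, _full_spec())
        assert fit.estimates["group:time"] == pytest.approx(3.0, abs=1e-10)
        assert fit.estimates["time"] == pytest.approx(2.0, abs=1e-10)
        # the fixture's changes are identical within group so the residual
        # variance sits at its boundary; cross-sectional contrasts are only
        # good to optimiser precision there
        assert fit.estimates["intercept"] == pytest.approx(12.0, abs=1e-5)
        assert fit.estimates["group"] == pytest.approx(9.0, abs=1e-5)

    def test_no_subject_variance_collapses_to_ols(self):
        rng = np.random.default_rng(0)
        d = generate_power_dataset(PowerDesignConfig(icc=0.0, seed=10), rng=rng)
        X = design_from(d)
        m = RandomInterceptLMM(method="ml").fit(X, d["y"], groups=d["subject_id"])
        assert m.sigma_b2_ <= 0.05 * m.sigma_e2_
        ols = np.linalg.lstsq(np.column_stack([np.ones(len(d)), X]), d["y"].to_numpy(), rcond=None)[0]
        # with sigma_b ~ 0 the GLS weights are near-uniform
        assert np.allclose(m.params_, ols, atol=0.02)

    def test_ml_reml_fixed_effects_agree(self, power_dataset):
        X = design_from(power_dataset)
        y, g = power_dataset["y"], power_dataset["subject_id"]
        ml = RandomInterceptLMM(method="ml").fit(X, y, groups=g)
        reml = RandomInterceptLMM(method="reml").fit(X, y, groups=g)
        # balanced complete design: GLS estimates coincide, REML variances larger
        assert np.allclose(ml.params_, reml.params_, rtol=1e-6)
        assert reml.sigma_e2_ >= ml.sigma_e2_ - 1e-12
        assert reml.sigma_b2_ + reml.sigma_e2_ >= ml.sigma_b2_ + ml.sigma_e2_ - 1e-9

    def test_unbalanced_subjects_contribute_single_visits(self, power_dataset):
        d = power_dataset.copy()
        drop = d[(d["time"] == 1) & (d["subject_id"].isin(d["subject_id"].unique()[:10]))].index
        d = d.drop(index=drop)
        fit = fit_random_intercept_lmm(d, _full_spec())
        assert fit.n_observations == 2 * 124 - 10
        assert fit.n_subjects == 124
        assert fit.converged


class TestInvariances:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(shift=st.floats(-1e3, 1e3, allow_nan=False))
    def test_location_invariance(self, shift):
        d = generate_power_dataset(PowerDesignConfig(seed=21))
        X = design_from(d)
        base = RandomInterceptLMM().fit(X, d["y"], groups=d["subject_id"])
        moved = RandomInterceptLMM().fit(X, d["y"] + shift, groups=d["subject_id"])
        assert moved.params_[0] == pytest.approx(base.params_[0] + shift, abs=1e-8 * (1 + abs(shift)))
        assert np.allclose(moved.params_[1:], base.params_[1:], atol=1e-9)
        assert np.allclose(moved.bse_, base.bse_, atol=1e-9)
        assert moved.sigma_b2_ == pytest.approx(base.sigma_b2_, rel=1e-5)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3, allow_nan=False))
    def test_scale_equivariance(self, scale):
        d = generate_power_dataset(PowerDesignConfig(seed=22))
        X = design_from(d)
        base = RandomInterceptLMM().fit(X, d["y"], groups=d["subject_id"])
        scaled = RandomInterceptLMM().fit(X, d["y"] * scale, groups=d["subject_id"])
        assert np.allclose(scaled.params_, base.params_ * scale, rtol=1e-7)
        assert np.allclose(scaled.bse_, base.bse_ * scale, rtol=1e-6)
        assert scaled.sigma_e2_ == pytest.approx(base.sigma_e2_ * scale**2, rel=1e-6)


class TestOracle:
    def test_agrees_with_statsmodels_mixedlm(self, power_dataset):
        import statsmodels.formula.api as smf

        X = design_from(power_dataset)
        m = RandomInterceptLMM().fit(X, power_dataset["y"], groups=power_dataset["subject_id"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm = smf.mixedlm("y ~ time*cad", power_dataset, groups=power_dataset["subject_id"]).fit(
                reml=True, method="powell"
            )
        assert np.allclose(m.params_, sm.fe_params.values, rtol=1e-6)
        assert np.allclose(m.bse_, sm.bse_fe.values, rtol=1e-4)
        assert m.sigma_b2_ == pytest.approx(float(sm.cov_re.iloc[0, 0]), rel=1e-3)
        assert m.sigma_e2_ == pytest.approx(float(sm.scale), rel=1e-3)


class TestWaldP:
    def test_normal_quantile_identity(self):
        fit = LmmFit(terms=("intercept", "group"), estimates={"group": 1.959964, "intercept": 0.0},
                     standard_errors={"group": 1.0, "intercept": 1.0})
        assert wald_p(fit, "group") == pytest.approx(0.05, abs=1e-6)

    def test_zero_estimate_gives_p_one(self):
        fit = LmmFit(terms=("group",), estimates={"group": 0.0}, standard_errors={"group": 2.0})
        assert wald_p(fit, "group") == 1.0

    def test_normal_tail(self):
        # z = 2.6 / 0.5927 = 4.3867 -> two-sided normal tail 1.1508e-5
        fit = LmmFit(terms=("group",), estimates={"group": 2.6}, standard_errors={"group": 0.5927})
        assert wald_p(fit, "group") == pytest.approx(1.1508e-5, rel=1e-3)

    def test_degenerate_se_warns(self):
        fit = LmmFit(terms=("group",), estimates={"group": 1.0}, standard_errors={"group": 0.0})
        with pytest.warns(UserWarning):
            assert wald_p(fit, "group") == 0.0

    def test_unknown_term_raises(self):
        fit = LmmFit(terms=("group",), estimates={"group": 1.0}, standard_errors={"group": 1.0})
        with pytest.raises(KeyError):
            wald_p(fit, "time")


class TestValidation:
    def test_all_missing_outcome_is_an_error(self, power_dataset):
        d = power_dataset.copy()
        d["y"] = np.nan
        with pytest.raises(EstimationError):
            fit_random_intercept_lmm(d, _full_spec())

    def test_model_spec_invariants(self):
        with pytest.raises(ValueError):
            ModelSpec(outcome="y", fixed_terms=("time",)).validate()
        with pytest.raises(ValueError):
            ModelSpec(outcome="y", fixed_terms=("intercept", "time", "group:time")).validate()
        with pytest.raises(ValueError):
            ModelSpec(outcome="y", time_coding="hours").validate()

    def test_groups_required(self, power_dataset):
        with pytest.raises(ValueError):
            RandomInterceptLMM().fit(design_from(power_dataset), power_dataset["y"])
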