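"""Prediction errors, external validation, forecasting, target attainment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pzapk import (
    ModelRegistry,
    PopulationParameters,
    ape,
    concentration_ss,
    external_validate,
    forecast_cohort,
    forecast_individual,
    impute_blq,
    mpe,
    prediction_records,
    simulate_dataset,
    study_design,
    subgroup_summary,
    target_attainment,
)
from pzapk.modelspec import final_model_spec

from conftest import make_subject


class TestPredictionErrors:
    def test_worked_arithmetic(self):
        rec = pd.DataFrame({"pred": [12.0, 10.0], "obs": [11.0, 12.0]})
        assert mpe(rec) == pytest.approx(-0.5)
        assert ape(rec) == pytest.approx(1.5)

    def test_perfect_predictions(self):
        rec = pd.DataFrame({"pred": [5.0, 9.0], "obs": [5.0, 9.0]})
        assert mpe(rec) == 0.0 and ape(rec) == 0.0

    def test_single_record_ape_equals_abs_mpe(self):
        rec = pd.DataFrame({"pred": [12.0], "obs": [9.5]})
        assert ape(rec) == abs(mpe(rec))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0, 60, allow_nan=False), st.floats(0, 60, allow_nan=False)),
            min_size=1,
            max_size=40,
        )
    )
    def test_ape_dominates_mpe_universally(self, pairs):
        rec = pd.DataFrame(pairs, columns=["pred", "obs"])
        assert ape(rec) >= abs(mpe(rec)) - 1e-12

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            mpe(pd.DataFrame({"pred": [], "obs": []}))


@pytest.fixture(scope="module")
def test_set():
    """Simulated external test cohort under the reference model."""
    subjects, _ = simulate_dataset(study_design(120), seed=77)
    return impute_blq(subjects)


class TestExternalValidation:
    def test_self_model_is_unbiased(self, test_set):
        pp = PopulationParameters.from_cv_percent()
        summary = external_validate(test_set, pp, mode="population")
        assert summary.mpe_ci[0] < 0 < summary.mpe_ci[1]
        assert summary.ape >= abs(summary.mpe)
        assert summary.n == sum(len(s.observations) for s in test_set)

    def test_inflated_clearance_underpredicts(self, test_set):
        fast = PopulationParameters.from_cv_percent(theta_cl=2 * 4.49)
        summary = external_validate(test_set, fast, mode="population")
        assert summary.mpe < 0

    def test_individual_mode_tightens_errors(self):
        subjects, _ = simulate_dataset(
            study_design(80, inpatient_fraction=1.0), seed=31
        )
        subjects = impute_blq(subjects)
        pp = PopulationParameters.from_cv_percent()
        pop = external_validate(subjects, pp, mode="population")
        ind = external_validate(subjects, pp, mode="individual")
        assert ind.ape <= pop.ape

    def test_mode_is_recorded_on_records(self, test_set):
        pp = PopulationParameters.from_cv_percent()
        spec = final_model_spec(pp)
        rec = prediction_records(test_set, spec, spec.paramset_from_population(pp),
                                 mode="individual")
        assert (rec["mode"] == "individual").all()


class TestModelRegistry:
    def test_duplicate_label_rejected(self):
        reg = ModelRegistry()
        reg.register("final", PopulationParameters.from_cv_percent())
        with pytest.raises(KeyError):
            reg.register("final", PopulationParameters.from_cv_percent())

    def test_yaml_round_trip(self, tmp_path):
        reg = ModelRegistry()
        reg.register("final", PopulationParameters.from_cv_percent())
        reg.register("perturbed", PopulationParameters.from_cv_percent(theta_cl=6.5))
        path = tmp_path / "registry.yaml"
        reg.to_yaml(path)
        back = ModelRegistry.from_yaml(path)
        assert back.labels() == ["final", "perturbed"]
        assert back["perturbed"].theta_cl == 6.5

    def test_true_model_beats_perturbed_comparator(self, test_set):
        reg = ModelRegistry()
        reg.register("final", PopulationParameters.from_cv_percent())
        reg.register("perturbed", PopulationParameters.from_cv_percent(theta_cl=9.0, theta_v=25.0))
        table = reg.validate_all(test_set, modes=("population",)).set_index("model")
        assert table.loc["final", "APE"] < table.loc["perturbed", "APE"]


class TestForecasting:
    def test_subject_on_typical_profile(self):
        pred = concentration_ss(4.49, 44.2, 1.49, 1500.0, 24.0, 2.0)
        subject = make_subject("a", ((2.0, float(pred)),))
        est = forecast_individual(subject, PopulationParameters.from_cv_percent())
        assert est.auc_0_24 == pytest.approx(1200.0 / 4.49, rel=1e-3)
        assert est.subgroup == "<70/noDM"

    def test_geriatric_dm_subject_forecast(self):
        pred = concentration_ss(5.9268, 44.2, 1.49, 1500.0, 24.0, 2.0)
        subject = make_subject("a", ((2.0, float(pred)),), age=75.0, dm=True)
        est = forecast_individual(subject, PopulationParameters.from_cv_percent())
        assert est.auc_0_24 == pytest.approx(1200.0 / 5.9268, rel=1e-3)
        assert est.subgroup == ">=70/DM"

    def test_higher_observed_clearance_lowers_forecast_auc(self):
        c_slow = float(concentration_ss(4.49, 44.2, 1.49, 1500.0, 24.0, 5.0))
        c_fast = float(concentration_ss(8.98, 44.2, 1.49, 1500.0, 24.0, 5.0))
        pp_wide = PopulationParameters.from_cv_percent(iiv_cv=(80.0, 3.0, 100.0))
        slow = forecast_individual(make_subject("a", ((5.0, c_slow),)), pp_wide)
        fast = forecast_individual(make_subject("b", ((5.0, c_fast),)), pp_wide)
        assert fast.cl > slow.cl
        assert fast.auc_0_24 < slow.auc_0_24

    def test_requires_observations(self):
        s = make_subject("a", ())
        with pytest.raises(ValueError):
            forecast_individual(s, PopulationParameters.from_cv_percent())


class TestTargetsAndSubgroups:
    def test_typical_exposure_misses_auc_target(self):
        est = pd.DataFrame({"auc_0_24": [1200.0 / 4.49], "cmax": [25.0]})
        attain = target_attainment(est)
        assert attain["auc"] == 0.0

    def test_inclusive_boundary(self):
        est = pd.DataFrame({"auc_0_24": [363.0], "cmax": [30.0]})
        attain = target_attainment(est)
        assert attain["auc"] == 1.0 and attain["cmax"] == 1.0 and attain["both"] == 1.0

    def test_empty_estimates_rejected(self):
        with pytest.raises(ValueError):
            target_attainment(pd.DataFrame({"auc_0_24": [], "cmax": []}))

    def test_identical_subjects_have_degenerate_summary(self):
        est = pd.DataFrame(
            {"auc_0_24": [200.0] * 5, "cmax": [25.0] * 5, "cl": [6.0] * 5,
             "subgroup": ["<70/noDM"] * 5}
        )
        summary = subgroup_summary(est)
        assert summary.loc["<70/noDM", "n"] == 5
        assert summary.loc["<70/noDM", "auc_0_24_q3"] == summary.loc["<70/noDM", "auc_0_24_q1"]

    def test_geriatric_dm_group_has_highest_clearance(self):
        subjects, _ = simulate_dataset(study_design(250), seed=55)
        subjects = impute_blq(subjects)
        est = forecast_cohort(subjects, PopulationParameters.from_cv_percent())
        summary = subgroup_summary(est)
        if ">=70/DM" in summary.index and len(summary) > 1:
            others = summary.drop(">=70/DM")
            assert summary.loc[">=70/DM", "cl_median"] > others["cl_median"].max()
        assert (summary["n"] > 0).all()
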