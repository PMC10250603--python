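"""Structural model and covariate machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pzapk import (
    CovariateSet,
    DosingRegimen,
    IndividualPK,
    PopulationParameters,
    allometric_factor,
    auc_0_24_ss,
    categorical_covariate_factor,
    cmax_ss,
    conc_ss,
    concentration_single_dose,
    concentration_ss,
    individual_parameters,
    is_geriatric_dm,
    lean_body_weight,
    power_covariate_factor,
)
from pzapk.pk import ParameterDomainError

TYPICAL = dict(cl=4.49, v=44.2, ka=1.49)


def ss_by_superposition(cl, v, ka, dose, tau, t, n_doses=200):
    """Independent oracle: sum of consecutive single-dose profiles."""
    return sum(concentration_single_dose(cl, v, ka, dose, t + m * tau) for m in range(n_doses))


class TestConcSS:
    def test_typical_value_matches_superposition_oracle(self):
        # frozen from the >=50-dose superposition oracle at the typical
        # parameters (1500 mg, t = 2 h)
        pk = IndividualPK(**TYPICAL)
        reg = DosingRegimen(dose=1500.0)
        assert conc_ss(pk, reg, 2.0) == pytest.approx(30.718, abs=0.05)

    @pytest.mark.parametrize("t", [0.5, 2.0, 7.5, 23.0])
    @pytest.mark.parametrize("cl,v,ka", [(4.49, 44.2, 1.49), (8.0, 30.0, 0.6), (2.0, 60.0, 3.0)])
    def test_superposition_property(self, cl, v, ka, t):
        closed = concentration_ss(cl, v, ka, 1500.0, 24.0, t)
        oracle = ss_by_superposition(cl, v, ka, 1500.0, 24.0, t)
        assert closed == pytest.approx(oracle, rel=1e-4)

    def test_periodic_at_interval_ends(self):
        pk = IndividualPK(**TYPICAL)
        reg = DosingRegimen(dose=1500.0)
        assert conc_ss(pk, reg, 0.0) == pytest.approx(conc_ss(pk, reg, 24.0), rel=1e-12)

    def test_zero_dose_gives_zero(self):
        assert np.all(concentration_ss(4.49, 44.2, 1.49, 0.0, 24.0, np.linspace(0, 24, 9)) == 0)

    def test_continuous_across_flipflop_switch(self):
        # ka values straddling the degeneracy tolerance differ by a hair,
        # so any visible jump would come from the branch switch itself
        ke = 3.0 / 30.0
        ka_inside = ke * (1 - 0.99e-6)  # limit branch
        ka_outside = ke * (1 - 1.01e-6)  # general branch
        for t in (0.0, 1.0, 5.0, 23.0):
            c_in = concentration_ss(3.0, 30.0, ka_inside, 1000.0, 24.0, t)
            c_out = concentration_ss(3.0, 30.0, ka_outside, 1000.0, 24.0, t)
            assert abs(c_in - c_out) < 1e-6

    def test_time_domain_checked(self):
        pk = IndividualPK(**TYPICAL)
        with pytest.raises(ValueError):
            conc_ss(pk, DosingRegimen(dose=1500.0), 25.0)

    def test_positive_parameters_required(self):
        with pytest.raises(ParameterDomainError):
            IndividualPK(cl=-1.0, v=44.2, ka=1.49)


class TestExposure:
    def test_auc_is_dose_over_clearance(self):
        pk = IndividualPK(**TYPICAL)
        assert auc_0_24_ss(pk, DosingRegimen(dose=1500.0)) == pytest.approx(334.08, abs=0.01)
        gdm = IndividualPK(cl=5.9268, v=44.2, ka=1.49)
        assert auc_0_24_ss(gdm, DosingRegimen(dose=1200.0)) == pytest.approx(202.47, abs=0.01)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        cl=st.floats(1.0, 12.0),
        v=st.floats(15.0, 90.0),
        ka=st.floats(0.3, 4.0),
        dose=st.floats(500.0, 2000.0),
    )
    def test_auc_matches_trapezoid_integral(self, cl, v, ka, dose):
        grid = np.linspace(0.0, 24.0, 10_001)
        numeric = np.trapezoid(concentration_ss(cl, v, ka, dose, 24.0, grid), grid)
        assert dose / cl == pytest.approx(numeric, rel=1e-3)

    def test_auc_halves_when_clearance_doubles(self):
        reg = DosingRegimen(dose=1500.0)
        a1 = auc_0_24_ss(IndividualPK(**TYPICAL), reg)
        a2 = auc_0_24_ss(IndividualPK(cl=2 * TYPICAL["cl"], v=44.2, ka=1.49), reg)
        assert a2 == pytest.approx(a1 / 2)

    def test_cmax_matches_fine_grid_oracle(self):
        pk = IndividualPK(**TYPICAL)
        reg = DosingRegimen(dose=1500.0)
        cmax, tmax = cmax_ss(pk, reg)
        grid = np.arange(0.0, 24.0, 1e-3)
        oracle = concentration_ss(pk.cl, pk.v, pk.ka, 1500.0, 24.0, grid)
        assert cmax == pytest.approx(oracle.max(), abs=1e-4)
        assert tmax == pytest.approx(grid[oracle.argmax()], abs=5e-3)
        assert 1.5 < tmax < 2.2

    def test_cmax_bounds_profile(self):
        pk = IndividualPK(cl=6.0, v=30.0, ka=0.8)
        reg = DosingRegimen(dose=1000.0)
        cmax, _ = cmax_ss(pk, reg)
        assert cmax >= concentration_ss(6.0, 30.0, 0.8, 1000.0, 24.0, np.linspace(0, 24, 200)).max()

    def test_cmax_decreases_in_volume(self):
        reg = DosingRegimen(dose=1500.0)
        cmaxes = [cmax_ss(IndividualPK(cl=4.49, v=v, ka=1.49), reg)[0] for v in (30, 44.2, 60, 90)]
        assert np.all(np.diff(cmaxes) < 0)

    def test_cmax_approaches_bolus_limit_for_fast_absorption(self):
        # Ka -> inf: peak tends to the accumulation-corrected bolus peak at t -> 0
        pk = IndividualPK(cl=4.49, v=44.2, ka=500.0)
        reg = DosingRegimen(dose=1500.0)
        cmax, tmax = cmax_ss(pk, reg)
        ke = pk.cl / pk.v
        bolus = 1500.0 / pk.v / (1 - np.exp(-ke * 24.0))
        assert cmax == pytest.approx(bolus, rel=0.02)
        assert tmax < 0.1


class TestCovariateFactors:
    def test_power_factor_identities(self):
        assert power_covariate_factor(50.0, 50.0, 0.75) == 1.0
        assert power_covariate_factor(200.0, 50.0, 0.75) == pytest.approx(2.8284, abs=1e-4)
        assert power_covariate_factor(7.0, 50.0, 0.0) == 1.0
        with pytest.raises(ParameterDomainError):
            power_covariate_factor(-1.0, 50.0, 0.75)

    def test_categorical_factor_reproduces_geriatric_dm_clearance(self):
        # published: CL 4.49 L/h, +32% for geriatric DM -> 5.9 L/h
        assert 4.49 * categorical_covariate_factor(0.32, True) == pytest.approx(5.9268)
        assert 4.49 * categorical_covariate_factor(0.32, False) == 4.49
        assert categorical_covariate_factor(0.0, True) == 1.0
        with pytest.raises(ParameterDomainError):
            categorical_covariate_factor(-1.5, True)

    def test_allometric_factor(self):
        assert allometric_factor(48.0) == 1.0
        assert allometric_factor(24.0, 48.0, 0.75) == pytest.approx(0.5946, abs=1e-4)
        assert allometric_factor(24.0, 48.0, 1.0) == 0.5

    @pytest.mark.parametrize(
        "age,dm,expected", [(70.0, True, True), (69.0, True, False), (85.0, False, False)]
    )
    def test_geriatric_dm_indicator(self, age, dm, expected):
        assert is_geriatric_dm(age, dm) is expected

    def test_reference_subject_has_unit_factors(self):
        pp = PopulationParameters.from_cv_percent()
        cov = CovariateSet(age=50.0, sex="M", body_weight=60.0, lean_body_weight=48.0, dm=False)
        pk = individual_parameters(pp, cov)
        assert (pk.cl, pk.v, pk.ka) == pytest.approx((4.49, 44.2, 1.49))

    def test_individual_parameters_compose(self):
        pp = PopulationParameters.from_cv_percent()
        gdm = CovariateSet(age=75.0, sex="M", body_weight=60.0, lean_body_weight=48.0, dm=True)
        assert individual_parameters(pp, gdm).cl == pytest.approx(5.9268)
        small = CovariateSet(age=50.0, sex="F", body_weight=30.0, lean_body_weight=24.0)
        pk = individual_parameters(pp, small)
        assert pk.cl == pytest.approx(4.49 * 0.5946, abs=2e-3)
        assert pk.v == pytest.approx(22.1)

    def test_eta_acts_lognormally(self):
        pp = PopulationParameters.from_cv_percent()
        cov = CovariateSet(age=50.0, sex="M", body_weight=60.0, lean_body_weight=48.0)
        pk = individual_parameters(pp, cov, eta=(0.2, -0.1, 0.5))
        assert pk.cl == pytest.approx(4.49 * np.exp(0.2))
        assert pk.v == pytest.approx(44.2 * np.exp(-0.1))
        assert pk.ka == pytest.approx(1.49 * np.exp(0.5))


def test_lean_body_weight_formula_is_sex_specific():
    m = lean_body_weight(70.0, 175.0, "M")
    f = lean_body_weight(70.0, 175.0, "F")
    assert 50 < m < 62 and 40 < f < 52 and m > f
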