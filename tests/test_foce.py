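"""FOCE-I objective, conditional modes and shrinkage."""

import numpy as np
import pytest
from scipy import integrate

from pzapk import (
    CovariateEffect,
    FoceEngine,
    ModelSpec,
    concentration_ss,
    estimate_ebe,
    eta_shrinkage,
    foce_ofv,
)

from conftest import make_subject


def single_eta_cl_spec(omega_cl=0.2, sigma=2.0):
    """Toy spec: no covariates, random effect on CL only (V/Ka IIV ~ 0)."""
    return ModelSpec(
        effects=(),
        theta_init={"cl": 4.49, "v": 44.2, "ka": 1.49},
        omega_init={"cl": omega_cl, "v": 1e-4, "ka": 1e-4},
        omega_fixed=frozenset({"v", "ka"}),
        sigma_init=sigma,
    )


def paramset(spec, **over):
    return spec.initial_paramset(over)


class TestFoceObjective:
    def test_omega_to_zero_limit_is_pooled_likelihood(self):
        """With no random effects the OFV is the pooled fixed-effects
        -2 log-likelihood (2*pi constants dropped)."""
        spec = ModelSpec(
            effects=(),
            omega_init={"cl": 1e-4, "v": 1e-4, "ka": 1e-4},
            omega_fixed=frozenset({"cl", "v", "ka"}),
            sigma_init=3.41,
        )
        subjects = [
            make_subject("a", ((2.0, 28.0), (5.0, 30.0))),
            make_subject("b", ((1.0, 22.0),)),
        ]
        ps = paramset(spec)
        got = foce_ofv(subjects, spec, ps)
        t = np.array([2.0, 5.0, 1.0])
        y = np.array([28.0, 30.0, 22.0])
        f = concentration_ss(4.0, 40.0, 1.5, 1500.0, 24.0, t)
        expected = np.sum(np.log(3.41**2) + (y - f) ** 2 / 3.41**2)
        assert got == pytest.approx(expected, abs=1e-3)

    def test_single_observation_at_prediction_closed_form(self):
        """One subject, one observation equal to the prediction: eta_hat = 0
        and OFV = log(sigma^2 + J Omega J')."""
        spec = single_eta_cl_spec(omega_cl=0.2, sigma=3.41)
        ps = paramset(spec)
        pred = concentration_ss(4.49, 44.2, 1.49, 1500.0, 24.0, 2.0)
        subject = make_subject("a", ((2.0, float(pred)),))
        eng = FoceEngine([subject], spec)
        eta, nfail = eng.eta_modes(ps, eta0=np.zeros((1, 3)))
        assert nfail == 0
        assert np.abs(eta).max() < 1e-6
        # independent sensitivity of the prediction to eta_cl
        h = 1e-6
        j = (
            concentration_ss(4.49 * np.exp(h), 44.2, 1.49, 1500.0, 24.0, 2.0)
            - concentration_ss(4.49 * np.exp(-h), 44.2, 1.49, 1500.0, 24.0, 2.0)
        ) / (2 * h)
        expected = np.log(3.41**2 + 0.2**2 * j**2)
        assert eng.ofv(ps) == pytest.approx(expected, rel=1e-4)

    def test_matches_adaptive_quadrature_oracle_on_toy(self):
        """OFV differences agree with -2 log marginal-likelihood ratios
        computed by adaptive quadrature over eta, within 2%."""
        omega, sigma = 0.2, 2.0
        spec = single_eta_cl_spec(omega, sigma)
        obs1 = ((1.0, 24.0), (2.0, 29.0), (5.0, 30.0), (8.0, 26.0), (12.0, 18.0))
        obs2 = ((1.0, 27.0), (2.0, 33.0), (5.0, 35.0), (8.0, 30.0), (12.0, 22.0))
        subjects = [make_subject("a", obs1), make_subject("b", obs2)]
        eng = FoceEngine(subjects, spec)

        def quad_m2ll(theta_cl):
            total = 0.0
            for s in subjects:
                ts = np.array([o.time for o in s.observations])
                ys = np.array([o.conc for o in s.observations])

                def integrand(e):
                    f = concentration_ss(theta_cl * np.exp(e), 44.2, 1.49, 1500.0, 24.0, ts)
                    lik = np.prod(
                        np.exp(-((ys - f) ** 2) / (2 * sigma**2)) / (np.sqrt(2 * np.pi) * sigma)
                    )
                    return lik * np.exp(-(e**2) / (2 * omega**2)) / (np.sqrt(2 * np.pi) * omega)

                val, _ = integrate.quad(integrand, -10 * omega, 10 * omega, limit=400)
                total += -2 * np.log(val)
            return total

        d_foce = eng.ofv(paramset(spec, theta_cl=5.5)) - eng.ofv(paramset(spec, theta_cl=4.49))
        d_quad = quad_m2ll(5.5) - quad_m2ll(4.49)
        assert d_foce == pytest.approx(d_quad, rel=0.02)

    def test_unused_parameter_leaves_ofv_unchanged(self):
        subjects = [make_subject("a", ((2.0, 28.0), (5.0, 30.0)))]
        spec = single_eta_cl_spec()
        null_effect = CovariateEffect(
            name="renal_cl", parameter="cl", kind="categorical", column="renal_disease", init=0.0
        )
        augmented = spec.with_effect(null_effect)
        ps = paramset(spec)
        ps_aug = paramset(augmented, theta_renal_cl=0.0)
        assert foce_ofv(subjects, augmented, ps_aug) == pytest.approx(
            foce_ofv(subjects, spec, ps), rel=1e-10
        )


class TestEmpiricalBayes:
    def test_observation_on_population_curve_gives_zero_eta(self):
        spec = single_eta_cl_spec()
        ps = paramset(spec)
        pred = concentration_ss(4.49, 44.2, 1.49, 1500.0, 24.0, 5.0)
        eta, pk, ipred = estimate_ebe(make_subject("a", ((5.0, float(pred)),)), spec, ps)
        assert np.abs(eta).max() < 1e-6
        assert ipred[0] == pytest.approx(pred, abs=1e-6)

    def test_high_observation_pulls_clearance_down(self):
        """An observation above the population curve at 5 h implies slower
        elimination: eta_CL < 0, matching a 1-D grid-search oracle."""
        spec = single_eta_cl_spec(omega_cl=0.3, sigma=2.0)
        ps = paramset(spec)
        pred = concentration_ss(4.49, 44.2, 1.49, 1500.0, 24.0, 5.0)
        y = float(pred) + 8.0
        eta, pk, _ = estimate_ebe(make_subject("a", ((5.0, y),)), spec, ps)
        assert eta[0] < 0
        # oracle: dense grid over eta_cl for the penalised objective
        grid = np.linspace(-1.5, 1.5, 20_001)
        f = concentration_ss(4.49 * np.exp(grid), 44.2, 1.49, 1500.0, 24.0, 5.0)
        obj = (y - f) ** 2 / 2.0**2 + grid**2 / 0.3**2
        assert eta[0] == pytest.approx(grid[obj.argmin()], abs=1e-3)

    def test_ebe_equals_inner_mode_of_objective(self):
        spec = single_eta_cl_spec()
        ps = paramset(spec)
        subject = make_subject("a", ((2.0, 24.0), (5.0, 33.0)))
        eta_op, _, _ = estimate_ebe(subject, spec, ps)
        eng = FoceEngine([subject], spec)
        eng.ofv(ps)  # runs the inner search and caches its modes
        assert eta_op == pytest.approx(eng._eta_cache[0], abs=1e-9)


class TestShrinkage:
    def test_definition_and_clipping(self):
        rng = np.random.default_rng(0)
        omega = np.array([0.5, 0.3, 1.0])
        draws = rng.normal(0, 1, (4000, 3)) * omega
        shr = eta_shrinkage(draws, omega)
        assert np.all(shr < 8.0)  # SD(eta) ~ omega -> ~0%
        assert np.all(eta_shrinkage(np.zeros((10, 3)), omega) == 100.0)

    def test_published_clearance_shrinkage_arithmetic(self):
        # SD(eta_hat) = 0.82 * omega -> 18% shrinkage
        eta = np.array([[0.82], [-0.82]])  # ddof=1 SD = 0.82*sqrt(2), scale below
        sd_target = 0.82
        eta = eta / eta.std(ddof=1) * sd_target
        assert eta_shrinkage(np.c_[eta, eta, eta], np.ones(3))[0] == pytest.approx(18.0)

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            eta_shrinkage(np.zeros((1, 3)), np.ones(3))
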