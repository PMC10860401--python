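"""Chi-square objective, profiles, PLCIs and risk indices, anchored by the
linear-Gaussian closed forms (where the chi-square is exactly quadratic and
the profile-likelihood interval coincides with the Wald interval)."""

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from pracident import (
    ChiSquareObjective,
    ParameterSpace,
    simulate_dataset,
    transform_parameters,
)
from conftest import LinearGaussian


class TestChi2:
    def test_zero_at_generating_point_noise_free(self, epi_model, epi_protocol):
        ds = simulate_dataset(epi_model, epi_protocol, seed=None)
        obj = ChiSquareObjective.from_model(epi_model, ds, use_fast=False)
        assert obj.chi2(epi_model.space.reference) == pytest.approx(0.0, abs=1e-12)

    def test_single_record_arithmetic(self):
        space = ParameterSpace(["a"], [0.0])
        obj = ChiSquareObjective(
            lambda th: np.array([0.0]), y=np.array([1.0]), sd=np.array([0.5]),
            space=space,
        )
        assert obj.chi2([0.0]) == pytest.approx(4.0)

    def test_quadratic_hessian_matches_normal_equations(self, lingauss):
        """Finite-difference Hessian of the objective equals 2 A' W A."""
        obj = lingauss.objective()
        theta0 = lingauss.theta_hat
        h = 1e-4
        p = len(theta0)
        H = np.empty((p, p))
        for i in range(p):
            for j in range(p):
                ei = np.eye(p)[i] * h
                ej = np.eye(p)[j] * h
                H[i, j] = (
                    obj.chi2(theta0 + ei + ej)
                    - obj.chi2(theta0 + ei - ej)
                    - obj.chi2(theta0 - ei + ej)
                    + obj.chi2(theta0 - ei - ej)
                ) / (4 * h * h)
        assert np.allclose(H, 2.0 * lingauss.hessian_half, rtol=1e-5, atol=1e-6)

    def test_simulation_failure_returns_penalty(self):
        space = ParameterSpace(["a"], [0.0])

        def predict(theta):
            raise RuntimeError("boom")

        obj = ChiSquareObjective(predict, np.array([1.0]), np.array([1.0]), space)
        assert obj.chi2([0.0]) == obj.penalty
        assert obj.n_penalized == 1


class TestFit:
    def test_linear_model_matches_normal_equations(self, lingauss):
        fit = lingauss.objective().fit()
        assert np.allclose(fit.params, lingauss.theta_hat, rtol=1e-6)
        assert fit.chi2_min == pytest.approx(lingauss.chi2_min, rel=1e-8)

    def test_deterministic(self, lingauss):
        f1 = lingauss.objective().fit()
        f2 = lingauss.objective().fit()
        assert np.array_equal(f1.params, f2.params)


class TestProfile:
    def test_profile_matches_parabola(self, lingauss):
        """Profiled chi-square of a linear-Gaussian model equals
        chi2_min + (x - that_i)^2 / se_i^2."""
        fit = lingauss.objective().fit()
        curve = fit.profile(0, stop_rise=6.0)
        expected = lingauss.profile_closed_form(0, curve.grid)
        assert np.allclose(curve.chi2_pl, expected, atol=5e-6, rtol=1e-6)

    def test_minimum_on_curve_equals_global_minimum(self, epi_fit):
        curve = epi_fit.profile("kappa")
        assert curve.chi2_pl.min() >= epi_fit.chi2_min - 1e-6
        assert curve.chi2_pl.min() == pytest.approx(epi_fit.chi2_min, abs=1e-3)

    def test_one_parameter_profile_is_objective_itself(self):
        space = ParameterSpace(["a"], [1.0])
        obj = ChiSquareObjective(
            lambda th: np.array([th[0], 2 * th[0]]),
            y=np.array([1.0, 2.0]),
            sd=np.array([1.0, 1.0]),
            space=space,
        )
        fit = obj.fit()
        curve = fit.profile(0, stop_rise=4.0)
        direct = np.array([obj.chi2([x]) for x in curve.grid])
        assert np.allclose(curve.chi2_pl, direct, atol=1e-12)

    def test_nuisance_argmin_reproduces_profile_value(self, epi_fit):
        curve = epi_fit.profile("mu")
        k = len(curve.grid) // 3
        psi = np.insert(curve.nuisance[k], curve.index, curve.grid[k])
        assert epi_fit.objective.chi2_work(psi) == pytest.approx(
            curve.chi2_pl[k], rel=1e-9
        )


class TestPlci:
    def test_wald_equivalence_linear_gaussian(self, lingauss):
        """For a quadratic objective the PLCI is exactly the Wald interval
        that_i +/- sqrt(Delta(alpha)) * se_i; agreement to 1e-3 relative."""
        fit = lingauss.objective().fit()
        for i in range(3):
            for alpha in (0.5, 0.95):
                ci = fit.plci(i, alpha)
                half = np.sqrt(chi2_dist.ppf(alpha, 1)) * lingauss.se(i)
                assert ci.finite
                assert ci.lower == pytest.approx(
                    lingauss.theta_hat[i] - half, rel=1e-3, abs=1e-3 * half
                )
                assert ci.upper == pytest.approx(
                    lingauss.theta_hat[i] + half, rel=1e-3, abs=1e-3 * half
                )

    def test_interval_shrinks_to_point_as_alpha_vanishes(self, lingauss):
        fit = lingauss.objective().fit()
        ci = fit.plci(0, 1e-6)
        assert ci.length < 1e-2 * lingauss.se(0)

    def test_nesting_across_levels(self, epi_fit):
        levels = [0.5, 0.8, 0.95, 0.99]
        cis = [epi_fit.plci("kappa", a) for a in levels]
        for small, big in zip(cis, cis[1:]):
            assert big.lower <= small.lower + 1e-9
            assert big.upper >= small.upper - 1e-9

    def test_invalid_alpha(self, lingauss):
        fit = lingauss.objective().fit()
        with pytest.raises(ValueError):
            fit.plci(0, 1.5)

    def test_unobserved_parameter_infinite_both_sides(self):
        """A parameter absent from the observation map is practically
        unidentifiable at every level: both sides flagged infinite."""
        lg = LinearGaussian(seed=3, p=3)
        lg.A[:, 2] = 0.0
        fit = lg.objective().fit()
        ci = fit.plci(2, 0.5, box_radius=50.0)
        assert not ci.finite_lower and not ci.finite_upper
        assert ci.length == np.inf


class TestRiskIndex:
    def test_identifiable_parameter_risk_near_one(self, lingauss):
        fit = lingauss.objective().fit()
        rr = fit.risk_index(0)
        assert not rr.unidentifiable
        assert rr.sup_alpha > 0.98
        assert rr.risk == pytest.approx(1.0, abs=0.03)

    def test_risk_supalpha_reciprocal_identity(self, epi_fit):
        for name in ("b", "kappa", "mu"):
            rr = epi_fit.risk_index(name)
            assert rr.risk * rr.sup_alpha == pytest.approx(1.0, abs=1e-12)
            assert rr.risk >= 1.0

    def test_noninfluential_parameter_unidentifiable(self):
        lg = LinearGaussian(seed=3, p=3)
        lg.A[:, 2] = 0.0
        fit = lg.objective().fit()
        rr = fit.risk_index(2, box_radius=50.0)
        assert rr.unidentifiable
        assert rr.risk == np.inf


class TestTransforms:
    def test_roundtrip_identity(self, epi_model):
        tr = transform_parameters(epi_model.space, "log-positive")
        theta = epi_model.space.reference
        back = tr.to_natural(tr.to_working(theta))
        assert np.allclose(back, theta, rtol=1e-15)

    def test_log_value(self, epi_model):
        tr = transform_parameters(epi_model.space, "log-positive")
        psi = tr.to_working(epi_model.space.reference)
        assert psi[2] == pytest.approx(np.log(0.051))

    def test_chi2_invariant_at_matched_points(self, lingauss):
        space = ParameterSpace(
            names=lingauss.space.names,
            reference=lingauss.space.reference,
            positive=(True, True, True),
        )
        obj_id = ChiSquareObjective(
            lambda th: lingauss.A @ th, lingauss.y, lingauss.sd, space
        )
        tr = transform_parameters(space, "log-positive")
        obj_log = ChiSquareObjective(
            lambda th: lingauss.A @ th, lingauss.y, lingauss.sd, space,
            transform=tr,
        )
        theta = lingauss.theta_true * 1.1
        assert obj_log.chi2_work(tr.to_working(theta)) == pytest.approx(
            obj_id.chi2(theta), rel=1e-12
        )

    def test_log_of_nonpositive_reference_rejected(self):
        space = ParameterSpace(["a"], [-1.0], positive=(True,))
        with pytest.raises(ValueError):
            transform_parameters(space, "log-positive")


class TestCoverage:
    def test_plci_covers_truth_at_nominal_rate(self, epi_model, epi_protocol):
        """Over repeated low-noise datasets, the 95% PLCI for the carrying
        capacity contains the true value about 95% of the time."""
        kappa_true = epi_model.space.reference[1]
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            ds = simulate_dataset(epi_model, epi_protocol, seed=10_000 + s)
            fit = ChiSquareObjective.from_model(epi_model, ds).fit()
            ci = fit.plci("kappa", 0.95)
            if ci.finite and ci.lower <= kappa_true <= ci.upper:
                hits += 1
        assert 0.90 <= hits / n_rep <= 1.0
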