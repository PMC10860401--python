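"""Case-study models: log-normal parameterization, growth bookkeeping,
epidemic vector field, weather fixture."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from pracident import simulate
from pracident.models import (
    LnasConstants,
    epidemics_rhs,
    generate_weather,
    lnas_simulate,
    lnas_step,
    lognormal_cdf,
    make_epidemics_model,
    make_lnas_model,
)
from pracident.models.lnas import LNAS_REFERENCE


class TestLognormalCdf:
    def test_median_maps_to_half(self):
        for spread in (10.0, 100.0, 900.0):
            assert lognormal_cdf(500.0, 500.0, spread) == pytest.approx(0.5)

    def test_zero_and_negative_support(self):
        assert lognormal_cdf(0.0, 500.0, 100.0) == 0.0
        assert lognormal_cdf(-3.0, 500.0, 100.0) == 0.0

    def test_quadrature_oracle(self):
        """CDF value agrees with numerical quadrature of the density of the
        chosen parameterization, and the variate's standard deviation really
        equals the spread parameter."""
        median, spread = 500.0, 100.0
        v = (spread / median) ** 2
        s = np.sqrt(np.log((1 + np.sqrt(1 + 4 * v)) / 2))

        def pdf(x):
            return np.exp(-((np.log(x) - np.log(median)) ** 2) / (2 * s**2)) / (
                x * s * np.sqrt(2 * np.pi)
            )

        val, _ = quad(pdf, 1e-9, 700.0, limit=200)
        assert lognormal_cdf(700.0, median, spread) == pytest.approx(val, abs=1e-8)

        mean, _ = quad(lambda x: x * pdf(x), 1e-9, 1e5, limit=400)
        second, _ = quad(lambda x: x**2 * pdf(x), 1e-9, 1e5, limit=400)
        assert np.sqrt(second - mean**2) == pytest.approx(spread, rel=1e-6)

    def test_log_sd_mode(self):
        from scipy.stats import lognorm

        expected = lognorm(0.4, scale=500.0).cdf(700.0)
        assert lognormal_cdf(700.0, 500.0, 0.4, mode="log-sd") == pytest.approx(
            expected, abs=1e-12
        )

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            lognormal_cdf(1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            lognormal_cdf(1.0, 1.0, 0.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        x1=st.floats(0.0, 5000.0),
        dx=st.floats(0.0, 1000.0),
        median=st.floats(1.0, 3000.0),
        spread=st.floats(1.0, 3000.0),
    )
    def test_monotone_nondecreasing(self, x1, dx, median, spread):
        assert lognormal_cdf(x1 + dx, median, spread) >= lognormal_cdf(
            x1, median, spread
        )


class TestLnasStep:
    theta = LNAS_REFERENCE
    c = LnasConstants()

    def test_no_radiation_no_production(self):
        state = np.array([300.0, 50.0, 20.0, 70.0])
        nxt, Q = lnas_step(state, self.theta, self.c, T_t=15.0, PAR_t=0.0)
        assert Q == 0.0
        assert nxt[1] == state[1] and nxt[2] == state[2]

    def test_thermal_time_cannot_decrease(self):
        state = np.array([300.0, 50.0, 20.0, 70.0])
        nxt, _ = lnas_step(state, self.theta, self.c, T_t=self.c.T_b - 3.0, PAR_t=2.0)
        assert nxt[0] == state[0]

    def test_allocation_fraction_limits(self):
        g0, gf = self.theta[6], self.theta[7]
        mu_a, sig_a = self.theta[2], self.theta[3]
        # tau -> 0: gamma -> gamma0 ; tau -> inf: gamma -> gammaf
        early = g0 + (gf - g0) * lognormal_cdf(1e-9, mu_a, sig_a)
        late = g0 + (gf - g0) * lognormal_cdf(1e9, mu_a, sig_a)
        assert early == pytest.approx(g0, abs=1e-9)
        assert late == pytest.approx(gf, abs=1e-6)

    def test_day_zero_production_is_seed_mass(self):
        nxt, Q = lnas_step(np.zeros(4), self.theta, self.c, T_t=12.0, PAR_t=4.0)
        assert Q == self.c.seed_mass
        assert nxt[3] == self.c.seed_mass


class TestLnasSimulation:
    def test_mass_balance_exact(self, lnas_model):
        """Leaf + root mass equals the cumulated production at every day."""
        traj = lnas_simulate(lnas_model, horizon=150)
        total = traj.state("Q_l") + traj.state("Q_r")
        cum = traj.state("cum_production")
        assert np.max(np.abs(total - cum) / np.maximum(cum, 1.0)) < 1e-10

    def test_outputs_finite_and_yield_monotone(self, lnas_model):
        traj = lnas_simulate(lnas_model, horizon=150)
        assert np.all(np.isfinite(traj.observables))
        assert np.all(np.diff(traj.state("Q_r")) >= 0)

    def test_green_mass_bounded_by_leaf_mass(self, lnas_model):
        traj = lnas_simulate(lnas_model, horizon=150)
        assert np.all(traj.observable("Qg") <= traj.state("Q_l") + 1e-12)

    def test_interception_fraction_below_cap(self, lnas_model, lnas_weather):
        """Daily production never exceeds 95% of the incident usable
        radiation times RUE."""
        traj = lnas_simulate(lnas_model, horizon=150)
        theta = lnas_model.space.reference
        RUE = theta[0]
        cum = traj.state("cum_production")
        Q_daily = np.diff(cum)  # production of days 0..149
        cap = 0.95 * RUE * np.asarray(lnas_weather.PAR[:150])
        assert np.all(Q_daily[1:] <= cap[1:] + 1e-12)

    def test_higher_rue_never_lowers_yield(self, lnas_weather):
        theta_lo = LNAS_REFERENCE.copy()
        theta_hi = LNAS_REFERENCE.copy()
        theta_hi[0] *= 2.0
        model = make_lnas_model(lnas_weather)
        y_lo = lnas_simulate(model, theta_lo, 150).state("Q_r")[-1]
        y_hi = lnas_simulate(model, theta_hi, 150).state("Q_r")[-1]
        assert y_hi >= y_lo

    def test_no_radiation_keeps_masses_constant(self):
        from pracident.models.weather import WeatherSeries

        flat = WeatherSeries(
            days=np.arange(40), T=np.full(40, 15.0), PAR=np.zeros(40)
        )
        model = make_lnas_model(flat)
        traj = lnas_simulate(model, horizon=39)
        # seed-mass production on day 0 is allocated once; nothing after
        assert np.all(np.diff(traj.state("Q_l")[1:]) == 0)
        assert np.all(np.diff(traj.state("Q_r")[1:]) == 0)

    def test_weather_shorter_than_horizon_errors(self):
        short = generate_weather(30, seed=1)
        model = make_lnas_model(short)
        with pytest.raises(Exception, match="cover"):
            lnas_simulate(model, horizon=60)


class TestEpidemicsVectorField:
    theta = np.array([1.177, 4.876, 0.051, 0.096, 0.246])

    def test_bare_plot_rate_is_production_only(self):
        d = epidemics_rhs(np.zeros(3), self.theta, t=3.0)
        assert d[0] == pytest.approx(1.177 * 4.876)
        assert d[1] == 0.0 and d[2] == 0.0

    def test_no_infection_force(self):
        theta = self.theta.copy()
        theta[2] = 0.0
        d = epidemics_rhs(np.array([3.0, 0.0, 0.0]), theta, t=5.0)
        assert d[1] == 0.0

    def test_cumulative_variant_has_no_removal(self):
        state = np.array([0.0, 2.0, 0.0])
        d = epidemics_rhs(state, self.theta, t=5.0, removal_in_I=False)
        assert d[1] == 0.0  # S = 0 and no -dI term
        assert d[2] == pytest.approx(0.246 * 2.0)

    def test_total_population_consistent_with_states(self, epi_model):
        traj = simulate(epi_model, horizon=np.arange(0.0, 13.0))
        N = traj.states.sum(axis=1)
        assert np.allclose(traj.observable("N"), N, rtol=1e-12)

    def test_cumulative_variant_monotone_compartments(self):
        model = make_epidemics_model(removal_in_I=False)
        traj = simulate(model, horizon=np.arange(0.0, 13.0))
        assert np.all(np.diff(traj.state("I")) >= -1e-12)
        assert np.all(np.diff(traj.state("R")) >= -1e-12)

    def test_default_variant_removed_monotone(self, epi_model):
        traj = simulate(epi_model, horizon=np.arange(0.0, 13.0))
        assert np.all(np.diff(traj.state("R")) >= -1e-12)
        assert np.all(traj.state("I") >= -1e-12)


class TestWeatherGenerator:
    def test_reproducible(self):
        w1 = generate_weather(100, seed=7)
        w2 = generate_weather(100, seed=7)
        assert np.array_equal(w1.T, w2.T) and np.array_equal(w1.PAR, w2.PAR)

    def test_zero_noise_is_pure_sinusoid(self):
        w = generate_weather(10, seed=0, T_noise_sd=0.0, PAR_noise_sd=0.0)
        expected_T0 = 15.0 + 7.0 * np.cos(2 * np.pi * (100 - 172) / 365.0)
        assert w.T[0] == pytest.approx(expected_T0, abs=1e-9)

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_par_nonnegative_any_seed(self, seed):
        w = generate_weather(10_000, seed=seed)
        assert np.all(w.PAR >= 0)

    def test_csv_roundtrip(self, tmp_path):
        w = generate_weather(50, seed=3)
        path = tmp_path / "weather.csv"
        w.to_csv(path)
        from pracident.models.weather import WeatherSeries

        back = WeatherSeries.from_csv(path)
        assert np.array_equal(back.T, w.T)
        assert np.array_equal(back.PAR, w.PAR)
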