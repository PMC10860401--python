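"""Shared fixtures: the two case-study models, a reference protocol, and a
linear-Gaussian toy problem with closed-form answers used as the exact
oracle for the sensitivity, profile and recovery machinery."""

import numpy as np
import pytest

from pracident import (
    ChiSquareObjective,
    DynamicalModel,
    NoiseSpec,
    ObservationProtocol,
    ParameterSpace,
    sensitivity_matrix,
    simulate_dataset,
)
from pracident.models import (
    generate_weather,
    make_epidemics_model,
    make_lnas_model,
)


@pytest.fixture(scope="session")
def epi_model():
    return make_epidemics_model()


@pytest.fixture(scope="session")
def epi_protocol():
    return ObservationProtocol(
        times=[2, 4, 6, 8, 10, 12],
        observed=["I", "N"],
        noise={
            "I": NoiseSpec("relative", 0.015),
            "N": NoiseSpec("relative", 0.015),
        },
    )


@pytest.fixture(scope="session")
def epi_dataset(epi_model, epi_protocol):
    return simulate_dataset(epi_model, epi_protocol, seed=11)


@pytest.fixture(scope="session")
def epi_fit(epi_model, epi_dataset):
    return ChiSquareObjective.from_model(epi_model, epi_dataset).fit()


@pytest.fixture(scope="session")
def epi_sensitivity(epi_model, epi_protocol):
    return sensitivity_matrix(epi_model, epi_protocol)


@pytest.fixture(scope="session")
def lnas_weather():
    return generate_weather(151, seed=5)


@pytest.fixture(scope="session")
def lnas_model(lnas_weather):
    return make_lnas_model(lnas_weather)


# ---------------------------------------------------------------------------
# linear-Gaussian toy problem: eta(theta) = A theta, additive Gaussian noise.
# Chi-square is exactly quadratic, so profiles, intervals and estimates all
# have closed forms.
# ---------------------------------------------------------------------------


class LinearGaussian:
    """Closed-form companion for a weighted linear least-squares problem."""

    def __init__(self, seed=0, n_times=8, n_comp=3, p=3, sd=0.5, noisy=True):
        rng = np.random.default_rng(seed)
        self.times = [float(t) for t in range(1, n_times + 1)]
        self.n_comp = n_comp
        n = n_times * n_comp
        self.A = rng.normal(size=(n, p)) + np.eye(n, p) * 2.0
        self.theta_true = rng.uniform(0.5, 2.0, p)
        self.sd = np.full(n, sd)
        eta = self.A @ self.theta_true
        self.y = eta + (rng.normal(0.0, self.sd) if noisy else 0.0)
        self.space = ParameterSpace(
            names=[f"t{i}" for i in range(p)], reference=self.theta_true
        )

    # -- closed forms ------------------------------------------------------

    @property
    def hessian_half(self):
        """H with chi2(theta) = chi2_min + (theta-that)' H (theta-that)."""
        W = 1.0 / self.sd**2
        return self.A.T @ (self.A * W[:, None])

    @property
    def theta_hat(self):
        W = 1.0 / self.sd**2
        return np.linalg.solve(self.hessian_half, self.A.T @ (W * self.y))

    @property
    def chi2_min(self):
        r = self.y - self.A @ self.theta_hat
        return float(np.sum((r / self.sd) ** 2))

    def se(self, i):
        return float(np.sqrt(np.linalg.inv(self.hessian_half)[i, i]))

    def profile_closed_form(self, i, x):
        return self.chi2_min + (x - self.theta_hat[i]) ** 2 / self.se(i) ** 2

    # -- package objects ---------------------------------------------------

    def objective(self, **kwargs):
        return ChiSquareObjective(
            lambda theta: self.A @ theta, self.y, self.sd, self.space, **kwargs
        )

    def model(self):
        """The same map wrapped as a (trivial) dynamical system, so the
        sensitivity-matrix path can be exercised against the analytic
        Jacobian."""
        A, times, n_comp = self.A, self.times, self.n_comp

        def transition(x, theta, u, t):
            return np.zeros_like(x)

        def observation(x, theta, u, t):
            ti = int(np.argmin(np.abs(np.asarray(times) - t)))
            return A[ti * n_comp : (ti + 1) * n_comp] @ theta

        return DynamicalModel(
            time_kind="continuous",
            space=self.space,
            transition=transition,
            observation=observation,
            initial_state=np.zeros(1),
            obs_names=tuple(f"c{i}" for i in range(n_comp)),
        )

    def protocol(self, sd_value=None):
        return ObservationProtocol(
            times=self.times,
            observed=[f"c{i}" for i in range(self.n_comp)],
            noise={
                f"c{i}": NoiseSpec("absolute", sd_value or float(self.sd[0]))
                for i in range(self.n_comp)
            },
        )


@pytest.fixture(scope="session")
def lingauss():
    return LinearGaussian(seed=0)
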