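"""Parameterized dynamical systems and their simulation.

A model is a state-transition rule — a vector field for continuous time or a
difference-equation map for discrete time — together with an observation map
that extracts the measurable quantities from the state.  Both depend on a
parameter vector ``theta`` and an exogenous input signal ``u(t)`` (for the
sugar-beet growth model this is daily weather).  Everything downstream
(collinearity indices, profile likelihoods, recovery errors) only talks to a
model through :func:`simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ParameterSpace",
    "DynamicalModel",
    "Trajectory",
    "SimulationError",
    "DomainError",
    "simulate",
]


class SimulationError(RuntimeError):
    """Raised when the state becomes non-finite during a simulation."""


class DomainError(ValueError):
    """Raised when a parameter vector lies outside its declared domain box."""


@dataclass(frozen=True)
class ParameterSpace:
    """Names, reference point and domain box of a model's parameters.

    Parameters
    ----------
    names : sequence of str
        Unique identifiers, one per parameter.
    reference : array-like
        Reference vector ``theta*`` in model units.  Must lie strictly inside
        every domain interval.
    domains : sequence of (float, float), optional
        Per-parameter open intervals ``(lower, upper)``; either end may be
        infinite.  Defaults to the whole real line for every parameter.
    positive : sequence of bool, optional
        Flags parameters that are positive by nature and therefore eligible
        for a log reparameterization.  Defaults to all ``False``.
    """

    names: tuple[str, ...]
    reference: np.ndarray
    domains: tuple[tuple[float, float], ...] = None  # type: ignore[assignment]
    positive: tuple[bool, ...] = None  # type: ignore[assignment]

    def __init__(self, names, reference, domains=None, positive=None):
        names = tuple(str(n) for n in names)
        reference = np.asarray(reference, dtype=float)
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        if reference.shape != (len(names),):
            raise ValueError("reference length must match number of names")
        if domains is None:
            domains = tuple((-np.inf, np.inf) for _ in names)
        else:
            domains = tuple((float(lo), float(hi)) for lo, hi in domains)
        if len(domains) != len(names):
            raise ValueError("one domain interval per parameter is required")
        for name, ref, (lo, hi) in zip(names, reference, domains):
            if not lo < ref < hi:
                raise ValueError(
                    f"reference value {ref} of parameter {name!r} is not "
                    f"strictly inside its domain ({lo}, {hi})"
                )
        if positive is None:
            positive = tuple(False for _ in names)
        else:
            positive = tuple(bool(p) for p in positive)
        if len(positive) != len(names):
            raise ValueError("one positivity flag per parameter is required")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "reference", reference)
        object.__setattr__(self, "domains", domains)
        object.__setattr__(self, "positive", positive)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name_or_index) -> int:
        if isinstance(name_or_index, str):
            return self.names.index(name_or_index)
        return int(name_or_index)

    def contains(self, theta) -> bool:
        theta = np.asarray(theta, dtype=float)
        return all(lo < v < hi for v, (lo, hi) in zip(theta, self.domains))

    def check(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(self),):
            raise DomainError(
                f"expected {len(self)} parameters, got shape {theta.shape}"
            )
        if not self.contains(theta):
            raise DomainError(f"parameter vector {theta} outside domain box")
        return theta


def _zero_input(t):
    return np.zeros(0)


@dataclass
class DynamicalModel:
    """A parameterized dynamical system, discrete or continuous in time.

    Attributes
    ----------
    time_kind : {"discrete", "continuous"}
        Discrete models advance by one step per unit time; continuous models
        define a vector field integrated by an adaptive Runge-Kutta scheme.
    space : ParameterSpace
    transition : callable ``(x, theta, u_t, t) -> x'``
        Next state (discrete) or state derivative (continuous).
    observation : callable ``(x, theta, u_t, t) -> y``
        Observable vector; its dimension must not depend on ``t``.
    initial_state : array
    input : callable ``t -> u(t)``, optional
        Exogenous input signal; defaults to an empty vector.
    state_names, obs_names : sequences of str
    fast_observables : callable ``(theta, times) -> (T, n) array``, optional
        Performance hook: a specialized routine returning the noise-free
        observables at the requested times, bypassing the generic simulator.
        Must agree with the generic path to solver accuracy; consumers that
        need states (or maximum accuracy) ignore it.
    """

    time_kind: str
    space: ParameterSpace
    transition: Callable
    observation: Callable
    initial_state: np.ndarray
    input: Callable = _zero_input
    state_names: Sequence[str] = ()
    obs_names: Sequence[str] = ()
    fast_observables: Optional[Callable] = None

    def __post_init__(self):
        if self.time_kind not in ("discrete", "continuous"):
            raise ValueError("time_kind must be 'discrete' or 'continuous'")
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        if not self.state_names:
            self.state_names = tuple(
                f"x{i}" for i in range(self.initial_state.size)
            )
        if not self.obs_names:
            y0 = np.atleast_1d(
                self.observation(
                    self.initial_state, self.space.reference, self.input(0.0), 0.0
                )
            )
            self.obs_names = tuple(f"y{i}" for i in range(y0.size))

    @property
    def state_dim(self) -> int:
        return self.initial_state.size

    @property
    def obs_dim(self) -> int:
        return len(self.obs_names)


@dataclass
class Trajectory:
    """Simulated states and observables on a time grid (units: days)."""

    times: np.ndarray
    states: np.ndarray
    observables: np.ndarray
    state_names: tuple[str, ...]
    obs_names: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times}
        for i, name in enumerate(self.state_names):
            data[name] = self.states[:, i]
        for i, name in enumerate(self.obs_names):
            # disambiguate observables that share a state's name
            col = f"obs_{name}" if name in self.state_names else name
            data[col] = self.observables[:, i]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def observable(self, name: str) -> np.ndarray:
        return self.observables[:, self.obs_names.index(name)]

    def state(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]


def _check_finite(x, t):
    if not np.all(np.isfinite(x)):
        raise SimulationError(f"non-finite state encountered at t = {t}")


def simulate(
    model: DynamicalModel,
    theta=None,
    horizon=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
    check_domain: bool = True,
) -> Trajectory:
    """Simulate a model on a time grid and return states plus observables.

    Parameters
    ----------
    model : DynamicalModel
    theta : array-like, optional
        Parameter vector; defaults to the space's reference.
    horizon : array-like
        Sorted, non-empty time grid.  For discrete models it must consist of
        consecutive integers starting at 0 (the transition is applied exactly
        once per step — no hidden sub-stepping).  For continuous models the
        solver is evaluated exactly on the grid via dense output.
    rtol, atol : float
        Tolerances of the adaptive Runge-Kutta integrator (continuous only).

    Raises
    ------
    SimulationError
        If any state component becomes non-finite, with the blow-up time.
    DomainError
        If ``theta`` lies outside the declared domain box.
    """
    if theta is None:
        theta = model.space.reference
    theta = np.asarray(theta, dtype=float)
    if check_domain:
        model.space.check(theta)
    if horizon is None:
        raise ValueError("horizon must be provided")
    times = np.asarray(horizon, dtype=float)
    if times.size == 0:
        raise ValueError("horizon is empty")
    if np.any(np.diff(times) <= 0):
        raise ValueError("horizon must be strictly increasing")

    if model.time_kind == "discrete":
        itimes = np.asarray(np.round(times), dtype=int)
        if not np.array_equal(itimes, np.arange(itimes.size)):
            raise ValueError(
                "discrete horizon must be consecutive integers from 0"
            )
        x = model.initial_state.copy()
        states = np.empty((itimes.size, x.size))
        for t in itimes:
            if t > 0:
                x = np.asarray(
                    model.transition(x, theta, model.input(float(t - 1)), float(t - 1)),
                    dtype=float,
                )
            _check_finite(x, t)
            states[t] = x
    else:
        if rtol <= 0 or atol <= 0:
            raise ValueError("solver tolerances must be positive")
        t0 = times[0]
        if t0 != 0.0:
            times = np.concatenate([[0.0], times])
            drop_first = True
        else:
            drop_first = False

        def rhs(t, x):
            return np.asarray(
                model.transition(x, theta, model.input(t), t), dtype=float
            )

        sol = solve_ivp(
            rhs,
            (times[0], times[-1]),
            model.initial_state,
            method=method,
            t_eval=times,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success or sol.y.shape[1] != times.size:
            raise SimulationError(
                f"integration failed near t = {sol.t[-1] if sol.t.size else times[0]}:"
                f" {sol.message}"
            )
        states = sol.y.T
        if drop_first:
            states = states[1:]
            times = times[1:]
        if not np.all(np.isfinite(states)):
            bad = int(np.where(~np.isfinite(states).all(axis=1))[0][0])
            raise SimulationError(
                f"non-finite state encountered at t = {times[bad]}"
            )

    observables = np.empty((times.size, model.obs_dim))
    for i, t in enumerate(times):
        y = np.atleast_1d(
            model.observation(states[i], theta, model.input(float(t)), float(t))
        )
        observables[i] = y
    _check_finite(observables, times[-1])
    return Trajectory(
        times=np.asarray(times, dtype=float),
        states=states,
        observables=observables,
        state_names=tuple(model.state_names),
        obs_names=tuple(model.obs_names),
    )
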