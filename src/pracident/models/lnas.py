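"""LNAS: a discrete-time compartment model of sugar-beet growth.

Daily biomass production follows a Beer-Lambert light-interception law and
is split between a leaf compartment ``Q_l`` and a root (yield) compartment
``Q_r`` by an allocation fraction that slides from ``gamma0`` to ``gammaf``
as thermal time accumulates.  Green (photosynthetically active) leaf mass
``Q_g`` is the unsenesced part of ``Q_l``.  With thermal time
``tau(t) = sum_s max(0, T(s) - T_b)``:

    tau(t+1) = tau(t) + max(0, T(t) - T_b)
    Q_g(t)   = (1 - G_s(tau(t) - tau_sen; mu_s, sigma_s)) * Q_l(t)
    gamma(t) = gamma0 + (gammaf - gamma0) * G_a(tau(t); mu_a, sigma_a)
    Q(t)     = 0.95 * RUE * PAR(t) * (1 - exp(-k_B * Q_g(t) * e_g))
    Q_l(t+1) = Q_l(t) + gamma(t) * Q(t)
    Q_r(t+1) = Q_r(t) + (1 - gamma(t)) * Q(t)

``G_a`` and ``G_s`` are log-normal cumulative distributions parameterized by
their median and standard deviation (see :func:`lognormal_cdf`).  The free
parameters are ``theta = (RUE, e_g, mu_a, sigma_a, mu_s, sigma_s, gamma0,
gammaf)``; the extinction coefficient ``k_B``, base temperature ``T_b``,
senescence onset ``tau_sen`` and the seed mass are treated as known
constants.  Growth bootstraps from the seed: production on day 0 equals the
seed mass, while ``Q_l(0) = Q_r(0) = 0``.

The numeric defaults below (constants and the reference parameter vector)
are documented, configurable choices producing a realistic sigmoidal yield
curve for a 150-day season; they are not a calibration to field data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from ..core import DynamicalModel, ParameterSpace, Trajectory, simulate

__all__ = [
    "LNAS_NAMES",
    "LNAS_REFERENCE",
    "LnasConstants",
    "lognormal_cdf",
    "lnas_step",
    "make_lnas_model",
    "lnas_simulate",
]

LNAS_NAMES = ("RUE", "e_g", "mu_a", "sigma_a", "mu_s", "sigma_s", "gamma0", "gammaf")

#: Reference vector: radiation-use efficiency (g/MJ), leaf mass-to-surface
#: conversion (m2/g), allocation median/spread (degC day), senescence
#: median/spread (degC day), initial and final leaf allocation fractions.
LNAS_REFERENCE = np.array([3.6, 0.06, 550.0, 950.0, 2300.0, 1600.0, 0.85, 0.15])


@dataclass(frozen=True)
class LnasConstants:
    """Quantities treated as known: extinction coefficient ``k_B``
    (dimensionless), base temperature ``T_b`` (degC), senescence-onset
    thermal time ``tau_sen`` (degC day) and the seed mass (g/m2) that
    bootstraps production on day 0."""

    k_B: float = 0.7
    T_b: float = 0.0
    tau_sen: float = 450.0
    seed_mass: float = 0.3

    def __post_init__(self):
        if not (np.isfinite(self.k_B) and self.k_B > 0):
            raise ValueError("k_B must be finite and positive")
        if self.seed_mass <= 0:
            raise ValueError("seed_mass must be positive")
        if not (np.isfinite(self.T_b) and np.isfinite(self.tau_sen)):
            raise ValueError("constants must be finite")


def lognormal_cdf(x, median, spread, mode: str = "variate-sd"):
    """CDF of a log-normal law parameterized by median and standard deviation.

    The underlying normal has mean ``ln(median)``.  Two readings of the
    spread parameter are supported:

    - ``"variate-sd"`` (default): ``spread`` is the standard deviation of the
      log-normal variate itself.  The log-scale sigma solves
      ``median^2 * e^(s^2) (e^(s^2) - 1) = spread^2``, in closed form
      ``s^2 = ln((1 + sqrt(1 + 4 v)) / 2)`` with ``v = (spread/median)^2``.
      This reading keeps the spread in the same units (degC day) and the
      same order of magnitude as the median, matching how the allocation and
      senescence spreads are quoted.
    - ``"log-sd"``: ``spread`` is the standard deviation of the underlying
      normal variable directly.

    Returns 0 for ``x <= 0``; non-decreasing and continuous in ``x``.
    """
    if median <= 0 or spread <= 0:
        raise ValueError("median and spread must be positive")
    if mode == "variate-sd":
        v = (spread / median) ** 2
        s = np.sqrt(np.log((1.0 + np.sqrt(1.0 + 4.0 * v)) / 2.0))
    elif mode == "log-sd":
        s = float(spread)
    else:
        raise ValueError("mode must be 'variate-sd' or 'log-sd'")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = norm.cdf((np.log(x[pos]) - np.log(median)) / s)
    return out if out.ndim else float(out)


def lnas_step(state, theta, constants: LnasConstants, T_t, PAR_t,
              sigma_mode: str = "variate-sd"):
    """One daily update; returns ``(next_state, Q_t)``.

    ``state = (tau, Q_l, Q_r, cum_production)``; allocation and senescence
    are evaluated with the pre-update thermal time, and the production of
    day ``t`` lands in the day ``t+1`` compartments.  Day 0 production (when
    ``cum_production == 0``) equals the seed mass.
    """
    tau, Q_l, Q_r, cumQ = state
    RUE, e_g, mu_a, sig_a, mu_s, sig_s, g0, gf = theta
    c = constants
    if cumQ == 0.0 and Q_l == 0.0 and Q_r == 0.0:
        Q_t = c.seed_mass
    else:
        G_s = lognormal_cdf(tau - c.tau_sen, mu_s, sig_s, mode=sigma_mode)
        Q_g = (1.0 - G_s) * Q_l
        Q_t = 0.95 * RUE * PAR_t * (1.0 - np.exp(-c.k_B * Q_g * e_g))
    G_a = lognormal_cdf(tau, mu_a, sig_a, mode=sigma_mode)
    gamma_t = g0 + (gf - g0) * G_a
    next_state = np.array([
        tau + max(0.0, T_t - c.T_b),
        Q_l + gamma_t * Q_t,
        Q_r + (1.0 - gamma_t) * Q_t,
        cumQ + Q_t,
    ])
    return next_state, Q_t


def make_lnas_model(
    weather,
    reference=None,
    constants: LnasConstants | None = None,
    sigma_mode: str = "variate-sd",
) -> DynamicalModel:
    """Build LNAS as a discrete-time :class:`DynamicalModel`.

    ``weather`` is a :class:`~pracident.models.weather.WeatherSeries` (or any
    object with ``T`` and ``PAR`` arrays indexed by day) supplying the daily
    temperature and photosynthetically active radiation inputs.  Observables
    are the green leaf biomass ``Q_g`` and the yield ``Q_r``.
    """
    constants = constants or LnasConstants()
    space = ParameterSpace(
        names=LNAS_NAMES,
        reference=LNAS_REFERENCE if reference is None else reference,
        domains=[(0, np.inf)] * 6 + [(0, 1), (0, 1)],
        positive=(True,) * 8,
    )
    T = np.asarray(weather.T, dtype=float)
    PAR = np.asarray(weather.PAR, dtype=float)

    def u(t):
        day = int(round(t))
        if day >= T.size:
            raise ValueError(
                f"weather series (length {T.size}) does not cover day {day}"
            )
        return np.array([T[day], PAR[day]])

    def transition(x, theta, u_t, t):
        nxt, _ = lnas_step(x, theta, constants, u_t[0], u_t[1], sigma_mode)
        return nxt

    def observation(x, theta, u_t, t):
        tau, Q_l, Q_r, _ = x
        G_s = lognormal_cdf(
            tau - constants.tau_sen, theta[4], theta[5], mode=sigma_mode
        )
        return np.array([(1.0 - G_s) * Q_l, Q_r])

    return DynamicalModel(
        time_kind="discrete",
        space=space,
        transition=transition,
        observation=observation,
        initial_state=np.zeros(4),
        input=u,
        state_names=("tau", "Q_l", "Q_r", "cum_production"),
        obs_names=("Qg", "Qr"),
    )


def lnas_simulate(model: DynamicalModel, theta=None, horizon: int = 150) -> Trajectory:
    """Simulate LNAS for ``horizon`` days (grid 0..horizon inclusive)."""
    return simulate(model, theta, np.arange(horizon + 1))
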