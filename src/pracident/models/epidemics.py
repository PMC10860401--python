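"""Plant-population epidemics model (SIR-type with decaying force of infection).

A population of stems is produced at rate ``b`` toward a carrying capacity
``kappa`` and exposed to a force of infection ``lambda0 * exp(-mu * t)`` that
decays over the season; infected stems die (are removed) at rate ``d``:

    dS/dt = b * (kappa - N) - lambda0 * exp(-mu t) * S
    dI/dt = lambda0 * exp(-mu t) * S - d * I
    dR/dt = d * I
    N     = S + I + R

The observables are the infected count ``I`` and the total stem count ``N``,
measured every other day early in the epidemic.

The removal term ``-d I`` in the infected compartment is the standard SIR
balance and is required for the death rate to influence the infected
dynamics at all; it is what produces the strong (mu, d) compensation this
model is known for.  A variant without the removal term (where ``d`` only
moves stems from I to R inside N) is available via ``removal_in_I=False``.

Reference parameter values (per-day rates, stems):
b = 1.177, kappa = 4.876, lambda0 = 0.051, mu = 0.096, d = 0.246.
"""

from __future__ import annotations

import numpy as np

from ..core import DynamicalModel, ParameterSpace

__all__ = [
    "EPIDEMICS_NAMES",
    "EPIDEMICS_REFERENCE",
    "epidemics_rhs",
    "make_epidemics_model",
    "epidemics_space",
]

EPIDEMICS_NAMES = ("b", "kappa", "lambda0", "mu", "d")
#: Reference point: production rate, carrying capacity, force of infection,
#: its decay rate, and the death rate of infected stems.
EPIDEMICS_REFERENCE = np.array([1.177, 4.876, 0.051, 0.096, 0.246])

_DEFAULT_X0 = np.zeros(3)


def epidemics_rhs(state, theta, t, removal_in_I: bool = True):
    """Vector field of the epidemics model at time ``t`` (days).

    ``state`` is ``(S, I, R)``; ``theta`` is ``(b, kappa, lambda0, mu, d)``.
    With ``removal_in_I=False`` the infected compartment keeps dead stems
    (dI/dt has no ``-d I`` term) so ``I`` is a cumulative count.
    """
    S, I, R = state
    b, kappa, lambda0, mu, d = theta
    N = S + I + R
    lam = lambda0 * np.exp(-mu * t)
    dS = b * (kappa - N) - lam * S
    dI = lam * S - (d * I if removal_in_I else 0.0)
    dR = d * I
    return np.array([dS, dI, dR])


# ---------------------------------------------------------------------------
# Fast path: fixed-step RK4 compiled with numba, used by likelihood-heavy
# analyses (fits, profiles, recovery-error replicates).  Cross-checked in the
# test suite against the adaptive integrator to < 1e-6 relative.
# ---------------------------------------------------------------------------

_FAST_DT = 0.01
_fast_kernel = None


def _build_fast_kernel():
    global _fast_kernel
    if _fast_kernel is not None:
        return _fast_kernel
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is a hard dependency
        njit = None

    def kernel(theta, times, x0, dt, removal):
        b = theta[0]
        kap = theta[1]
        l0 = theta[2]
        mu = theta[3]
        d = theta[4]
        S = x0[0]
        I = x0[1]
        R = x0[2]
        out = np.empty((len(times), 2))
        t = 0.0
        for ti in range(len(times)):
            tgt = times[ti]
            span = tgt - t
            if span > 0.0:
                nsub = int(np.ceil(span / dt - 1e-12))
                h = span / nsub
                for _ in range(nsub):
                    lam1 = l0 * np.exp(-mu * t)
                    N1 = S + I + R
                    k1S = b * (kap - N1) - lam1 * S
                    k1I = lam1 * S - removal * d * I
                    k1R = d * I
                    th = t + 0.5 * h
                    lam2 = l0 * np.exp(-mu * th)
                    S2 = S + 0.5 * h * k1S
                    I2 = I + 0.5 * h * k1I
                    R2 = R + 0.5 * h * k1R
                    N2 = S2 + I2 + R2
                    k2S = b * (kap - N2) - lam2 * S2
                    k2I = lam2 * S2 - removal * d * I2
                    k2R = d * I2
                    S3 = S + 0.5 * h * k2S
                    I3 = I + 0.5 * h * k2I
                    R3 = R + 0.5 * h * k2R
                    N3 = S3 + I3 + R3
                    k3S = b * (kap - N3) - lam2 * S3
                    k3I = lam2 * S3 - removal * d * I3
                    k3R = d * I3
                    t4 = t + h
                    lam4 = l0 * np.exp(-mu * t4)
                    S4 = S + h * k3S
                    I4 = I + h * k3I
                    R4 = R + h * k3R
                    N4 = S4 + I4 + R4
                    k4S = b * (kap - N4) - lam4 * S4
                    k4I = lam4 * S4 - removal * d * I4
                    k4R = d * I4
                    S += h / 6.0 * (k1S + 2.0 * k2S + 2.0 * k3S + k4S)
                    I += h / 6.0 * (k1I + 2.0 * k2I + 2.0 * k3I + k4I)
                    R += h / 6.0 * (k1R + 2.0 * k2R + 2.0 * k3R + k4R)
                    t = t4
                    if not (np.isfinite(S) and np.isfinite(I) and np.isfinite(R)):
                        out[:] = np.nan
                        return out
                    if abs(S) > 1e30 or abs(I) > 1e30 or abs(R) > 1e30:
                        out[:] = np.nan
                        return out
            out[ti, 0] = I
            out[ti, 1] = S + I + R
        return out

    if njit is not None:
        _fast_kernel = njit(cache=True)(kernel)
    else:
        _fast_kernel = kernel
    return _fast_kernel


def epidemics_space(domains=None) -> ParameterSpace:
    """Default parameter space: all five rates treated as real-valued.

    The real-line domain matches how the profile-likelihood intervals are
    reported (lower bounds may be negative); all parameters are flagged
    positive-by-nature so a log reparameterization remains available.
    """
    return ParameterSpace(
        names=EPIDEMICS_NAMES,
        reference=EPIDEMICS_REFERENCE,
        domains=domains,
        positive=(True, True, True, True, True),
    )


def make_epidemics_model(
    reference=None,
    initial_state=None,
    removal_in_I: bool = True,
    domains=None,
    fast: bool = True,
) -> DynamicalModel:
    """Build the epidemics model as a continuous-time :class:`DynamicalModel`.

    Parameters
    ----------
    reference : array-like, optional
        Reference parameter vector (defaults to the fitted field values).
    initial_state : array-like, optional
        ``(S, I, R)`` at day 0.  The default is a bare plot ``(0, 0, 0)``:
        stems appear through the production term ``b (kappa - N)``.
    removal_in_I : bool
        Include the ``-d I`` removal term in dI/dt (default).  ``False``
        gives the variant where ``I`` accumulates and ``d`` only routes
        stems into R.
    fast : bool
        Attach the compiled fixed-step RK4 observable evaluator.
    """
    x0 = _DEFAULT_X0 if initial_state is None else np.asarray(initial_state, float)
    space = ParameterSpace(
        names=EPIDEMICS_NAMES,
        reference=EPIDEMICS_REFERENCE if reference is None else reference,
        domains=domains,
        positive=(True,) * 5,
    )

    def transition(x, theta, u, t):
        return epidemics_rhs(x, theta, t, removal_in_I=removal_in_I)

    def observation(x, theta, u, t):
        S, I, R = x
        return np.array([I, S + I + R])

    fast_obs = None
    if fast:
        removal_flag = 1.0 if removal_in_I else 0.0
        x0_fast = np.ascontiguousarray(x0, dtype=float)

        def fast_obs(theta, times):
            kernel = _build_fast_kernel()
            return kernel(
                np.ascontiguousarray(theta, dtype=float),
                np.ascontiguousarray(times, dtype=float),
                x0_fast,
                _FAST_DT,
                removal_flag,
            )

    return DynamicalModel(
        time_kind="continuous",
        space=space,
        transition=transition,
        observation=observation,
        initial_state=x0,
        state_names=("S", "I", "R"),
        obs_names=("I", "N"),
        fast_observables=fast_obs,
    )
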