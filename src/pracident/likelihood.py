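"""Chi-square objective, profile likelihood, confidence intervals and the
profile-likelihood risk index.

The weighted least-squares objective for a dataset ``(y_kl, sigma_kl)`` is

    chi2(theta) = sum_k sum_l (y_kl - eta_kl(theta))^2 / sigma_kl^2 .

The profile likelihood of parameter ``i`` minimizes ``chi2`` over all other
parameters at fixed ``theta_i``; the profile-likelihood confidence interval
(PLCI) at level ``alpha`` is bounded by the crossings of the profile with
``chi2_min + Delta(alpha)``, where ``Delta(alpha)`` is the alpha-quantile of
the chi-square distribution with one degree of freedom.  A parameter is
practically unidentifiable at level ``alpha`` when its PLCI has infinite
length.  The risk index sharpens that binary notion:

    r_i = 1 / sup { alpha in (0, 1) : PLCI_i(alpha) is finite } ,

so ``r_i`` close to 1 means the parameter stays identifiable at almost every
confidence level, and large ``r_i`` means even low-confidence intervals are
unbounded.

Endpoints are located by outward profile marching plus bracketed bisection;
finiteness of a side means the profile reaches the threshold before the edge
of a (large, configurable) search box.  Parameters restricted to a natural
range can be mapped to the real line first (log transform for positive
parameters); endpoints are reported back in original units.

Everything is exposed in a model/results split: :class:`ChiSquareObjective`
is built from a model, protocol and dataset (or any prediction function) and
its :meth:`~ChiSquareObjective.fit` returns a :class:`ChiSquareFit` carrying
the estimate and offering ``profile``, ``plci``, ``risk_index`` and
``summary``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist

from .core import DynamicalModel, ParameterSpace
from .observation import Dataset, model_observables

__all__ = [
    "ParameterTransform",
    "transform_parameters",
    "ChiSquareObjective",
    "ChiSquareFit",
    "ProfileCurve",
    "ConfidenceInterval",
    "RiskResult",
    "ProfileQualityError",
]

PENALTY = 1e12


class ProfileQualityError(RuntimeError):
    """Too many profile points failed to converge to trust the curve."""


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterTransform:
    """Per-parameter bijection between natural and working scales.

    ``modes[j]`` is ``"identity"`` or ``"log"``; the log mode maps a positive
    parameter to the real line so profile marching can run unconstrained.
    The objective value is unchanged at corresponding points.
    """

    modes: tuple[str, ...]

    def __post_init__(self):
        for m in self.modes:
            if m not in ("identity", "log"):
                raise ValueError(f"unknown transform mode {m!r}")

    def to_working(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        out = theta.copy()
        for j, m in enumerate(self.modes):
            if m == "log":
                if theta[j] <= 0:
                    raise ValueError(
                        f"log transform of non-positive value {theta[j]} "
                        f"(parameter {j})"
                    )
                out[j] = np.log(theta[j])
        return out

    def to_natural(self, psi) -> np.ndarray:
        psi = np.asarray(psi, dtype=float)
        out = psi.copy()
        for j, m in enumerate(self.modes):
            if m == "log":
                out[j] = np.exp(psi[j])
        return out


def transform_parameters(
    space: ParameterSpace, mode: str = "identity"
) -> ParameterTransform:
    """Build a transform for a parameter space.

    ``mode="identity"`` leaves every parameter on its natural scale;
    ``mode="log-positive"`` log-transforms every parameter flagged positive
    (and errors if any flagged parameter has a non-positive reference).
    """
    if mode == "identity":
        return ParameterTransform(("identity",) * len(space))
    if mode == "log-positive":
        modes = []
        for j, pos in enumerate(space.positive):
            if pos:
                if space.reference[j] <= 0:
                    raise ValueError(
                        f"parameter {space.names[j]!r} flagged positive but "
                        f"its reference is {space.reference[j]}"
                    )
                modes.append("log")
            else:
                modes.append("identity")
        return ParameterTransform(tuple(modes))
    raise ValueError("mode must be 'identity' or 'log-positive'")


# ---------------------------------------------------------------------------
# Nelder-Mead with restarts
# ---------------------------------------------------------------------------


def _minimize_simplex(
    fun: Callable,
    x0: np.ndarray,
    maxfev: Optional[int] = None,
    xatol: float = 1e-7,
    fatol: float = 1e-9,
    restarts: int = 2,
    restart_ftol: float = 1e-6,
):
    """Derivative-free simplex minimization, re-started from its own result
    until the improvement stalls.  Returns (x, f, converged, nfev)."""
    x = np.asarray(x0, dtype=float)
    best_f = np.inf
    nfev = 0
    converged = False
    for _ in range(restarts + 1):
        res = minimize(
            fun,
            x,
            method="Nelder-Mead",
            options={
                "xatol": xatol,
                "fatol": fatol,
                **({"maxfev": maxfev} if maxfev else {}),
            },
        )
        nfev += res.nfev
        if res.fun < best_f:
            improvement = best_f - res.fun
            x, best_f = res.x, res.fun
        else:
            improvement = 0.0
        converged = bool(res.success)
        if improvement < restart_ftol * (1.0 + abs(best_f)):
            break
    return x, float(best_f), converged, nfev


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


class ChiSquareObjective:
    """Weighted least-squares objective for a dataset.

    Parameters
    ----------
    predict : callable ``theta -> eta``
        Noise-free measurement vector on the natural parameter scale, in the
        dataset's record order.
    y, sd : arrays
        Measured values and their standard deviations.
    space : ParameterSpace
    transform : ParameterTransform, optional
        Working-scale bijection (default: identity everywhere).
    penalty : float
        Value returned inside optimizers when the simulation fails or
        produces non-finite output (analyses outside optimizers should treat
        such points as errors).
    """

    def __init__(self, predict, y, sd, space: ParameterSpace,
                 transform: Optional[ParameterTransform] = None,
                 penalty: float = PENALTY):
        self.predict = predict
        self.y = np.asarray(y, dtype=float)
        self.sd = np.asarray(sd, dtype=float)
        if self.y.shape != self.sd.shape:
            raise ValueError("y and sd must have the same shape")
        if np.any(self.sd <= 0):
            raise ValueError("all sds must be strictly positive")
        self.space = space
        self.transform = transform or transform_parameters(space, "identity")
        self.penalty = penalty
        self.n_penalized = 0

    @classmethod
    def from_model(
        cls,
        model: DynamicalModel,
        dataset: Dataset,
        transform: Optional[ParameterTransform] = None,
        use_fast: bool = True,
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ) -> "ChiSquareObjective":
        """Objective for a dynamical model under the dataset's protocol."""
        protocol = dataset.protocol

        def predict(theta):
            return model_observables(
                model, theta, protocol, rtol=rtol, atol=atol, use_fast=use_fast
            )

        return cls(predict, dataset.values, dataset.sd, model.space,
                   transform=transform)

    @property
    def n_params(self) -> int:
        return len(self.space)

    def chi2(self, theta) -> float:
        """Objective on the natural scale; raises nothing, returns the
        penalty on simulation failure (and counts it)."""
        try:
            eta = np.asarray(self.predict(np.asarray(theta, dtype=float)))
        except Exception:
            self.n_penalized += 1
            return self.penalty
        if not np.all(np.isfinite(eta)):
            self.n_penalized += 1
            return self.penalty
        return float(np.sum(((self.y - eta) / self.sd) ** 2))

    def chi2_work(self, psi) -> float:
        """Objective on the working (transformed) scale."""
        return self.chi2(self.transform.to_natural(psi))

    def fit(
        self,
        start=None,
        maxfev: Optional[int] = None,
        xatol: float = 1e-7,
        fatol: float = 1e-9,
        restarts: int = 2,
    ) -> "ChiSquareFit":
        """Minimize the objective by the derivative-free simplex method.

        ``start`` is on the natural scale and defaults to the space's
        reference.  Restarts re-launch the simplex from its own solution
        until the improvement stalls, which markedly improves profile
        quality on ill-conditioned problems.
        """
        if start is None:
            start = self.space.reference
        psi0 = self.transform.to_working(start)
        psi, fmin, converged, nfev = _minimize_simplex(
            self.chi2_work, psi0, maxfev=maxfev, xatol=xatol, fatol=fatol,
            restarts=restarts,
        )
        return ChiSquareFit(
            objective=self,
            params_work=psi,
            chi2_min=fmin,
            converged=converged,
            nfev=nfev,
            fit_options={"maxfev": maxfev, "xatol": xatol, "fatol": fatol,
                         "restarts": restarts},
        )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class ProfileCurve:
    """Profiled objective along one parameter (working scale).

    ``grid`` is sorted and contains the fit point; ``chi2_pl[k]`` is the
    minimum of the objective over the other parameters at ``grid[k]``, and
    ``nuisance[k]`` the minimizing values of those parameters.  The curve is
    extended lazily outward by the marching routine; ``edge_left/right``
    flag that marching hit the search-box boundary.
    """

    index: int
    grid: np.ndarray
    chi2_pl: np.ndarray
    nuisance: np.ndarray
    converged: np.ndarray
    chi2_min: float
    center: float
    box: tuple[float, float]
    edge_left: bool = False
    edge_right: bool = False

    def max_rise(self, side: str) -> float:
        """Largest profile elevation above the minimum on one side."""
        mask = self.grid < self.center if side == "left" else self.grid > self.center
        if not mask.any():
            return 0.0
        return float(np.max(self.chi2_pl[mask]) - self.chi2_min)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"theta_i": self.grid, "chi2_pl": self.chi2_pl,
             "converged": self.converged}
        )


@dataclass(frozen=True)
class ConfidenceInterval:
    """Profile-likelihood confidence interval on the natural scale."""

    index: int
    name: str
    alpha: float
    threshold: float
    lower: float
    upper: float
    finite_lower: bool
    finite_upper: bool
    estimate: float

    @property
    def finite(self) -> bool:
        return self.finite_lower and self.finite_upper

    @property
    def length(self) -> float:
        return self.upper - self.lower if self.finite else np.inf


@dataclass(frozen=True)
class RiskResult:
    """Risk index of one parameter: reciprocal of the largest confidence
    level at which the PLCI is still finite."""

    index: int
    name: str
    sup_alpha: float
    risk: float
    alpha_tol: float
    box_radius: float
    unidentifiable: bool


class ChiSquareFit:
    """Result of a chi-square fit; entry point for profiles and intervals."""

    def __init__(self, objective, params_work, chi2_min, converged, nfev,
                 fit_options=None):
        self.objective = objective
        self.params_work = np.asarray(params_work, dtype=float)
        self.chi2_min = float(chi2_min)
        self.converged = converged
        self.nfev = nfev
        self.fit_options = fit_options or {}
        self._profiles: dict[int, ProfileCurve] = {}

    @property
    def params(self) -> np.ndarray:
        """Estimate on the natural scale."""
        return self.objective.transform.to_natural(self.params_work)

    @property
    def names(self) -> tuple[str, ...]:
        return self.objective.space.names

    # -- profiling ---------------------------------------------------------

    def _param_index(self, i) -> int:
        return self.objective.space.index(i)

    def _profile_point(self, i: int, x: float, nuis_start: np.ndarray,
                       maxfev: Optional[int] = None):
        """Minimize over the nuisance parameters at fixed working value x."""
        obj = self.objective

        def fun(nuis):
            psi = np.insert(nuis, i, x)
            return obj.chi2_work(psi)

        nuis, f, conv, _ = _minimize_simplex(
            fun, nuis_start, maxfev=maxfev,
            xatol=self.fit_options.get("xatol", 1e-7),
            fatol=self.fit_options.get("fatol", 1e-9),
            restarts=3,
            restart_ftol=1e-8,
        )
        return nuis, f, conv

    def profile(
        self,
        i,
        stop_rise: float = 8.0,
        box_radius: Optional[float] = None,
        init_step_frac: float = 0.02,
        target_rise: float = 1.0,
        max_points_per_side: int = 300,
        jump_tol: float = 25.0,
        quality_threshold: float = 0.2,
    ) -> ProfileCurve:
        """Profile the objective along parameter ``i`` by outward marching.

        From the fit point, the parameter is stepped outward in both
        directions; at each grid value the other parameters are re-minimized,
        warm-started from the neighboring point's minimizer.  The step adapts
        so the profile rises by roughly ``target_rise`` per point.  Marching
        on a side stops when the profile exceeds ``chi2_min + stop_rise`` or
        the search box (radius ``box_radius`` on the working scale, default
        ``1e3 * max(|estimate|, 1)``) is reached.  A point exceeding its
        neighbor by more than ``jump_tol`` is re-minimized from the fit
        point's nuisance values (guard against optimizer glitches).

        The curve is cached per parameter and extended lazily when a later
        call needs a higher ``stop_rise``.

        Raises :class:`ProfileQualityError` if more than
        ``quality_threshold`` of the points fail to converge.
        """
        i = self._param_index(i)
        if self.objective.n_params == 1:
            # profile of the only parameter is the objective itself
            return self._profile_1d(i, stop_rise, box_radius, init_step_frac,
                                    max_points_per_side)
        center = self.params_work[i]
        if box_radius is None:
            box_radius = 1e3 * max(abs(center), 1.0)
        box = (center - box_radius, center + box_radius)

        curve = self._profiles.get(i)
        if curve is None:
            nuis0 = np.delete(self.params_work, i)
            curve = ProfileCurve(
                index=i,
                grid=np.array([center]),
                chi2_pl=np.array([self.chi2_min]),
                nuisance=nuis0[None, :].copy(),
                converged=np.array([True]),
                chi2_min=self.chi2_min,
                center=center,
                box=box,
            )
            self._profiles[i] = curve

        for side in ("left", "right"):
            self._march(curve, i, side, stop_rise, init_step_frac,
                        target_rise, max_points_per_side, jump_tol)

        frac_bad = 1.0 - curve.converged.mean()
        if frac_bad > quality_threshold:
            raise ProfileQualityError(
                f"{frac_bad:.0%} of profile points for "
                f"{self.names[i]!r} failed to converge"
            )
        return curve

    def _profile_1d(self, i, stop_rise, box_radius, init_step_frac,
                    max_points_per_side):
        center = self.params_work[i]
        if box_radius is None:
            box_radius = 1e3 * max(abs(center), 1.0)
        obj = self.objective
        scale = max(abs(center), 1.0)
        grid = [center]
        vals = [self.chi2_min]
        for direction in (-1.0, 1.0):
            step = init_step_frac * scale
            x = center
            for _ in range(max_points_per_side):
                x = x + direction * step
                if abs(x - center) > box_radius:
                    break
                v = obj.chi2_work(np.array([x]))
                grid.append(x)
                vals.append(v)
                if v - self.chi2_min > stop_rise:
                    break
                step *= 1.5
        order = np.argsort(grid)
        grid = np.asarray(grid)[order]
        vals = np.asarray(vals)[order]
        curve = ProfileCurve(
            index=i, grid=grid, chi2_pl=vals,
            nuisance=np.zeros((grid.size, 0)),
            converged=np.ones(grid.size, dtype=bool),
            chi2_min=self.chi2_min, center=center,
            box=(center - box_radius, center + box_radius),
            edge_left=grid[0] <= center - box_radius * 0.999,
            edge_right=grid[-1] >= center + box_radius * 0.999,
        )
        self._profiles[i] = curve
        return curve

    def _march(self, curve: ProfileCurve, i: int, side: str,
               stop_rise: float, init_step_frac: float, target_rise: float,
               max_points: int, jump_tol: float):
        """Extend one side of a cached profile until it clears stop_rise."""
        sgn = -1.0 if side == "left" else 1.0
        if side == "left" and (curve.edge_left or curve.max_rise("left") >= stop_rise):
            return
        if side == "right" and (curve.edge_right or curve.max_rise("right") >= stop_rise):
            return
        # step scale follows the parameter's own magnitude when it has one
        scale = abs(curve.center) if abs(curve.center) > 1e-8 else 1.0
        # resume from the outermost existing point on this side
        if side == "left":
            k = 0
        else:
            k = curve.grid.size - 1
        x = curve.grid[k]
        prev_val = curve.chi2_pl[k]
        nuis = curve.nuisance[k].copy()
        if curve.grid.size > 1 and ((side == "left" and k == 0) or
                                    (side == "right" and k == curve.grid.size - 1)):
            neighbor = curve.grid[1] if side == "left" else curve.grid[-2]
            step = max(abs(x - neighbor), init_step_frac * scale)
        else:
            step = init_step_frac * scale

        new_pts = []
        lo, hi = curve.box
        for _ in range(max_points):
            x = x + sgn * step
            if x < lo or x > hi:
                if side == "left":
                    curve.edge_left = True
                else:
                    curve.edge_right = True
                break
            nuis_new, f, conv = self._profile_point(i, x, nuis)
            rise_jump = f - prev_val
            if rise_jump > jump_tol:
                # guard: retry from the fit point's nuisance values
                nuis_retry, f_retry, conv_retry = self._profile_point(
                    i, x, np.delete(self.params_work, i)
                )
                if f_retry < f:
                    nuis_new, f, conv = nuis_retry, f_retry, conv_retry
            new_pts.append((x, f, nuis_new.copy(), conv))
            nuis = nuis_new
            rise = f - curve.chi2_min
            if rise >= stop_rise:
                break
            inc = max(f - prev_val, 1e-3)
            step *= float(np.clip(target_rise / inc, 0.5, 2.0))
            prev_val = f
        else:
            warnings.warn(
                f"profile marching for {self.names[i]!r} ({side}) stopped at "
                f"the point budget before clearing the threshold"
            )

        if new_pts:
            xs = np.array([p[0] for p in new_pts])
            fs = np.array([p[1] for p in new_pts])
            ns = np.array([p[2] for p in new_pts])
            cs = np.array([p[3] for p in new_pts])
            grid = np.concatenate([curve.grid, xs])
            vals = np.concatenate([curve.chi2_pl, fs])
            nuisance = np.concatenate([curve.nuisance, ns])
            convs = np.concatenate([curve.converged, cs])
            order = np.argsort(grid)
            curve.grid = grid[order]
            curve.chi2_pl = vals[order]
            curve.nuisance = nuisance[order]
            curve.converged = convs[order]

    # -- intervals ---------------------------------------------------------

    def plci(
        self,
        i,
        alpha: float,
        box_radius: Optional[float] = None,
        xtol_rel: float = 1e-4,
        **profile_kwargs,
    ) -> ConfidenceInterval:
        """Profile-likelihood confidence interval at level ``alpha``.

        Each endpoint is the crossing of the profile with
        ``chi2_min + Delta(alpha)`` nearest the estimate, refined by
        bisection between the bracketing profile points.  A side is flagged
        infinite when marching reaches the search box without the profile
        clearing the threshold.  Endpoints are reported in original units.
        """
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        i = self._param_index(i)
        delta = float(chi2_dist.ppf(alpha, 1))
        curve = self.profile(i, stop_rise=delta * 1.05 + 0.5,
                             box_radius=box_radius, **profile_kwargs)
        threshold = self.chi2_min + delta

        lower_w, fin_lo = self._endpoint(curve, i, "left", threshold, xtol_rel)
        upper_w, fin_hi = self._endpoint(curve, i, "right", threshold, xtol_rel)

        tr = self.objective.transform
        mode = tr.modes[i]
        to_nat = (lambda v: float(np.exp(v))) if mode == "log" else float
        est = self.params[i]
        return ConfidenceInterval(
            index=i,
            name=self.names[i],
            alpha=alpha,
            threshold=delta,
            lower=to_nat(lower_w) if fin_lo else -np.inf if mode != "log" else 0.0,
            upper=to_nat(upper_w) if fin_hi else np.inf,
            finite_lower=fin_lo,
            finite_upper=fin_hi,
            estimate=est,
        )

    def _endpoint(self, curve: ProfileCurve, i: int, side: str,
                  threshold: float, xtol_rel: float):
        """First threshold crossing on one side, bisection-refined."""
        center = curve.center
        if side == "left":
            mask = curve.grid <= center
            xs = curve.grid[mask][::-1]          # outward from the center
            fs = curve.chi2_pl[mask][::-1]
            ns = curve.nuisance[mask][::-1]
        else:
            mask = curve.grid >= center
            xs = curve.grid[mask]
            fs = curve.chi2_pl[mask]
            ns = curve.nuisance[mask]
        above = np.where(fs >= threshold)[0]
        if above.size == 0:
            return np.nan, False
        k = int(above[0])
        if k == 0:
            return float(xs[0]), True
        x_in, x_out = xs[k - 1], xs[k]
        nuis = ns[k - 1].copy()
        scale = max(abs(center), 1.0)
        if curve.nuisance.shape[1] == 0:
            def value_at(x):
                return self.objective.chi2_work(np.array([x])), None
        else:
            def value_at(x):
                nuis_x, f, _ = self._profile_point(i, x, nuis)
                return f, nuis_x
        for _ in range(60):
            if abs(x_out - x_in) <= xtol_rel * max(abs(x_out), 0.01 * scale):
                break
            mid = 0.5 * (x_in + x_out)
            f, nuis_mid = value_at(mid)
            if f >= threshold:
                x_out = mid
            else:
                x_in = mid
                if nuis_mid is not None:
                    nuis = nuis_mid
        return float(0.5 * (x_in + x_out)), True

    # -- risk index --------------------------------------------------------

    def risk_index(
        self,
        i,
        alpha_tol: float = 0.005,
        box_radius: Optional[float] = None,
        **profile_kwargs,
    ) -> RiskResult:
        """Risk index by bisection on the confidence level.

        Finiteness of the PLCI is monotone in ``alpha`` (nested intervals),
        so the supremum level with a finite interval is found by bisecting
        ``alpha`` on (0, 1) to tolerance ``alpha_tol``; each probe tests
        whether the profile clears the corresponding threshold on both sides
        before the search box.  The profile is marched once to the highest
        probed threshold and the probes reuse it.  If the interval is
        already infinite at the lowest probe, the parameter is flagged
        unidentifiable and the risk is infinite.
        """
        i = self._param_index(i)
        alpha_lo = alpha_tol
        alpha_hi = 1.0 - alpha_tol
        delta_hi = float(chi2_dist.ppf(alpha_hi, 1))
        curve = self.profile(i, stop_rise=delta_hi * 1.05 + 0.5,
                             box_radius=box_radius, **profile_kwargs)
        radius = curve.box[1] - curve.center

        def finite_at(alpha: float) -> bool:
            delta = float(chi2_dist.ppf(alpha, 1))
            return (curve.max_rise("left") >= delta
                    and curve.max_rise("right") >= delta)

        if not finite_at(alpha_lo):
            return RiskResult(
                index=i, name=self.names[i], sup_alpha=0.0, risk=np.inf,
                alpha_tol=alpha_tol, box_radius=radius, unidentifiable=True,
            )
        if finite_at(alpha_hi):
            sup_alpha = alpha_hi
        else:
            lo, hi = alpha_lo, alpha_hi  # finite at lo, infinite at hi
            while hi - lo > alpha_tol:
                mid = 0.5 * (lo + hi)
                if finite_at(mid):
                    lo = mid
                else:
                    hi = mid
            sup_alpha = lo
        return RiskResult(
            index=i, name=self.names[i], sup_alpha=sup_alpha,
            risk=1.0 / sup_alpha, alpha_tol=alpha_tol, box_radius=radius,
            unidentifiable=False,
        )

    # -- reporting ---------------------------------------------------------

    def summary(self, alpha: Optional[float] = None) -> pd.DataFrame:
        """Tabular summary: estimates, and PLCIs when ``alpha`` is given."""
        data = {"parameter": list(self.names), "estimate": self.params}
        df = pd.DataFrame(data)
        if alpha is not None:
            lowers, uppers, finite = [], [], []
            for j in range(self.objective.n_params):
                ci = self.plci(j, alpha)
                lowers.append(ci.lower)
                uppers.append(ci.upper)
                finite.append(ci.finite)
            df[f"lower_{alpha}"] = lowers
            df[f"upper_{alpha}"] = uppers
            df["finite"] = finite
        df.attrs["chi2_min"] = self.chi2_min
        df.attrs["converged"] = self.converged
        return df
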