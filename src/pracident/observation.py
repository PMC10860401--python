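"""Observation protocols, Gaussian noise models and datasets.

An :class:`ObservationProtocol` fixes which observable components are
measured, at which times, and with what Gaussian noise.  Flattened
measurement vectors are always ordered time-major, component-minor: all
components at ``t_1``, then all components at ``t_2``, and so on.  Every
index module in the package relies on this ordering.

Noise can be specified per component either as an absolute standard
deviation or as a fraction of the component's time-mean over the protocol
(the convention used for the epidemics case: sd = 1.5% of the mean over the
observation times of the noise-free observable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import DynamicalModel, Trajectory, simulate

__all__ = [
    "NoiseSpec",
    "ObservationProtocol",
    "Dataset",
    "ProtocolError",
    "observe",
    "model_observables",
    "resolve_noise",
    "make_dataset",
    "simulate_dataset",
]


class ProtocolError(ValueError):
    """A protocol request inconsistent with the trajectory it is applied to."""


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise for one component: ``kind`` is ``"absolute"`` (``value``
    is the sd) or ``"relative"`` (sd = ``value`` x time-mean of the
    noise-free component over the protocol times)."""

    kind: str
    value: float

    def __post_init__(self):
        if self.kind not in ("absolute", "relative"):
            raise ValueError("noise kind must be 'absolute' or 'relative'")
        if self.value <= 0:
            raise ValueError("noise level must be strictly positive")


@dataclass(frozen=True)
class ObservationProtocol:
    """Observation times, observed components and a per-component noise spec.

    ``times`` must be non-empty and strictly increasing; ``observed`` is an
    ordered subset of the model's observable names.
    """

    times: tuple[float, ...]
    observed: tuple[str, ...]
    noise: Mapping[str, NoiseSpec] = field(default_factory=dict)

    def __init__(self, times, observed, noise=None):
        times = tuple(float(t) for t in times)
        if len(times) == 0:
            raise ValueError("protocol needs at least one observation time")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("observation times must be strictly increasing")
        observed = tuple(str(c) for c in observed)
        if len(observed) == 0:
            raise ValueError("protocol needs at least one observed component")
        noise = dict(noise or {})
        for comp, spec in noise.items():
            if not isinstance(spec, NoiseSpec):
                raise TypeError(f"noise for {comp!r} must be a NoiseSpec")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "observed", observed)
        object.__setattr__(self, "noise", noise)

    @property
    def n_records(self) -> int:
        return len(self.times) * len(self.observed)

    def record_index(self) -> pd.DataFrame:
        """(component, time) labels of the flattened measurement vector,
        time-major, component-minor."""
        rows = [
            {"component": comp, "time": t}
            for t in self.times
            for comp in self.observed
        ]
        return pd.DataFrame(rows)


def observe(traj: Trajectory, protocol: ObservationProtocol) -> np.ndarray:
    """Extract the flat noise-free measurement vector from a trajectory.

    Every protocol time must lie exactly on the trajectory grid — there is
    no silent interpolation.
    """
    cols = []
    for comp in protocol.observed:
        if comp not in traj.obs_names:
            raise ProtocolError(f"component {comp!r} not among {traj.obs_names}")
        cols.append(traj.obs_names.index(comp))
    idx = []
    for t in protocol.times:
        hits = np.where(np.isclose(traj.times, t, rtol=0.0, atol=1e-9))[0]
        if hits.size == 0:
            raise ProtocolError(f"time {t} absent from the trajectory grid")
        idx.append(int(hits[0]))
    block = traj.observables[np.asarray(idx)][:, cols]  # (T, n_obs)
    return block.reshape(-1)


def model_observables(
    model: DynamicalModel,
    theta,
    protocol: ObservationProtocol,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    use_fast: bool = True,
    check_domain: bool = False,
) -> np.ndarray:
    """Noise-free measurement vector ``eta(theta)`` under a protocol.

    Uses the model's compiled fast evaluator when available (and requested);
    otherwise simulates on the protocol grid with the adaptive integrator.
    Returns the flat vector in time-major, component-minor order.
    """
    theta = np.asarray(theta, dtype=float)
    if use_fast and model.fast_observables is not None:
        times = np.asarray(protocol.times, dtype=float)
        block = model.fast_observables(theta, times)
        cols = [model.obs_names.index(c) for c in protocol.observed]
        return np.asarray(block)[:, cols].reshape(-1)
    if model.time_kind == "discrete":
        horizon = np.arange(int(round(max(protocol.times))) + 1)
    else:
        horizon = np.asarray(protocol.times, dtype=float)
    traj = simulate(
        model, theta, horizon, rtol=rtol, atol=atol, check_domain=check_domain
    )
    return observe(traj, protocol)


def resolve_noise(traj: Trajectory, protocol: ObservationProtocol) -> np.ndarray:
    """Per-record noise standard deviations ``sigma_kl``.

    Relative specs resolve to ``fraction x mean`` where the mean is taken
    over the protocol times of that component's noise-free values; absolute
    specs pass through.  A relative spec on a component whose time-mean is
    zero is degenerate and raises.
    """
    eta = observe(traj, protocol)
    n_comp = len(protocol.observed)
    sd = np.empty_like(eta)
    for j, comp in enumerate(protocol.observed):
        try:
            spec = protocol.noise[comp]
        except KeyError:
            raise ProtocolError(f"no noise specification for component {comp!r}")
        if spec.kind == "absolute":
            sd[j::n_comp] = spec.value
        else:
            mean = float(np.mean(eta[j::n_comp]))
            if abs(mean) < 1e-300:
                raise ProtocolError(
                    f"relative noise on component {comp!r} with zero time-mean"
                )
            sd[j::n_comp] = spec.value * abs(mean)
    return sd


@dataclass
class Dataset:
    """Measured values with uncertainties: one record per (component, time).

    ``values`` and ``sd`` are flat arrays in the protocol's time-major,
    component-minor order.  ``provenance`` records the seed and generating
    parameter vector when the data are synthetic.
    """

    protocol: ObservationProtocol
    values: np.ndarray
    sd: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        n = self.protocol.n_records
        if self.values.shape != (n,) or self.sd.shape != (n,):
            raise ValueError(
                f"expected {n} records, got {self.values.shape} values "
                f"and {self.sd.shape} sds"
            )
        if np.any(self.sd <= 0):
            raise ValueError("all record sds must be strictly positive")

    def to_frame(self) -> pd.DataFrame:
        df = self.protocol.record_index()
        df["value"] = self.values
        df["sd"] = self.sd
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, noise=None, provenance=None) -> "Dataset":
        df = pd.read_csv(path, float_precision="round_trip")
        times = tuple(dict.fromkeys(df["time"].tolist()))
        observed = tuple(dict.fromkeys(df["component"].tolist()))
        protocol = ObservationProtocol(times=times, observed=observed, noise=noise)
        order = {
            (comp, t): i
            for i, (t, comp) in enumerate(
                (t, c) for t in times for c in observed
            )
        }
        values = np.empty(len(df))
        sd = np.empty(len(df))
        for _, row in df.iterrows():
            i = order[(row["component"], row["time"])]
            values[i] = row["value"]
            sd[i] = row["sd"]
        return cls(protocol=protocol, values=values, sd=sd,
                   provenance=provenance or {})


def make_dataset(
    eta: np.ndarray,
    sd: np.ndarray,
    protocol: ObservationProtocol,
    seed: Optional[int] = None,
    provenance: Optional[dict] = None,
) -> Dataset:
    """Add independent centered Gaussian noise to a measurement vector.

    ``y_kl = eta_kl + eps_kl`` with ``eps_kl ~ N(0, sigma_kl^2)`` independent
    across records; reproducible given ``seed``.  With ``seed=None`` no noise
    is added (the degenerate, noise-free protocol).
    """
    eta = np.asarray(eta, dtype=float)
    sd = np.asarray(sd, dtype=float)
    prov = dict(provenance or {})
    if seed is None:
        values = eta.copy()
    else:
        rng = np.random.default_rng(seed)
        values = eta + rng.normal(0.0, sd)
        prov.setdefault("seed", seed)
    return Dataset(protocol=protocol, values=values, sd=sd, provenance=prov)


def simulate_dataset(
    model: DynamicalModel,
    protocol: ObservationProtocol,
    theta=None,
    seed: Optional[int] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Dataset:
    """Generate a synthetic dataset at ``theta`` under a protocol.

    Simulates the noise-free trajectory with the adaptive integrator,
    resolves the noise specification against it, then draws one Gaussian
    noise realization (or none when ``seed`` is None).
    """
    if theta is None:
        theta = model.space.reference
    theta = np.asarray(theta, dtype=float)
    if model.time_kind == "discrete":
        horizon = np.arange(int(round(max(protocol.times))) + 1)
    else:
        horizon = np.asarray(protocol.times, dtype=float)
        if horizon[0] != 0.0:
            horizon = np.concatenate([[0.0], horizon])
    traj = simulate(model, theta, horizon, rtol=rtol, atol=atol)
    eta = observe(traj, protocol)
    sd = resolve_noise(traj, protocol)
    return make_dataset(
        eta, sd, protocol, seed=seed,
        provenance={"theta": theta.tolist(), "seed": seed},
    )
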