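"""Synthetic daily weather series driving the sugar-beet growth model.

Real trials record daily mean temperature and photosynthetically active
radiation (PAR) at the site; here both are emulated by a seasonal sinusoid
(annual period, peaking mid-summer) plus bounded day-to-day noise.  Units:
degC and MJ/m2/day.  PAR is clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WeatherSeries", "generate_weather"]


@dataclass(frozen=True)
class WeatherSeries:
    """Daily weather inputs: day index, temperature ``T`` (degC) and
    radiation ``PAR`` (MJ/m2), with ``PAR >= 0`` everywhere."""

    days: np.ndarray
    T: np.ndarray
    PAR: np.ndarray

    def __post_init__(self):
        if np.any(self.PAR < 0):
            raise ValueError("PAR must be non-negative")
        if not (len(self.days) == len(self.T) == len(self.PAR)):
            raise ValueError("days, T and PAR must have equal length")

    def __len__(self) -> int:
        return len(self.days)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "T": self.T, "PAR": self.PAR})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WeatherSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            days=df["day"].to_numpy(),
            T=df["T"].to_numpy(dtype=float),
            PAR=df["PAR"].to_numpy(dtype=float),
        )


def generate_weather(
    n_days: int,
    seed: int,
    T_mean: float = 15.0,
    T_amplitude: float = 7.0,
    T_noise_sd: float = 1.5,
    PAR_mean: float = 5.0,
    PAR_amplitude: float = 3.0,
    PAR_noise_sd: float = 1.0,
    season_start_day: int = 100,
) -> WeatherSeries:
    """Generate a reproducible synthetic weather series.

    Day 0 of the simulation is day ``season_start_day`` of the calendar year
    (spring sowing); both signals follow an annual sinusoid peaking at
    mid-year plus independent Gaussian noise, and PAR is clipped at zero.
    With zero noise amplitudes the series is the pure sinusoid.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    days = np.arange(n_days)
    phase = 2.0 * np.pi * (days + season_start_day - 172) / 365.0
    seasonal = np.cos(phase)
    T = T_mean + T_amplitude * seasonal + rng.normal(0.0, T_noise_sd, n_days)
    PAR = PAR_mean + PAR_amplitude * seasonal + rng.normal(0.0, PAR_noise_sd, n_days)
    return WeatherSeries(days=days, T=T, PAR=np.maximum(PAR, 0.0))
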