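"""Optional diagnostic plots: profile curves, objective surfaces over a
parameter pair, and trajectory overlays against data."""

from __future__ import annotations

import numpy as np

from .likelihood import ChiSquareFit, ProfileCurve
from .observation import Dataset


def plot_profile(curve: ProfileCurve, ax=None, threshold: float | None = None):
    """Profiled chi-square along one parameter; optionally draw the
    confidence threshold line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.grid, curve.chi2_pl, marker=".", lw=1)
    ax.axvline(curve.center, color="grey", lw=0.8, ls="--")
    if threshold is not None:
        ax.axhline(curve.chi2_min + threshold, color="crimson", lw=0.8)
    ax.set_xlabel("parameter value (working scale)")
    ax.set_ylabel(r"$\chi^2_{PL}$")
    return ax


def plot_objective_surface(fit: ChiSquareFit, i, j, span: float = 0.5,
                           n: int = 40, ax=None):
    """Heatmap of the objective over a grid of two parameters, the others
    held at the fit; reveals compensation valleys between the pair."""
    import matplotlib.pyplot as plt

    i = fit._param_index(i)
    j = fit._param_index(j)
    psi = fit.params_work
    gi = np.linspace(psi[i] * (1 - span), psi[i] * (1 + span), n)
    gj = np.linspace(psi[j] * (1 - span), psi[j] * (1 + span), n)
    Z = np.empty((n, n))
    for a, xi in enumerate(gi):
        for b, xj in enumerate(gj):
            p = psi.copy()
            p[i] = xi
            p[j] = xj
            Z[b, a] = fit.objective.chi2_work(p)
    if ax is None:
        _, ax = plt.subplots()
    pcm = ax.pcolormesh(gi, gj, np.log10(Z + 1e-12), shading="auto")
    ax.figure.colorbar(pcm, ax=ax, label=r"$\log_{10}\chi^2$")
    ax.set_xlabel(fit.names[i])
    ax.set_ylabel(fit.names[j])
    return ax


def plot_trajectory_overlay(trajectories, component: str, dataset: Dataset = None,
                            labels=None, ax=None):
    """Overlay one observable across several simulated trajectories, with
    the noisy data points when a dataset is given."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for k, traj in enumerate(trajectories):
        label = labels[k] if labels else None
        ax.plot(traj.times, traj.observable(component), label=label)
    if dataset is not None:
        df = dataset.to_frame()
        sel = df[df["component"] == component]
        ax.plot(sel["time"], sel["value"], "k.", label="data")
    ax.set_xlabel("time (days)")
    ax.set_ylabel(component)
    if labels or dataset is not None:
        ax.legend()
    return ax
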