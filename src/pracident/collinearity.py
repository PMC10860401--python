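"""Scaled sensitivity matrices and collinearity indices of parameter subsets.

The sensitivity matrix has entries

    S_ij = (dtheta_j / SC_i) * d eta_i / d theta_j   evaluated at theta*,

where ``eta`` is the flat noise-free measurement vector of a protocol,
``dtheta_j`` is the uncertainty range of parameter ``j`` and ``SC_i`` a
normalization constant for record ``i`` (by default the time-mean of the
record's component).  The collinearity index of a parameter subset ``K`` is

    gamma_K = 1 / sqrt(lambda_min),

with ``lambda_min`` the smallest eigenvalue of the Gram matrix of the
columns of ``S`` restricted to ``K`` after normalizing each column to unit
Euclidean norm.  ``gamma_K = 1`` means the subset's effects on the output
are orthogonal; a large ``gamma_K`` means a change caused by one parameter
in ``K`` can be compensated up to ``(1 - 1/gamma_K) * 100%`` by the others,
and ``gamma_K = +inf`` (zero eigenvalue) means exact local compensation.

Because columns are re-normalized, ``gamma_K`` is invariant to any positive
rescaling of the ``dtheta`` ranges; they are kept for reporting ``S``
itself.  Indices are monotone non-decreasing under subset inclusion
(eigenvalue interlacing).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import DynamicalModel
from .observation import ObservationProtocol, model_observables

__all__ = [
    "SensitivityMatrix",
    "CollinearitySet",
    "sensitivity_matrix",
    "collinearity_index",
    "all_subset_indices",
    "compensation_percent",
    "mean_collinearity",
]

#: eigenvalues below this fraction of the Gram trace count as zero
LAMBDA_FLOOR = 1e-12

#: refuse to enumerate more subsets than this without an explicit override
SUBSET_CAP = 2**16


@dataclass
class SensitivityMatrix:
    """Scaled sensitivity matrix with its scaling metadata.

    ``entries`` is (records x parameters); ``delta`` are the per-parameter
    uncertainty ranges, ``sc`` the per-record normalization constants and
    ``fd_meta`` the finite-difference scheme actually used.
    """

    entries: np.ndarray
    param_names: tuple[str, ...]
    delta: np.ndarray
    sc: np.ndarray
    theta_ref: np.ndarray
    fd_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("sensitivity matrix has non-finite entries")

    @property
    def n_params(self) -> int:
        return self.entries.shape[1]

    def subset_indices(self, names_or_ids: Sequence) -> list[int]:
        out = []
        for k in names_or_ids:
            out.append(
                self.param_names.index(k) if isinstance(k, str) else int(k)
            )
        return out


def sensitivity_matrix(
    model: DynamicalModel,
    protocol: ObservationProtocol,
    theta_ref=None,
    delta=None,
    fd_step: Optional[np.ndarray] = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    sc_mode: str = "time-mean",
) -> SensitivityMatrix:
    """Build the scaled sensitivity matrix at ``theta_ref`` by central FD.

    Parameters
    ----------
    delta : array-like, optional
        Uncertainty ranges ``dtheta_j``; default ``|theta*_j|`` (100%
        relative uncertainty).  Harmless to collinearity indices (column
        normalization) but kept for reporting.
    fd_step : array-like, optional
        Per-parameter central-difference steps; default
        ``1e-4 * max(|theta*_j|, 1)``.
    rtol, atol : float
        Integrator tolerances, tightened ~100x relative to plain simulation
        so finite-difference noise stays below truncation error.
    sc_mode : {"time-mean", "value"}
        Record normalization: the time-mean of the record's component
        (default) or the record's own noise-free value.
    """
    space = model.space
    if theta_ref is None:
        theta_ref = space.reference
    theta_ref = np.asarray(theta_ref, dtype=float)
    p = theta_ref.size
    if delta is None:
        delta = np.abs(theta_ref).astype(float)
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0):
        raise ValueError("all uncertainty ranges must be strictly positive")
    if fd_step is None:
        fd_step = 1e-4 * np.maximum(np.abs(theta_ref), 1.0)
    fd_step = np.asarray(fd_step, dtype=float)

    def eta(theta):
        return model_observables(
            model, theta, protocol, rtol=rtol, atol=atol, use_fast=False
        )

    base = eta(theta_ref)
    jac = np.empty((base.size, p))
    for j in range(p):
        tp = theta_ref.copy()
        tm = theta_ref.copy()
        tp[j] += fd_step[j]
        tm[j] -= fd_step[j]
        try:
            jac[:, j] = (eta(tp) - eta(tm)) / (2.0 * fd_step[j])
        except Exception as exc:
            raise RuntimeError(
                f"simulation failed while perturbing parameter "
                f"{space.names[j]!r}: {exc}"
            ) from exc

    n_comp = len(protocol.observed)
    sc = np.empty(base.size)
    if sc_mode == "time-mean":
        for j in range(n_comp):
            mean = float(np.mean(base[j::n_comp]))
            if abs(mean) < 1e-12:
                warnings.warn(
                    f"near-zero time-mean for component "
                    f"{protocol.observed[j]!r}; using SC = 1"
                )
                mean = 1.0
            sc[j::n_comp] = mean
    elif sc_mode == "value":
        sc = np.where(np.abs(base) < 1e-12, 1.0, base)
    else:
        raise ValueError("sc_mode must be 'time-mean' or 'value'")

    entries = (delta[None, :] / sc[:, None]) * jac
    return SensitivityMatrix(
        entries=entries,
        param_names=tuple(space.names),
        delta=delta,
        sc=sc,
        theta_ref=theta_ref,
        fd_meta={"scheme": "central", "step": fd_step.tolist(),
                 "rtol": rtol, "atol": atol, "sc_mode": sc_mode},
    )


def collinearity_index(S, subset) -> float:
    """Collinearity index ``gamma_K`` of one parameter subset.

    ``S`` may be a :class:`SensitivityMatrix` or a plain 2-D array.  The
    subset is given by parameter names or column indices and must be
    non-empty.  Returns ``inf`` when a restricted column is identically zero
    or the smallest eigenvalue of the normalized Gram matrix is numerically
    zero (below ``1e-12`` of the Gram trace).
    """
    if isinstance(S, SensitivityMatrix):
        cols = S.subset_indices(subset)
        A = S.entries[:, cols]
    else:
        A = np.asarray(S, dtype=float)[:, list(subset)]
    if A.shape[1] == 0:
        raise ValueError("parameter subset must be non-empty")
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0.0):
        return np.inf
    A = A / norms
    gram = A.T @ A
    lam_min = float(np.linalg.eigvalsh(gram)[0])
    if lam_min <= LAMBDA_FLOOR * float(np.trace(gram)):
        return np.inf
    return 1.0 / np.sqrt(lam_min)


@dataclass
class CollinearitySet:
    """Collinearity indices for a family of parameter subsets."""

    indices: dict
    param_names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subset, value in self.indices.items():
            row = {
                "subset": "+".join(self.param_names[i] for i in subset),
                "size": len(subset),
                "gamma": value if np.isfinite(value) else np.inf,
                "compensation_percent": compensation_percent(value),
            }
            extra = self.meta.get("per_subset", {}).get(subset, {})
            row.update(extra)
            rows.append(row)
        df = pd.DataFrame(rows)
        return df.sort_values("gamma", ascending=False, ignore_index=True)

    def max_index(self, finite_only: bool = True) -> float:
        vals = np.array(list(self.indices.values()))
        if finite_only:
            vals = vals[np.isfinite(vals)]
        return float(vals.max()) if vals.size else np.nan

    def argmax_pair(self) -> tuple:
        """Subset attaining the largest index among the pairs in the set."""
        pairs = {k: v for k, v in self.indices.items() if len(k) == 2}
        if not pairs:
            raise ValueError("no pairs in this collinearity set")
        return max(pairs, key=lambda k: pairs[k])

    def __getitem__(self, subset):
        key = tuple(
            sorted(
                self.param_names.index(k) if isinstance(k, str) else int(k)
                for k in subset
            )
        )
        return self.indices[key]


def _iter_subsets(p: int, min_size: int, max_size: int):
    for r in range(min_size, max_size + 1):
        yield from itertools.combinations(range(p), r)


def all_subset_indices(
    S: SensitivityMatrix,
    min_size: int = 2,
    max_size: Optional[int] = None,
    cap: int = SUBSET_CAP,
) -> CollinearitySet:
    """Collinearity indices for every subset with sizes in a range.

    ``min_size = max_size = 2`` gives the pairwise table; the default upper
    bound is the full parameter count (full enumeration).  Enumeration above
    ``cap`` subsets is refused with the count, to avoid accidental
    combinatorial blow-ups — raise ``cap`` explicitly to proceed.
    """
    p = S.n_params
    if max_size is None:
        max_size = p
    if not 1 <= min_size <= max_size <= p:
        raise ValueError("need 1 <= min_size <= max_size <= n_params")
    count = sum(math.comb(p, r) for r in range(min_size, max_size + 1))
    if count > cap:
        raise ValueError(
            f"{count} subsets exceed the cap of {cap}; pass a larger cap "
            "to enumerate anyway"
        )
    indices = {
        K: collinearity_index(S, K) for K in _iter_subsets(p, min_size, max_size)
    }
    return CollinearitySet(indices=indices, param_names=S.param_names)


def compensation_percent(gamma: float) -> float:
    """Percentage of an output change within a subset that the remaining
    subset parameters can compensate: ``(1 - 1/gamma) * 100``.

    ``gamma = 1`` (orthogonal effects) gives 0%; ``gamma = +inf`` (exact
    collinearity) gives 100%.
    """
    if gamma < 1.0:
        raise ValueError("collinearity indices are >= 1 by construction")
    if np.isinf(gamma):
        return 100.0
    return (1.0 - 1.0 / gamma) * 100.0


def default_prior_sampler(theta_ref, log_sd: float = 1.0):
    """Componentwise log-normal prior centered at ``theta_ref`` with the
    given standard deviation on the natural-log scale."""
    theta_ref = np.asarray(theta_ref, dtype=float)

    def sample(rng: np.random.Generator) -> np.ndarray:
        return theta_ref * np.exp(rng.normal(0.0, log_sd, theta_ref.size))

    return sample


def mean_collinearity(
    model: DynamicalModel,
    protocol: ObservationProtocol,
    n_samples: int,
    seed: int,
    subsets: Optional[Iterable] = None,
    prior_sampler=None,
    min_size: int = 2,
    max_size: Optional[int] = None,
    **sens_kwargs,
) -> CollinearitySet:
    """Prior-averaged ("mean") collinearity indices.

    Draws parameter vectors from a prior (default: componentwise log-normal
    centered at the reference with log-sd 1), evaluates the sensitivity
    matrix and the requested subset indices at each draw, and reports the
    per-subset sample mean with a Monte-Carlo standard error.  Draws where
    the simulation fails or the index is infinite are counted separately and
    excluded from the mean.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    space = model.space
    p = len(space)
    if prior_sampler is None:
        prior_sampler = default_prior_sampler(space.reference)
    if subsets is None:
        if max_size is None:
            max_size = p
        subsets = list(_iter_subsets(p, min_size, max_size))
    else:
        subsets = [
            tuple(
                sorted(
                    space.names.index(k) if isinstance(k, str) else int(k)
                    for k in sub
                )
            )
            for sub in subsets
        ]

    rng = np.random.default_rng(seed)
    draws = {K: [] for K in subsets}
    n_inf = {K: 0 for K in subsets}
    n_failed = 0
    for _ in range(n_samples):
        theta = prior_sampler(rng)
        try:
            S = sensitivity_matrix(model, protocol, theta_ref=theta, **sens_kwargs)
        except Exception:
            n_failed += 1
            continue
        for K in subsets:
            g = collinearity_index(S, K)
            if np.isfinite(g):
                draws[K].append(g)
            else:
                n_inf[K] += 1
    if n_failed == n_samples:
        raise RuntimeError("all prior draws failed to simulate")

    indices = {}
    per_subset = {}
    for K in subsets:
        vals = np.asarray(draws[K])
        if vals.size == 0:
            indices[K] = np.inf
            per_subset[K] = {"mc_se": np.nan, "n_valid": 0, "n_inf": n_inf[K]}
            continue
        indices[K] = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
        per_subset[K] = {"mc_se": se, "n_valid": int(vals.size), "n_inf": n_inf[K]}
    return CollinearitySet(
        indices=indices,
        param_names=tuple(space.names),
        meta={
            "per_subset": per_subset,
            "n_samples": n_samples,
            "n_failed": n_failed,
            "seed": seed,
        },
    )
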