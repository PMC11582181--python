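"""Approximate standard errors from slice likelihoods.

Near the MLE the log-likelihood surface is approximately quadratic (local
asymptotic normality), so its curvature along one parameter axis at a time
can be estimated by evaluating the (particle-filter) log-likelihood on a
grid around the estimate — a *slice* — and fitting a quadratic by least
squares:

    l(theta) ~ a + b theta + c theta^2,   curvature = 2c < 0,
    SE = (-2c)^(-1/2).

Replicated filter evaluations share common random-number seeds across grid
points so Monte-Carlo noise largely cancels out of the curvature.  Because
each parameter is sliced on its own (cross-parameter information is
ignored), these SEs are *liberal* — smaller than the truth — which is why
downstream inference favours wide Wald intervals: 95% intervals use
theta +/- 1.96 SE and the conservative 99.8% intervals theta +/- 3.09 SE
(the latter empirically deliver roughly nominal 95% coverage).

For linear-Gaussian models the exact Kalman likelihood can be used as the
slice backend, which removes Monte-Carlo noise entirely (and serves as the
correctness oracle for the particle backend).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import identify_innovations
from .errors import CurvatureError, InfeasibleDynamicsError, ParameterError, SliceError, StationarityError
from .filtering import kalman_filter
from .measurement import MeasurementModel
from .mif2 import ParameterVector, model_at, pf_loglik

__all__ = [
    "SliceSpec",
    "SliceSEResult",
    "slice_loglik",
    "quadratic_curvature",
    "wald_ci",
    "slice_standard_errors",
]

_Z = {0.95: 1.96, 0.998: 3.09}


@dataclass(frozen=True)
class SliceSpec:
    """Grid and replication settings for one parameter's slice."""

    param_index: int
    half_width: float
    n_points: int = 11
    n_reps: int = 3
    K: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 5 or self.n_points % 2 == 0:
            raise ParameterError("n_points must be odd and >= 5")
        if not self.half_width > 0:
            raise ParameterError("half_width must be positive")


@dataclass(frozen=True)
class SliceSEResult:
    """Per-parameter slice-likelihood standard errors and Wald intervals."""

    se: np.ndarray
    curvature: np.ndarray
    ci95: np.ndarray  # (n_params, 2)
    ci998: np.ndarray
    slices: tuple  # per parameter: dict with grid, mean_loglik, rep_sd


def _feasible(pv: ParameterVector) -> bool:
    try:
        identify_innovations(pv.A)
    except (StationarityError, InfeasibleDynamicsError):
        return False
    return True


def slice_loglik(data, base_model: MeasurementModel, estimate: ParameterVector,
                 spec: SliceSpec, backend: str = "pf", center=None):
    """Evaluate the log-likelihood along one parameter axis.

    Returns a dict with keys ``grid`` (feasible parameter values),
    ``mean_loglik``, ``rep_sd`` (per-point SD over filter replicates, zero
    for the exact backend) and ``dropped`` (infeasible grid values).
    """
    theta_hat = float(estimate.values[spec.param_index])
    grid = theta_hat + np.linspace(-spec.half_width, spec.half_width, spec.n_points)
    rep_seeds = [
        int(np.random.SeedSequence([spec.seed, 77, r]).generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        for r in range(spec.n_reps)
    ]
    kept, means, sds, dropped = [], [], [], []
    for val in grid:
        v = estimate.values.copy()
        v[spec.param_index] = val
        pv = estimate.with_values(v)
        if not _feasible(pv):
            dropped.append(float(val))
            continue
        if backend == "kalman":
            model = model_at(pv, base_model, center=center)
            covs = identify_innovations(pv.A)
            lls = [kalman_filter(np.asarray(data, dtype=float), pv.A, covs, model).loglik]
        elif backend == "pf":
            # common random numbers: same seeds at every grid point
            lls = [pf_loglik(data, base_model, pv, K=spec.K, seed=s, center=center)
                   for s in rep_seeds]
        else:
            raise ParameterError(f"unknown slice backend {backend!r}")
        kept.append(float(val))
        means.append(float(np.mean(lls)))
        sds.append(float(np.std(lls)))
    if len(kept) < 5:
        raise SliceError(
            f"only {len(kept)} feasible grid points for parameter {spec.param_index}"
        )
    return {
        "grid": np.array(kept),
        "mean_loglik": np.array(means),
        "rep_sd": np.array(sds),
        "dropped": np.array(dropped),
    }


def quadratic_curvature(grid, loglik=None):
    """Fit l(theta) ~ a + b theta + c theta^2 and return (curvature, se).

    Accepts either the dict returned by :func:`slice_loglik` or a pair of
    arrays.  Raises :class:`CurvatureError` when the fit is convex or flat
    (a nearly flat slice signals under-identification).
    """
    if isinstance(grid, dict):
        loglik = grid["mean_loglik"]
        grid = grid["grid"]
    grid = np.asarray(grid, dtype=float)
    loglik = np.asarray(loglik, dtype=float)
    if grid.size < 5:
        raise SliceError("need at least 5 points for a quadratic fit")
    c, b, a = np.polyfit(grid - grid.mean(), loglik, 2)  # center for conditioning
    curvature = 2.0 * c
    if not curvature < 0:
        raise CurvatureError(
            f"slice is convex or flat (curvature {curvature:.3g}); parameter may be under-identified"
        )
    return float(curvature), float((-curvature) ** -0.5)


def wald_ci(estimate: float, se: float, level: float = 0.95):
    """Wald interval estimate +/- z * SE with z = 1.96 (95%) or 3.09 (99.8%)."""
    if not se > 0:
        raise ParameterError("se must be positive")
    if level not in _Z:
        raise ParameterError(f"supported levels: {sorted(_Z)}")
    z = _Z[level]
    return (estimate - z * se, estimate + z * se)


def slice_standard_errors(data, base_model: MeasurementModel, estimate: ParameterVector,
                          param_indices=None, half_width: float = 0.05, n_points: int = 11,
                          n_reps: int = 3, K: int = 1000, seed: int = 0,
                          backend: str = "pf", center=None) -> SliceSEResult:
    """Slice SEs and Wald intervals for a set of parameters (defaults to the
    four transition-matrix entries)."""
    if param_indices is None:
        param_indices = range(4)
    param_indices = list(param_indices)
    ses, curvs, ci95, ci998, slices = [], [], [], [], []
    for j in param_indices:
        sl = slice_loglik(
            data, base_model, estimate,
            SliceSpec(param_index=j, half_width=half_width, n_points=n_points,
                      n_reps=n_reps, K=K, seed=seed),
            backend=backend, center=center,
        )
        curv, se = quadratic_curvature(sl)
        est = float(estimate.values[j])
        ses.append(se)
        curvs.append(curv)
        ci95.append(wald_ci(est, se, 0.95))
        ci998.append(wald_ci(est, se, 0.998))
        slices.append(sl)
    return SliceSEResult(
        se=np.array(ses), curvature=np.array(curvs),
        ci95=np.array(ci95), ci998=np.array(ci998), slices=tuple(slices),
    )
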