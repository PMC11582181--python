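"""State filtering: bootstrap particle filter and exact Kalman filter.

The particle filter is the workhorse for the graded-response model, whose
filtering distribution has no analytic form.  Particles are initialised from
``f0 = N(0, I)``, propagated through the state equation ``N(A x, Sigma)``
(with ``Sigma`` implied by the identification constraint unless supplied),
weighted by the measurement likelihood, and resampled with replacement every
timepoint.  The log-likelihood accumulates the per-timepoint log mean weight,
and filtered means are the weighted particle averages *before* resampling.
Systematic resampling is the default (lower variance); multinomial is kept
for oracle tests.

Note ``f0 = N(0, I)`` intentionally differs from the stationary law
``N(0, Gamma)``: the filter conditions on data immediately and the choice
washes out within a few timepoints, but it is part of the estimation recipe
and is kept for both filtering and MIF2.

The Kalman filter gives exact filtered means and the exact prediction-error-
decomposition log-likelihood for the linear-Gaussian measurement model; it
serves as the comparator model's engine and as a correctness oracle for the
particle filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .dynamics import IdentifiedCovariances, identify_innovations
from .errors import DegeneracyError, DimensionError, ParameterError
from .measurement import MeasurementModel

__all__ = [
    "ParticleEnsemble",
    "FilterOutput",
    "resample",
    "particle_filter",
    "kalman_filter",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ParticleEnsemble:
    """K weighted state particles at one timepoint."""

    states: np.ndarray  # (K, p)
    log_weights: np.ndarray  # (K,)
    t: int

    def normalized_weights(self) -> np.ndarray:
        m = np.max(self.log_weights)
        w = np.exp(self.log_weights - m)
        return w / w.sum()


@dataclass(frozen=True)
class FilterOutput:
    """Filtered state means, log-likelihood and effective-sample-size trace."""

    filtered_means: np.ndarray  # (T, p)
    loglik: float
    ess_trace: np.ndarray  # (T,)
    filtered_covs: np.ndarray = None  # (T, p, p); exact filters only


def resample(log_weights, K: int, scheme: str = "systematic", seed: int = 0) -> np.ndarray:
    """Draw K particle indices with probability proportional to the weights.

    The systematic scheme stratifies the unit interval with a single uniform
    draw; multinomial draws K iid indices.
    """
    lw = np.asarray(log_weights, dtype=float)
    if lw.ndim != 1 or lw.size < 1:
        raise DimensionError("log_weights must be a nonempty vector")
    m = np.max(lw)
    if m == -np.inf:
        raise DegeneracyError("all particle log-weights are -inf", t=None)
    w = np.exp(lw - m)
    w /= w.sum()
    out = np.empty(K, dtype=np.int64)
    rng = np.random.default_rng(seed)
    if scheme == "systematic":
        u = (rng.random() + np.arange(K)) / K
        out = np.searchsorted(np.cumsum(w), u).astype(np.int64)
        np.clip(out, 0, lw.size - 1, out=out)
    elif scheme == "multinomial":
        out = rng.choice(lw.size, size=K, p=w).astype(np.int64)
    else:
        raise ParameterError(f"unknown resampling scheme {scheme!r}")
    return out


def _scheme_code(scheme: str) -> int:
    if scheme == "systematic":
        return 0
    if scheme == "multinomial":
        return 1
    raise ParameterError(f"unknown resampling scheme {scheme!r}")


def _grm_arrays(model: MeasurementModel):
    q = model.q
    ncat = np.array([it.n_categories for it in model.items], dtype=np.int64)
    jmax = int(ncat.max())
    beta = np.full((q, jmax - 1), np.inf)
    for i, it in enumerate(model.items):
        beta[i, : it.beta.size] = it.beta
    alpha = np.array([it.alpha for it in model.items], dtype=float)
    return model.state_indices(), alpha, beta, ncat


def _linear_arrays(model: MeasurementModel):
    loading = np.array([it.loading for it in model.items], dtype=float)
    err_var = np.array([it.error_var for it in model.items], dtype=float)
    return model.state_indices(), model.center.astype(float), loading, err_var


def particle_filter(
    data,
    A,
    model: MeasurementModel,
    K: int,
    seed: int,
    scheme: str = "systematic",
    sigma=None,
    x0=None,
) -> FilterOutput:
    """Run the bootstrap particle filter at fixed parameters.

    Parameters
    ----------
    data : (T, q) array
        Integer categories (0 = missing) for the grm kind; reals (NaN =
        missing) for the linear kind.
    A : (p, p) array
        Stationary transition matrix; the innovation covariance is derived
        from the identification constraint unless ``sigma`` is given.
    K : int
        Number of particles (>= 2).
    sigma : optional (p,) or (p, p) diagonal
        Override for the innovation covariance (testing hook).
    x0 : optional (p,) vector
        Start every particle at this state instead of drawing from N(0, I).
    """
    if K < 2:
        raise ParameterError("particle filter needs K >= 2")
    A = np.asarray(A, dtype=float)
    p = A.shape[0]
    if sigma is None:
        sigma_diag = identify_innovations(A).sigma_diag
    else:
        sigma = np.asarray(sigma, dtype=float)
        sigma_diag = np.diag(sigma) if sigma.ndim == 2 else sigma
    use_x0 = x0 is not None
    x0_arr = np.zeros(p) if x0 is None else np.asarray(x0, dtype=float)
    code = _scheme_code(scheme)
    data = np.asarray(data)
    if data.ndim != 2 or data.shape[1] != model.q:
        raise DimensionError(f"data shape {data.shape} does not match q={model.q}")
    if model.kind == "grm":
        sidx, alpha, beta, ncat = _grm_arrays(model)
        y = data.astype(np.int64)
        ll, fm, ess, err_t = _kernels.pf_grm(
            y, sidx, alpha, beta, ncat, A, sigma_diag.astype(float),
            int(K), int(seed), code, x0_arr, use_x0,
        )
    else:
        sidx, center, loading, err_var = _linear_arrays(model)
        y = data.astype(float)
        ll, fm, ess, err_t = _kernels.pf_linear(
            y, sidx, center, loading, err_var, A, sigma_diag.astype(float),
            int(K), int(seed), code, x0_arr, use_x0,
        )
    if err_t >= 0:
        raise DegeneracyError(
            f"all particle weights vanished at t={err_t} (impossible parameters?)",
            t=int(err_t),
        )
    return FilterOutput(filtered_means=fm, loglik=float(ll), ess_trace=ess)


def kalman_filter(data, A, covs: IdentifiedCovariances, model: MeasurementModel) -> FilterOutput:
    """Exact filter for the linear-Gaussian model.

    Uses the prediction-error decomposition for the log-likelihood and drops
    the rows of the loading matrix for items missing at a given timepoint.
    The initial state distribution is N(0, I), matching the particle filter.
    """
    if model.kind != "linear":
        raise ParameterError("kalman_filter requires a linear measurement model")
    A = np.asarray(A, dtype=float)
    p = A.shape[0]
    data = np.asarray(data, dtype=float)
    T, q = data.shape
    if q != model.q:
        raise DimensionError(f"data has {q} columns for {model.q} items")
    sidx, center, loading, err_var = _linear_arrays(model)
    C = np.zeros((q, p))
    C[np.arange(q), sidx] = loading
    Sigma = covs.Sigma if covs.Sigma.ndim == 2 else np.diag(covs.Sigma)
    x = np.zeros(p)
    P = np.eye(p)
    fmeans = np.zeros((T, p))
    fcovs = np.zeros((T, p, p))
    loglik = 0.0
    for t in range(T):
        x = A @ x
        P = A @ P @ A.T + Sigma
        obs = ~np.isnan(data[t])
        if obs.any():
            Ct = C[obs]
            Rt = np.diag(err_var[obs])
            v = data[t, obs] - center[obs] - Ct @ x
            S = Ct @ P @ Ct.T + Rt
            try:
                L = np.linalg.cholesky(S)
            except np.linalg.LinAlgError as exc:
                raise ParameterError("innovation covariance not positive definite") from exc
            alpha_v = np.linalg.solve(L, v)
            Kt = P @ Ct.T @ np.linalg.solve(S, np.eye(S.shape[0]))
            x = x + Kt @ v
            P = (np.eye(p) - Kt @ Ct) @ P
            P = 0.5 * (P + P.T)
            loglik += -0.5 * (
                obs.sum() * _LOG_2PI + 2.0 * np.sum(np.log(np.diag(L))) + alpha_v @ alpha_v
            )
        fmeans[t] = x
        fcovs[t] = P
    return FilterOutput(
        filtered_means=fmeans, loglik=float(loglik),
        ess_trace=np.full(T, np.nan), filtered_covs=fcovs,
    )
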