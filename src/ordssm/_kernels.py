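"""Numba kernels for the particle filter and MIF2 hot loops.

These are implementation detail: the public surface lives in
:mod:`ordssm.filtering` and :mod:`ordssm.mif2`.  The particle-filter kernels
handle any number of states p (the innovation covariance is supplied by the
caller); the MIF2 kernels specialise to the 2-state model used throughout
(the identification constraint there has the closed form

    gamma_12 = (a11 a21 + a12 a22) / (1 - a11 a22 - a12 a21)
    sigma_1  = 1 - (a11^2 + 2 a11 a12 gamma_12 + a12^2)
    sigma_2  = 1 - (a21^2 + 2 a21 a22 gamma_12 + a22^2)

with stationarity by the Jury conditions |det A| < 1 and |tr A| < 1 + det A),
which is validated in tests against the general selection-matrix solve in
:mod:`ordssm.dynamics`.

Conventions shared with the wrappers:
  * ordinal data are int64 (T, q) with categories 1..J and 0 = missing;
  * continuous data are float64 (T, q) with NaN = missing;
  * GR threshold blocks on the estimation scale are
    [beta_1, log(beta_2 - beta_1), ..., log(beta_{J-1} - beta_{J-2})];
  * kernels return an error sentinel (iteration, timepoint) instead of
    raising; wrappers convert it to DegeneracyError.
"""

import numpy as np
from numba import njit

# safe fastmath subset: keeps NaN/inf semantics (we rely on -inf log-weights
# and NaN missing markers)
_FM = {"contract", "arcp", "reassoc", "nsz"}

LOG_2PI = float(np.log(2.0 * np.pi))
SIGMA_FLOOR = 1e-8


@njit(cache=True, inline="always", fastmath=_FM)
def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=True)
def _systematic_indices(w, out):
    """Systematic resampling: one uniform stratifies the whole ensemble."""
    K = w.shape[0]
    u = np.random.random() / K
    c = w[0]
    i = 0
    for k in range(K):
        target = u + k / K
        while c < target and i < K - 1:
            i += 1
            c += w[i]
        out[k] = i


@njit(cache=True)
def _multinomial_indices(w, out):
    """Multinomial resampling via binary search on the weight cdf."""
    K = w.shape[0]
    cdf = np.empty(K)
    c = 0.0
    for k in range(K):
        c += w[k]
        cdf[k] = c
    cdf[K - 1] = 1.0
    for k in range(K):
        u = np.random.random()
        lo = 0
        hi = K - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if cdf[mid] < u:
                lo = mid + 1
            else:
                hi = mid
        out[k] = lo


@njit(cache=True, inline="always", fastmath=_FM)
def _identify_p2(a11, a12, a21, a22):
    """Closed-form identification for p=2.

    Returns (feasible, sigma_1, sigma_2)."""
    tr = a11 + a22
    det = a11 * a22 - a12 * a21
    if not (abs(det) < 1.0 and abs(tr) < 1.0 + det):
        return False, 0.0, 0.0
    den = 1.0 - a11 * a22 - a12 * a21
    if abs(den) < 1e-12:
        return False, 0.0, 0.0
    g = (a11 * a21 + a12 * a22) / den
    if abs(g) >= 1.0:
        return False, 0.0, 0.0
    s1 = 1.0 - (a11 * a11 + 2.0 * a11 * a12 * g + a12 * a12)
    s2 = 1.0 - (a21 * a21 + 2.0 * a21 * a22 * g + a22 * a22)
    if s1 <= SIGMA_FLOOR or s2 <= SIGMA_FLOOR:
        return False, 0.0, 0.0
    return True, s1, s2


@njit(cache=True, inline="always", fastmath=_FM)
def _grm_cat_logprob(xv, j, Ji, alpha_i, beta_i):
    """log P(y = j | x) for fixed thresholds beta_i (length >= Ji-1)."""
    lo = 1.0 if j == 1 else _logistic(alpha_i * (xv - beta_i[j - 2]))
    hi = 0.0 if j == Ji else _logistic(alpha_i * (xv - beta_i[j - 1]))
    d = lo - hi
    if d < 1e-300:
        d = 1e-300
    return np.log(d)


# ---------------------------------------------------------------------------
# particle filters at fixed parameters (any p)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=_FM)
def pf_grm(y, state_idx, alpha, beta, ncat, A, sigma_diag, K, seed, scheme, x0, use_x0):
    """Bootstrap particle filter, graded-response measurement.

    Returns (loglik, filtered_means (T,p), ess (T,), err_t);
    err_t >= 0 flags total degeneracy at that timepoint.
    """
    np.random.seed(seed)
    T, q = y.shape
    p = A.shape[0]
    x = np.empty((K, p))
    xn = np.empty((K, p))
    logw = np.empty(K)
    w = np.empty(K)
    idx = np.empty(K, dtype=np.int64)
    fmeans = np.zeros((T, p))
    ess = np.zeros(T)
    sd = np.sqrt(sigma_diag)
    for k in range(K):
        for d in range(p):
            x[k, d] = x0[d] if use_x0 else np.random.normal()
    loglik = 0.0
    for t in range(T):
        maxlw = -np.inf
        for k in range(K):
            for d in range(p):
                v = 0.0
                for e in range(p):
                    v += A[d, e] * x[k, e]
                xn[k, d] = v + sd[d] * np.random.normal()
            lw = 0.0
            for i in range(q):
                j = y[t, i]
                if j <= 0:
                    continue
                lw += _grm_cat_logprob(xn[k, state_idx[i]], j, ncat[i], alpha[i], beta[i])
            logw[k] = lw
            if lw > maxlw:
                maxlw = lw
        if maxlw == -np.inf:
            return loglik, fmeans, ess, t
        sw = 0.0
        for k in range(K):
            w[k] = np.exp(logw[k] - maxlw)
            sw += w[k]
        loglik += maxlw + np.log(sw / K)
        s2 = 0.0
        for k in range(K):
            w[k] /= sw
            s2 += w[k] * w[k]
            for d in range(p):
                fmeans[t, d] += w[k] * xn[k, d]
        ess[t] = 1.0 / s2
        if scheme == 0:
            _systematic_indices(w, idx)
        else:
            _multinomial_indices(w, idx)
        for k in range(K):
            for d in range(p):
                x[k, d] = xn[idx[k], d]
    return loglik, fmeans, ess, -1


@njit(cache=True, fastmath=_FM)
def pf_linear(y, state_idx, center, loading, err_var, A, sigma_diag, K, seed, scheme, x0, use_x0):
    """Bootstrap particle filter, linear-Gaussian measurement (NaN = missing)."""
    np.random.seed(seed)
    T, q = y.shape
    p = A.shape[0]
    x = np.empty((K, p))
    xn = np.empty((K, p))
    logw = np.empty(K)
    w = np.empty(K)
    idx = np.empty(K, dtype=np.int64)
    fmeans = np.zeros((T, p))
    ess = np.zeros(T)
    sd = np.sqrt(sigma_diag)
    for k in range(K):
        for d in range(p):
            x[k, d] = x0[d] if use_x0 else np.random.normal()
    loglik = 0.0
    for t in range(T):
        maxlw = -np.inf
        for k in range(K):
            for d in range(p):
                v = 0.0
                for e in range(p):
                    v += A[d, e] * x[k, e]
                xn[k, d] = v + sd[d] * np.random.normal()
            lw = 0.0
            for i in range(q):
                yv = y[t, i]
                if np.isnan(yv):
                    continue
                r = yv - center[i] - loading[i] * xn[k, state_idx[i]]
                lw += -0.5 * (LOG_2PI + np.log(err_var[i]) + r * r / err_var[i])
            logw[k] = lw
            if lw > maxlw:
                maxlw = lw
        if maxlw == -np.inf:
            return loglik, fmeans, ess, t
        sw = 0.0
        for k in range(K):
            w[k] = np.exp(logw[k] - maxlw)
            sw += w[k]
        loglik += maxlw + np.log(sw / K)
        s2 = 0.0
        for k in range(K):
            w[k] /= sw
            s2 += w[k] * w[k]
            for d in range(p):
                fmeans[t, d] += w[k] * xn[k, d]
        ess[t] = 1.0 / s2
        if scheme == 0:
            _systematic_indices(w, idx)
        else:
            _multinomial_indices(w, idx)
        for k in range(K):
            for d in range(p):
                x[k, d] = xn[idx[k], d]
    return loglik, fmeans, ess, -1


# ---------------------------------------------------------------------------
# MIF2 (p = 2): one filtering iteration per call
#
# All randomness is pre-generated by the caller (numpy's ziggurat sampler is
# markedly faster than drawing scalars in-kernel, and it keeps the kernels
# pure functions): perturb (T, K, D) and state (T, K, 2) standard normals,
# init (K, 2) initial-state normals, u (T,) resampling uniforms.
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=_FM)
def _systematic_indices_u(w, u0, out):
    K = w.shape[0]
    u = u0 / K
    c = w[0]
    i = 0
    for k in range(K):
        target = u + k / K
        while c < target and i < K - 1:
            i += 1
            c += w[i]
        out[k] = i


@njit(cache=True, fastmath=_FM)
def mif2_grm_iteration(y, state_idx, alpha, beta_fixed, ncat, toff, est_meas,
                       theta, sd_m, perturb, state_noise, init, u):
    """One MIF2 iteration (a full filtering pass) for the 2-state GR model.

    theta (K, D) is the parameter swarm carried over from the previous
    iteration, modified in place; layout [a11, a12, a21, a22, (per-item
    threshold blocks: first value then log intervals)].  sd_m (D,) is the
    cooled perturbation SD for this iteration.  Returns (loglik, err_t).
    """
    T, q = y.shape
    K, D = theta.shape
    x = np.empty((K, 2))
    xn = np.empty((K, 2))
    th_new = np.empty((K, D))
    logw = np.empty(K)
    w = np.empty(K)
    idx = np.empty(K, dtype=np.int64)
    for k in range(K):
        x[k, 0] = init[k, 0]
        x[k, 1] = init[k, 1]
    ll = 0.0
    for t in range(T):
        maxlw = -np.inf
        for k in range(K):
            for d in range(D):
                theta[k, d] += sd_m[d] * perturb[t, k, d]
            feas, s1, s2 = _identify_p2(theta[k, 0], theta[k, 1], theta[k, 2], theta[k, 3])
            if not feas:
                logw[k] = -np.inf
                continue
            nx0 = theta[k, 0] * x[k, 0] + theta[k, 1] * x[k, 1] + np.sqrt(s1) * state_noise[t, k, 0]
            nx1 = theta[k, 2] * x[k, 0] + theta[k, 3] * x[k, 1] + np.sqrt(s2) * state_noise[t, k, 1]
            xn[k, 0] = nx0
            xn[k, 1] = nx1
            lw = 0.0
            for i in range(q):
                j = y[t, i]
                if j <= 0:
                    continue
                xv = nx0 if state_idx[i] == 0 else nx1
                Ji = ncat[i]
                if est_meas:
                    base = toff[i]
                    # cumulative decode up to the two boundaries we need
                    if j > 1:
                        blo = theta[k, base]
                        for v in range(2, j):
                            blo += np.exp(theta[k, base + v - 1])
                        lo = _logistic(alpha[i] * (xv - blo))
                    else:
                        blo = 0.0
                        lo = 1.0
                    if j < Ji:
                        if j == 1:
                            bj = theta[k, base]
                        else:
                            bj = blo + np.exp(theta[k, base + j - 1])
                        hi = _logistic(alpha[i] * (xv - bj))
                    else:
                        hi = 0.0
                    dprob = lo - hi
                    if dprob < 1e-300:
                        dprob = 1e-300
                    lw += np.log(dprob)
                else:
                    lw += _grm_cat_logprob(xv, j, Ji, alpha[i], beta_fixed[i])
            logw[k] = lw
            if lw > maxlw:
                maxlw = lw
        if maxlw == -np.inf:
            return ll, t
        sw = 0.0
        for k in range(K):
            w[k] = np.exp(logw[k] - maxlw)
            sw += w[k]
        ll += maxlw + np.log(sw / K)
        for k in range(K):
            w[k] /= sw
        _systematic_indices_u(w, u[t], idx)
        for k in range(K):
            src = idx[k]
            x[k, 0] = xn[src, 0]
            x[k, 1] = xn[src, 1]
            for d in range(D):
                th_new[k, d] = theta[src, d]
        for k in range(K):
            for d in range(D):
                theta[k, d] = th_new[k, d]
    return ll, -1


@njit(cache=True, fastmath=_FM)
def mif2_linear_iteration(y, state_idx, center, loading0, err_var0, est_meas,
                          theta, sd_m, perturb, state_noise, init, u):
    """One MIF2 iteration for the 2-state linear-approximation model.

    theta layout: [a11, a12, a21, a22, (loadings (q), log error vars (q))]
    when est_meas, else just the 4 dynamics entries (loading0/err_var0
    fixed)."""
    T, q = y.shape
    K, D = theta.shape
    x = np.empty((K, 2))
    xn = np.empty((K, 2))
    th_new = np.empty((K, D))
    logw = np.empty(K)
    w = np.empty(K)
    idx = np.empty(K, dtype=np.int64)
    for k in range(K):
        x[k, 0] = init[k, 0]
        x[k, 1] = init[k, 1]
    ll = 0.0
    for t in range(T):
        maxlw = -np.inf
        for k in range(K):
            for d in range(D):
                theta[k, d] += sd_m[d] * perturb[t, k, d]
            feas, s1, s2 = _identify_p2(theta[k, 0], theta[k, 1], theta[k, 2], theta[k, 3])
            if not feas:
                logw[k] = -np.inf
                continue
            nx0 = theta[k, 0] * x[k, 0] + theta[k, 1] * x[k, 1] + np.sqrt(s1) * state_noise[t, k, 0]
            nx1 = theta[k, 2] * x[k, 0] + theta[k, 3] * x[k, 1] + np.sqrt(s2) * state_noise[t, k, 1]
            xn[k, 0] = nx0
            xn[k, 1] = nx1
            lw = 0.0
            for i in range(q):
                yv = y[t, i]
                if np.isnan(yv):
                    continue
                xv = nx0 if state_idx[i] == 0 else nx1
                if est_meas:
                    lam = theta[k, 4 + i]
                    v = np.exp(theta[k, 4 + q + i])
                else:
                    lam = loading0[i]
                    v = err_var0[i]
                r = yv - center[i] - lam * xv
                lw += -0.5 * (LOG_2PI + np.log(v) + r * r / v)
            logw[k] = lw
            if lw > maxlw:
                maxlw = lw
        if maxlw == -np.inf:
            return ll, t
        sw = 0.0
        for k in range(K):
            w[k] = np.exp(logw[k] - maxlw)
            sw += w[k]
        ll += maxlw + np.log(sw / K)
        for k in range(K):
            w[k] /= sw
        _systematic_indices_u(w, u[t], idx)
        for k in range(K):
            src = idx[k]
            x[k, 0] = xn[src, 0]
            x[k, 1] = xn[src, 1]
            for d in range(D):
                th_new[k, d] = theta[src, d]
        for k in range(K):
            for d in range(D):
                theta[k, d] = th_new[k, d]
    return ll, -1
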