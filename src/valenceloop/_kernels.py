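"""Compiled scalar kernels for the sequential filter/smoother recursions.

The forward filter and fixed-interval smoother are inherently sequential in
time, and the EM loop re-runs them hundreds of times over thousands of bins,
so the inner recursions are JIT-compiled with numba.  Everything here works
on plain float64 arrays; the public API lives in ``mixed_filter``.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def sigmoid(t: float) -> float:
    if t >= 0.0:
        return 1.0 / (1.0 + math.exp(-t))
    e = math.exp(t)
    return e / (1.0 + e)


@njit(cache=True)
def update_step(x_pred, v_pred, z, n, alpha, beta, gamma, sigma_w2,
                use_binary, tol, max_iter):
    """One implicit posterior-mode update.

    Solves  x = x_pred + C [ beta (z - alpha - beta x_pred)
                             + sigma_w2 (n - p(x)) ]
    with C = v_pred / (beta^2 v_pred + sigma_w2) and p(x) the sigmoidal
    spike probability.  The left side is monotone in x so the root is
    unique; Newton starts at x_pred with a bisection fallback on the
    bracket implied by p in (0, 1).

    Returns (x_filt, v_filt, gain, n_newton_iters); the iteration count is
    -1 if the tolerance was not met within max_iter.
    """
    C = v_pred / (beta * beta * v_pred + sigma_w2)
    base = x_pred + C * beta * (z - alpha - beta * x_pred)
    if not use_binary:
        v = 1.0 / (1.0 / v_pred + beta * beta / sigma_w2)
        return base, v, C, 0
    lo = base + C * sigma_w2 * (n - 1.0)
    hi = base + C * sigma_w2 * n
    x = x_pred
    if x < lo:
        x = lo
    elif x > hi:
        x = hi
    status = -1
    for it in range(max_iter):
        p = sigmoid(gamma + x)
        g = x - base - C * sigma_w2 * (n - p)
        if abs(g) < tol:
            status = it
            break
        # keep the bracket valid: g is increasing in x
        if g > 0.0:
            hi = x
        else:
            lo = x
        gp = 1.0 + C * sigma_w2 * p * (1.0 - p)
        xn = x - g / gp
        if xn <= lo or xn >= hi:
            xn = 0.5 * (lo + hi)
        x = xn
    p = sigmoid(gamma + x)
    v = 1.0 / (1.0 / v_pred + p * (1.0 - p) + beta * beta / sigma_w2)
    return x, v, C, status


@njit(cache=True)
def filter_loop(n, z, alpha, beta, gamma, sigma_e2, sigma_w2, x0, v0,
                use_binary, tol, max_iter):
    """Forward mixed-filter recursion over a whole sequence."""
    K = z.shape[0]
    x_pred = np.empty(K)
    v_pred = np.empty(K)
    x_filt = np.empty(K)
    v_filt = np.empty(K)
    gain = np.empty(K)
    n_iter = np.empty(K, dtype=np.int64)
    xp = x0
    vp = v0
    for k in range(K):
        x_pred[k] = xp
        v_pred[k] = vp
        xf, vf, C, st = update_step(xp, vp, z[k], n[k], alpha, beta, gamma,
                                    sigma_w2, use_binary, tol, max_iter)
        x_filt[k] = xf
        v_filt[k] = vf
        gain[k] = C
        n_iter[k] = st
        xp = xf
        vp = vf + sigma_e2
    return x_pred, v_pred, x_filt, v_filt, gain, n_iter


@njit(cache=True)
def smooth_loop(x_pred, v_pred, x_filt, v_filt):
    """Backward fixed-interval smoothing recursion."""
    K = x_filt.shape[0]
    x_sm = np.empty(K)
    v_sm = np.empty(K)
    A = np.empty(max(K - 1, 0))
    x_sm[K - 1] = x_filt[K - 1]
    v_sm[K - 1] = v_filt[K - 1]
    for k in range(K - 2, -1, -1):
        a = v_filt[k] / v_pred[k + 1]
        A[k] = a
        x_sm[k] = x_filt[k] + a * (x_sm[k + 1] - x_pred[k + 1])
        v_sm[k] = v_filt[k] + a * a * (v_sm[k + 1] - v_pred[k + 1])
    return x_sm, v_sm, A
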