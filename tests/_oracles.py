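"""Independent reference implementations used only as test oracles."""

import numpy as np


def kalman_rts(z, alpha, beta, se2, sw2, x0, v0):
    """Textbook scalar Kalman filter + RTS smoother for
    z_k = alpha + beta x_k + noise over a random-walk state.

    Written in gain form (the implementation under test uses the
    information form for the update variance).
    """
    z = np.asarray(z, dtype=float)
    K = len(z)
    xp = np.empty(K)
    vp = np.empty(K)
    xf = np.empty(K)
    vf = np.empty(K)
    x_prev, v_prev = x0, v0
    for k in range(K):
        xp[k], vp[k] = x_prev, v_prev
        S = beta ** 2 * vp[k] + sw2
        G = vp[k] * beta / S
        xf[k] = xp[k] + G * (z[k] - alpha - beta * xp[k])
        vf[k] = (1.0 - G * beta) * vp[k]
        x_prev, v_prev = xf[k], vf[k] + se2
    xs = xf.copy()
    vs = vf.copy()
    for k in range(K - 2, -1, -1):
        A = vf[k] / vp[k + 1]
        xs[k] = xf[k] + A * (xs[k + 1] - xp[k + 1])
        vs[k] = vf[k] + A ** 2 * (vs[k + 1] - vp[k + 1])
    return xp, vp, xf, vf, xs, vs


def posterior_mode_grid(x_pred, v_pred, z, n, alpha, beta, gamma, sw2,
                        span=10.0):
    """Grid-search argmax of the exact one-step log posterior, refined to
    ~1e-8 resolution around the coarse maximum."""

    def logpost(x):
        t = gamma + x
        # log p and log(1-p) in a numerically stable form
        log_p = -np.logaddexp(0.0, -t)
        log_q = -np.logaddexp(0.0, t)
        return (-(x - x_pred) ** 2 / (2.0 * v_pred)
                + n * log_p + (1 - n) * log_q
                - (z - alpha - beta * x) ** 2 / (2.0 * sw2))

    xs = np.linspace(x_pred - span, x_pred + span, 200_001)
    best = xs[np.argmax(logpost(xs))]
    step = xs[1] - xs[0]
    for _ in range(3):
        xs = np.linspace(best - 2 * step, best + 2 * step, 2001)
        best = xs[np.argmax(logpost(xs))]
        step = xs[1] - xs[0]
    return best


def centroid_riemann(mu_fn, lo, hi, n_points=1_000_001):
    """Fine-quadrature centroid of a membership function on [lo, hi]."""
    x = np.linspace(lo, hi, n_points)
    mu = mu_fn(x)
    denom = np.trapezoid(mu, x)
    if denom <= 0:
        return 0.0
    return float(np.trapezoid(mu * x, x) / denom)
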