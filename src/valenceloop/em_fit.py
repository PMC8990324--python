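"""Expectation-maximization estimation of the valence state-space model.

Estimates theta = [alpha, beta, sigma_eps^2, sigma_omega^2] together with
the hidden state from joint binary + continuous features.  The E-step runs
the mixed filter and fixed-interval smoother (``mixed_filter``); the M-step
has closed forms: the smoothed initial state, a 2x2 normal-equation solve
for (alpha, beta), and moment-matching updates for the two variances using
the smoothed second moments W and the lag-one cross moments.

The sigmoid offset gamma is not part of theta: the level of the latent
state is not separately identifiable from (gamma, alpha), so gamma is
pinned at initialization from the empirical spike rate (anchoring
p = mean(n) at x = 0) and held fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mixed_filter
from .valence_ssm import ValenceParams

__all__ = ["EMResult", "init_params", "m_step", "fit", "gaussian_loglik"]

log = logging.getLogger(__name__)

_VAR_FLOOR = 1e-8


@dataclass
class EMResult:
    params: ValenceParams
    trajectory: mixed_filter.SmoothedTrajectory
    posterior: mixed_filter.FilterPosterior
    n_iters: int
    converged: bool
    param_history: pd.DataFrame
    ci95: np.ndarray  # (K, 2) lower/upper band around x_sm


def init_params(n, z, min_K: int = 10) -> ValenceParams:
    """Data-driven starting values for EM.

    alpha starts at the feature mean, beta at 1, sigma_omega^2 at the
    feature variance, sigma_eps^2 at 0.005 per bin; gamma is the logit of
    the spike rate clipped away from 0 and 1 by 1/K.
    """
    n = np.asarray(n, dtype=float)
    z = np.asarray(z, dtype=float)
    K = len(z)
    if K < min_K:
        raise ValueError(f"need at least {min_K} bins, got {K}")
    var_z = float(np.var(z))
    if var_z < 1e-6:
        var_z = 1e-6
    p_bar = float(np.mean(n))
    p_bar = min(max(p_bar, 1.0 / K), 1.0 - 1.0 / K)
    gamma = float(np.log(p_bar / (1.0 - p_bar)))
    return ValenceParams(alpha=float(np.mean(z)), beta=1.0,
                         sigma_eps2=0.005, sigma_omega2=var_z,
                         gamma=gamma, x0=0.0)


def m_step(sm: mixed_filter.SmoothedTrajectory, n, z,
           params: ValenceParams) -> ValenceParams:
    """Closed-form parameter update given smoothed moments.

    ``params`` supplies the held-fixed gamma and the current sigma_eps^2
    used for the x0 boundary moment W_0 = sigma_eps^2 + x0^2.
    """
    z = np.asarray(z, dtype=float)
    x = sm.x_sm
    W = sm.W
    K = len(x)

    x0_new = float(x[0])

    Sx = float(np.sum(x))
    SW = float(np.sum(W))
    Sz = float(np.sum(z))
    Sxz = float(np.sum(x * z))
    Sz2 = float(np.sum(z * z))

    M = np.array([[K, Sx], [Sx, SW]])
    rhs = np.array([Sz, Sxz])
    det = K * SW - Sx * Sx
    if abs(det) < 1e-12 * max(abs(K * SW), 1.0):
        warnings.warn("near-singular normal equations (constant smoothed "
                      "state); adding ridge", RuntimeWarning)
        M = M + 1e-8 * np.eye(2)
    alpha, beta = np.linalg.solve(M, rhs)

    sw2 = (Sz2 + K * alpha ** 2 + beta ** 2 * SW - 2 * alpha * Sz
           - 2 * beta * Sxz + 2 * alpha * beta * Sx) / K
    sw2 = max(float(sw2), _VAR_FLOOR)

    # process-noise update: K^-1 sum_k [W_k - 2 W_{k-1,k} + W_{k-1}]
    # with the k=1 term using the x0 moments W_0 = sigma_eps^2 + x0^2.
    W0 = params.sigma_eps2 + x0_new ** 2
    W_prev = np.concatenate(([W0], W[:-1]))
    Wc = sm.W_cross.copy()
    Wc[0] = sm.cov_cross[0] + x0_new * x[0]
    se2 = float(np.sum(W - 2.0 * Wc + W_prev)) / K
    se2 = max(se2, _VAR_FLOOR)

    return ValenceParams(alpha=float(alpha), beta=float(beta),
                         sigma_eps2=se2, sigma_omega2=sw2,
                         gamma=params.gamma, x0=x0_new)


def _rel_change(new: ValenceParams, old: ValenceParams) -> float:
    pairs = [(new.alpha, old.alpha), (new.beta, old.beta),
             (new.sigma_eps2, old.sigma_eps2),
             (new.sigma_omega2, old.sigma_omega2)]
    return max(abs(a - b) / (abs(b) + 1e-12) for a, b in pairs)


def fit(n, z, init: ValenceParams | None = None, tol: float = 1e-6,
        max_iters: int = 500, use_binary: bool = True) -> EMResult:
    """Alternate E (filter -> smooth -> moments) and M steps to convergence.

    Convergence is the maximum relative parameter change dropping below
    ``tol``; non-convergence within ``max_iters`` only flags the result.
    The returned trajectory and the 95% band ``x_sm +- 1.96 sqrt(v_sm)``
    come from a final E-step at the fitted parameters.
    """
    n = np.asarray(n, dtype=float)
    z = np.asarray(z, dtype=float)
    params = init if init is not None else init_params(n, z)
    history = [dict(iteration=0, **params.as_dict())]
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        post = mixed_filter.filter_sequence(n, z, params,
                                            use_binary=use_binary)
        sm = mixed_filter.smooth(post)
        new_params = m_step(sm, n, z, params)
        change = _rel_change(new_params, params)
        params = new_params
        history.append(dict(iteration=it, **params.as_dict()))
        if change < tol:
            converged = True
            break
    post = mixed_filter.filter_sequence(n, z, params, use_binary=use_binary)
    sm = mixed_filter.smooth(post)
    half = 1.96 * np.sqrt(sm.v_sm)
    ci95 = np.column_stack([sm.x_sm - half, sm.x_sm + half])
    return EMResult(params=params, trajectory=sm, posterior=post,
                    n_iters=it, converged=converged,
                    param_history=pd.DataFrame(history), ci95=ci95)


def gaussian_loglik(z, params: ValenceParams) -> float:
    """Observed-data log-likelihood of the continuous channel alone.

    Prediction-error decomposition of the linear-Gaussian sub-model
    (binary channel disabled).  EM on that sub-model must not decrease
    this quantity across iterations.
    """
    z = np.asarray(z, dtype=float)
    post = mixed_filter.filter_sequence(np.zeros_like(z), z, params,
                                        use_binary=False)
    S = params.beta ** 2 * post.v_pred + params.sigma_omega2
    innov = z - params.alpha - params.beta * post.x_pred
    return float(np.sum(-0.5 * np.log(2 * np.pi * S)
                        - 0.5 * innov ** 2 / S))


def result_to_frames(res: EMResult):
    """(state_frame, params_dict) export used by the CLI."""
    K = len(res.trajectory)
    state = pd.DataFrame({
        "k": np.arange(K),
        "x_sm": res.trajectory.x_sm,
        "v_sm": res.trajectory.v_sm,
        "ci_lo": res.ci95[:, 0],
        "ci_hi": res.ci95[:, 1],
    })
    return state, res.params.as_dict()
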