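"""Kalman-based mixed filter and fixed-interval smoother for a scalar state.

The filter fuses, per 0.5-s bin, a Bernoulli observation (through a
sigmoidal link) and a linear-Gaussian observation of the same latent
valence state.  The prediction step is the Chapman-Kolmogorov step of the
random-walk state model; the update step is the posterior mode of the
one-step posterior

    exp(-(x - x_pred)^2 / 2 v_pred) * p(x)^n (1 - p(x))^(1-n)
        * exp(-(z - alpha - beta x)^2 / 2 sigma_omega^2)

which is found by a safeguarded Newton iteration (the scalar stationarity
equation is monotone, so the mode is unique).  The backward pass is the
standard fixed-interval (RTS-type) smoother, extended with the lag-one
cross-covariance and the second-moment sequences the EM M-step consumes.

With the binary channel disabled the recursions collapse exactly to the
textbook scalar Kalman filter / RTS smoother, which is used as an
independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import SolverError
from .valence_ssm import ValenceParams

__all__ = [
    "FilterPosterior",
    "SmoothedTrajectory",
    "OnlineMixedFilter",
    "predict",
    "update",
    "filter_sequence",
    "smooth",
]

NEWTON_TOL = 1e-10
NEWTON_MAX_ITER = 50


@dataclass
class FilterPosterior:
    """Forward-filter output: one-step predictions and filtered moments."""

    x_pred: np.ndarray
    v_pred: np.ndarray
    x_filt: np.ndarray
    v_filt: np.ndarray
    gain: np.ndarray
    x0: float = 0.0
    v0: float = 0.0

    def __len__(self) -> int:
        return len(self.x_filt)


@dataclass
class SmoothedTrajectory:
    """Smoother output plus the moments needed by the EM M-step.

    ``cov_cross[k]`` is the smoothed lag-one covariance Cov(x_{k-1}, x_k |
    all data); ``W[k] = v_sm[k] + x_sm[k]^2`` and ``W_cross[k] =
    cov_cross[k] + x_sm[k-1] * x_sm[k]`` are the corresponding second
    moments.  Index 0 of the cross sequences refers to the (x0, x_1) pair.
    """

    x_sm: np.ndarray
    v_sm: np.ndarray
    A: np.ndarray
    W: np.ndarray
    W_cross: np.ndarray
    cov_cross: np.ndarray

    def __len__(self) -> int:
        return len(self.x_sm)


def predict(x_prev_filt: float, v_prev_filt: float,
            sigma_eps2: float) -> tuple[float, float]:
    """One-step prediction of the random-walk state: mean unchanged,
    variance inflated by the process noise."""
    if v_prev_filt <= 0:
        raise ValueError("v_prev_filt must be > 0")
    return x_prev_filt, v_prev_filt + sigma_eps2


def update(x_pred: float, v_pred: float, z_k: float, n_k: int,
           params: ValenceParams, use_binary: bool = True,
           ) -> tuple[float, float, float]:
    """Mixed-observation update at one bin.

    Returns ``(x_filt, v_filt, gain)``.  With ``use_binary=False`` the
    binary correction is dropped and the update is the exact scalar Kalman
    update for the continuous channel.
    """
    if v_pred <= 0:
        raise ValueError("v_pred must be > 0")
    if n_k not in (0, 1):
        raise ValueError(f"n_k must be 0 or 1, got {n_k}")
    xf, vf, C, status = _kernels.update_step(
        float(x_pred), float(v_pred), float(z_k), float(n_k),
        params.alpha, params.beta, params.gamma, params.sigma_omega2,
        use_binary, NEWTON_TOL, NEWTON_MAX_ITER)
    if status < 0:
        raise SolverError(
            f"implicit update did not converge in {NEWTON_MAX_ITER} "
            f"iterations (x_pred={x_pred}, n={n_k}, z={z_k})",
            last_iterate=xf)
    return xf, vf, C


def filter_sequence(n, z, params: ValenceParams,
                    v0: float | None = None,
                    use_binary: bool = True) -> FilterPosterior:
    """Run the forward filter over aligned binary/continuous sequences.

    Starts from ``(params.x0, v0)`` where ``v0`` defaults to the process
    noise variance.  Batch output is identical to feeding the same data one
    bin at a time through :class:`OnlineMixedFilter`.
    """
    n = np.ascontiguousarray(n, dtype=np.float64)
    z = np.ascontiguousarray(z, dtype=np.float64)
    if n.shape != z.shape:
        raise ValueError("n and z must have equal length")
    if v0 is None:
        v0 = params.sigma_eps2
    if len(z) == 0:
        e = np.empty(0)
        return FilterPosterior(e, e.copy(), e.copy(), e.copy(), e.copy(),
                               x0=params.x0, v0=v0)
    x_pred, v_pred, x_filt, v_filt, gain, n_iter = _kernels.filter_loop(
        n, z, params.alpha, params.beta, params.gamma,
        params.sigma_eps2, params.sigma_omega2, params.x0, float(v0),
        use_binary, NEWTON_TOL, NEWTON_MAX_ITER)
    bad = np.nonzero(n_iter < 0)[0]
    if bad.size:
        k = int(bad[0])
        raise SolverError(
            f"implicit update failed to converge at bin {k}",
            last_iterate=float(x_filt[k]))
    return FilterPosterior(x_pred, v_pred, x_filt, v_filt, gain,
                           x0=params.x0, v0=v0)


class OnlineMixedFilter:
    """Streaming wrapper around predict/update for closed-loop use.

    Feeding observations one bin at a time reproduces
    :func:`filter_sequence` exactly.
    """

    def __init__(self, params: ValenceParams, v0: float | None = None,
                 use_binary: bool = True):
        self.params = params
        self.use_binary = use_binary
        self._x_pred = params.x0
        self._v_pred = params.sigma_eps2 if v0 is None else v0
        self.x_filt: list[float] = []
        self.v_filt: list[float] = []

    def step(self, n_k: int, z_k: float) -> tuple[float, float]:
        xf, vf, _ = update(self._x_pred, self._v_pred, z_k, n_k,
                           self.params, self.use_binary)
        self.x_filt.append(xf)
        self.v_filt.append(vf)
        self._x_pred, self._v_pred = predict(xf, vf, self.params.sigma_eps2)
        return xf, vf


def smooth(post: FilterPosterior) -> SmoothedTrajectory:
    """Backward fixed-interval smoother with EM moment sequences.

    Initialised at the last filtered moments; ``A_k = v_filt[k] /
    v_pred[k+1]``.  The lag-one covariance is ``cov_cross[k] = A_{k-1}
    v_sm[k]``; its k=0 boundary (the x0/x_1 pair) uses the prior gain
    ``v0 / v_pred[0]`` which equals one under the default ``v0`` choice.
    """
    if len(post) == 0:
        raise ValueError("cannot smooth an empty posterior")
    x_sm, v_sm, A = _kernels.smooth_loop(post.x_pred, post.v_pred,
                                         post.x_filt, post.v_filt)
    K = len(x_sm)
    cov_cross = np.empty(K)
    cov_cross[0] = (post.v0 / post.v_pred[0]) * v_sm[0]
    if K > 1:
        cov_cross[1:] = A * v_sm[1:]
    W = v_sm + x_sm ** 2
    W_cross = np.empty(K)
    W_cross[0] = cov_cross[0] + post.x0 * x_sm[0]
    if K > 1:
        W_cross[1:] = cov_cross[1:] + x_sm[:-1] * x_sm[1:]
    return SmoothedTrajectory(x_sm=x_sm, v_sm=v_sm, A=A, W=W,
                              W_cross=W_cross, cov_cross=cov_cross)


def posterior_to_frame(post: FilterPosterior,
                       sm: SmoothedTrajectory | None = None):
    """CSV-ready export of filter (and optionally smoother) moments."""
    import pandas as pd

    d = {
        "k": np.arange(len(post)),
        "x_pred": post.x_pred,
        "v_pred": post.v_pred,
        "x_filt": post.x_filt,
        "v_filt": post.v_filt,
    }
    if sm is not None:
        d["x_sm"] = sm.x_sm
        d["v_sm"] = sm.v_sm
    return pd.DataFrame(d)
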