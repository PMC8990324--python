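"""Generative state-space model of emotional valence.

The latent valence state ``x_k`` follows a first-order random walk driven by
process noise, an exogenous environmental stimulus ``s_k`` and a control
input ``u_k``::

    x_{k+1} = x_k + eps_k + s_k + u_k,        eps_k ~ N(0, sigma_eps^2)

Two observation channels are emitted from the state each bin: a binary
"spike" ``n_k ~ Bernoulli(p_k)`` with a sigmoidal link
``p_k = exp(gamma + x_k) / (1 + exp(gamma + x_k))``, and a continuous
feature ``z_k = alpha + beta * x_k + omega_k`` with
``omega_k ~ N(0, sigma_omega^2)``.  One state step corresponds to one 0.5-s
feature bin (2 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValenceParams",
    "LatentTrajectory",
    "step_state",
    "spike_prob",
    "emit_observations",
    "simulate",
]

BIN_LEN_S = 0.5
"""Default duration of one state/feature bin in seconds."""


@dataclass
class ValenceParams:
    """Parameter set theta of the valence state-space model.

    Attributes
    ----------
    alpha : float
        Baseline level of the continuous feature.
    beta : float
        Gain of the continuous feature with respect to the state.
    sigma_eps2 : float
        Process-noise variance (per 0.5-s step); must be positive.
    sigma_omega2 : float
        Continuous observation-noise variance; must be positive.
    gamma : float
        Offset of the sigmoidal binary link.
    x0 : float
        Initial latent state.
    """

    alpha: float = 0.0
    beta: float = 1.0
    sigma_eps2: float = 0.005
    sigma_omega2: float = 0.01
    gamma: float = 0.0
    x0: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.alpha, self.beta, self.sigma_eps2, self.sigma_omega2,
                self.gamma, self.x0)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all parameters must be finite")
        if self.sigma_eps2 <= 0:
            raise ValueError(f"sigma_eps2 must be > 0, got {self.sigma_eps2}")
        if self.sigma_omega2 <= 0:
            raise ValueError(f"sigma_omega2 must be > 0, got {self.sigma_omega2}")

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "sigma_eps2": self.sigma_eps2,
            "sigma_omega2": self.sigma_omega2,
            "gamma": self.gamma,
            "x0": self.x0,
        }


@dataclass
class LatentTrajectory:
    """Latent state path together with the inputs that produced it."""

    x: np.ndarray
    s: np.ndarray
    u: np.ndarray
    bin_len_s: float = BIN_LEN_S

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if not (len(self.x) == len(self.s) == len(self.u)):
            raise ValueError("x, s, u must have equal lengths")

    def __len__(self) -> int:
        return len(self.x)


def step_state(x_k: float, s_k: float, u_k: float, params: ValenceParams,
               rng: np.random.Generator) -> float:
    """Advance the latent state by one bin (state equation)."""
    eps = rng.normal(0.0, math.sqrt(params.sigma_eps2))
    return x_k + eps + s_k + u_k


def spike_prob(x_k, gamma: float):
    """Sigmoidal spike probability ``p_k`` given state and link offset.

    Strictly inside (0, 1) and monotone increasing in ``x_k``.  Accepts
    scalars or arrays.
    """
    t = np.asarray(gamma + np.asarray(x_k, dtype=float))
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    if np.isscalar(x_k) or np.ndim(x_k) == 0:
        return float(out)
    return out


def emit_observations(x_k: float, params: ValenceParams,
                      rng: np.random.Generator) -> tuple[int, float]:
    """Draw one (n_k, z_k) pair from the two observation models."""
    p = spike_prob(x_k, params.gamma)
    n = int(rng.random() < p)
    z = params.alpha + params.beta * x_k + rng.normal(
        0.0, math.sqrt(params.sigma_omega2))
    return n, z


def simulate(params: ValenceParams, K: int,
             s=None, u=None,
             rng: np.random.Generator | int | None = None,
             ) -> tuple[LatentTrajectory, np.ndarray, np.ndarray]:
    """Simulate a full trajectory plus observations.

    Parameters
    ----------
    params : ValenceParams
    K : int
        Number of bins to simulate.
    s, u : array-like or None
        Stimulus / control sequences of length K (or K-1; only the first
        K-1 entries drive transitions).  ``None`` means identically zero,
        which reproduces the open-loop model used during estimation.
    rng : numpy Generator or seed

    Returns
    -------
    (trajectory, n, z)
        The latent trajectory and the binary / continuous observations,
        each of length K.
    """
    rng = np.random.default_rng(rng)
    s_arr = np.zeros(K) if s is None else np.resize(np.asarray(s, float), K)
    u_arr = np.zeros(K) if u is None else np.resize(np.asarray(u, float), K)
    x = np.empty(K)
    n = np.empty(K, dtype=np.int64)
    z = np.empty(K)
    xk = params.x0
    for k in range(K):
        x[k] = xk
        n[k], z[k] = emit_observations(xk, params, rng)
        xk = step_state(xk, s_arr[k], u_arr[k], params, rng)
    return LatentTrajectory(x=x, s=s_arr, u=u_arr), n, z


def trajectory_to_frame(traj: LatentTrajectory, n=None, z=None):
    """Export a trajectory (and optional observations) as a DataFrame."""
    import pandas as pd

    d = {"k": np.arange(len(traj)), "x": traj.x, "s": traj.s, "u": traj.u}
    if n is not None:
        d["n"] = np.asarray(n)
    if z is not None:
        d["z"] = np.asarray(z)
    return pd.DataFrame(d)
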