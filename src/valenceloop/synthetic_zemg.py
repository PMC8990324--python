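"""Synthetic facial-EMG generator with known ground truth.

Produces raw zEMG-like recordings so the full front-end -> EM -> stimulus
pipeline can be exercised without any external dataset.  A recording is a
sequence of labeled 1-min HV/LV trials: within each trial a bin-rate
latent valence path (class target plus random-walk wander) modulates the
envelope of band-limited (20-240 Hz) Gaussian noise, and 50 Hz line
interference plus weak harmonics is added on top.  The latent path and
trial labels are always returned alongside the samples.

Model-exact feature data (bypassing the raw-EMG layer) for estimator
recovery experiments is produced by :func:`generate_feature_data` and its
trial-concatenating variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import signal

from .emg_features import FeatureSeries, RawEMG
from .valence_ssm import BIN_LEN_S, ValenceParams, simulate, spike_prob

__all__ = [
    "SyntheticSpec",
    "generate_recording",
    "generate_feature_data",
    "generate_trialized_feature_data",
]


def _default_envelope_gain(latent):
    """Positive, strictly increasing latent -> envelope map."""
    return np.exp(0.5 * np.asarray(latent, dtype=float))


def _default_trial_plan() -> list[tuple[str, float]]:
    return [("HV", 60.0), ("LV", 60.0)] * 3


@dataclass
class SyntheticSpec:
    """Recording recipe: trial layout, latent targets, noise levels."""

    fs: float = 512.0
    trial_plan: list[tuple[str, float]] = field(
        default_factory=_default_trial_plan)
    latent_plan: dict[str, float] = field(
        default_factory=lambda: {"HV": 1.0, "LV": -1.0})
    wander_sd: float = 0.05          # latent random-walk step sd per bin
    envelope_gain: Callable = _default_envelope_gain
    line_noise_amp: float = 0.1      # 50 Hz amplitude relative to unit-RMS carrier
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fs <= 500:
            raise ValueError("fs must exceed 500 Hz")
        if any(d <= 0 for _, d in self.trial_plan):
            raise ValueError("trial durations must be > 0")
        g = self.envelope_gain(np.array([-1.0, 0.0, 1.0]))
        if not (np.all(g > 0) and np.all(np.diff(g) > 0)):
            raise ValueError("envelope_gain must be positive and "
                             "strictly increasing")


def generate_recording(spec: SyntheticSpec
                       ) -> tuple[RawEMG, np.ndarray, list[str]]:
    """Synthesise one recording.

    Returns ``(raw, latent_truth, labels)``: the raw EMG with 1-based
    trial boundaries, the bin-rate latent path across the whole recording,
    and the per-trial labels.
    """
    rng = np.random.default_rng(spec.seed)
    spb = int(round(spec.fs * BIN_LEN_S))

    latent_parts = []
    boundaries = []
    labels = []
    start = 0
    for tid, (label, dur_s) in enumerate(spec.trial_plan, start=1):
        n_bins = int(round(dur_s / BIN_LEN_S))
        wander = np.cumsum(rng.normal(0.0, spec.wander_sd, n_bins))
        latent_parts.append(spec.latent_plan[label] + wander)
        n_samp = n_bins * spb
        boundaries.append((start, start + n_samp, label))
        labels.append(label)
        start += n_samp
    latent = np.concatenate(latent_parts)
    n_samples = start

    carrier = rng.standard_normal(n_samples)
    sos = signal.butter(3, [20.0, 240.0], btype="bandpass", fs=spec.fs,
                        output="sos")
    carrier = signal.sosfiltfilt(sos, carrier)
    carrier /= np.sqrt(np.mean(carrier ** 2))

    t = np.arange(n_samples) / spec.fs
    centers = (np.arange(len(latent)) + 0.5) * BIN_LEN_S
    env = np.interp(t, centers, spec.envelope_gain(latent))
    line = spec.line_noise_amp * (
        np.sin(2 * np.pi * 50.0 * t)
        + 0.3 * np.sin(2 * np.pi * 100.0 * t)
        + 0.15 * np.sin(2 * np.pi * 150.0 * t))
    samples = carrier * env + line
    raw = RawEMG(samples=samples, fs=spec.fs, trial_boundaries=boundaries)
    return raw, latent, labels


def generate_feature_data(params: ValenceParams, s, K: int,
                          seed=None) -> tuple[FeatureSeries, np.ndarray]:
    """Model-exact (n, z) features plus the true latent path.

    Simulates the open-loop state equation (u = 0) with stimulus ``s``
    (scalar, sequence, or None for zero) and both observation channels
    directly at the bin rate.
    """
    if s is None:
        s_arr = None
    else:
        s_arr = np.broadcast_to(np.asarray(s, dtype=float),
                                (K,)) if np.ndim(s) == 0 else np.asarray(
                                    s, dtype=float)
    traj, n, z = simulate(params, K, s=s_arr, u=None, rng=seed)
    q = spike_prob(traj.x, params.gamma)
    fs = FeatureSeries(n=n, z=z, q=q, bin_len_s=BIN_LEN_S)
    return fs, traj.x


def generate_trialized_feature_data(params: ValenceParams,
                                    n_trials: int = 40,
                                    bins_per_trial: int = 120,
                                    seed=None,
                                    ) -> tuple[FeatureSeries, np.ndarray]:
    """Concatenation of independent fixed-length trials.

    Emulates a session of ``n_trials`` separate 1-min recordings (the
    state restarts at x0 in each trial, as it would across distinct video
    trials) concatenated into one feature sequence of length
    ``n_trials * bins_per_trial``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_trials)
    ns, zs, qs, xs = [], [], [], []
    for child in children:
        fs, x = generate_feature_data(params, None, bins_per_trial,
                                      seed=np.random.default_rng(child))
        ns.append(fs.n)
        zs.append(fs.z)
        qs.append(fs.q)
        xs.append(x)
    fs = FeatureSeries(n=np.concatenate(ns), z=np.concatenate(zs),
                       q=np.concatenate(qs), bin_len_s=BIN_LEN_S)
    return fs, np.concatenate(xs)
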