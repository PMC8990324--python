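"""Environmental-stimulus modeling for the virtual subject.

The exogenous drive s_k on the latent valence state is recovered from an
estimated state trajectory as its first differences, summarised per
valence class (HV / LV) by a 100-term sinusoidal harmonic model

    s_k = sum_j rho_j sin(zeta_j k + phi_j),   j = 1..100,

and re-synthesised into stimulus schedules (e.g., half LV then half HV)
with a short linear transition ramp between classes.  Harmonics are
estimated by magnitude-ranked DFT component selection: deterministic,
exactly the same functional form, and free of the local-minimum issues a
300-parameter nonlinear fit would have.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientTrialsError, TooShortError

__all__ = [
    "StimulusModel",
    "TrialSummary",
    "derive_stimuli",
    "select_trials",
    "fit_harmonics",
    "evaluate_harmonics",
    "synthesize_schedule",
]

N_HARMONICS = 100


@dataclass
class TrialSummary:
    """Per-trial statistics of the estimated valence state."""

    trial_id: int
    label: str  # "HV" or "LV", from self-assessment (above 5 = HV)
    mean_state: float
    sd_state: float

    def __post_init__(self) -> None:
        if self.sd_state < 0:
            raise ValueError("sd_state must be >= 0")
        if self.label not in ("HV", "LV"):
            raise ValueError(f"label must be HV or LV, got {self.label!r}")


@dataclass
class StimulusModel:
    """Per-class harmonic stimulus representations plus transition rule.

    Each harmonics array has shape (100, 3): columns are amplitude rho_j,
    angular frequency zeta_j (radians per bin) and phase phi_j.
    """

    harmonics_hv: np.ndarray
    harmonics_lv: np.ndarray
    transition_s: float = 0.5
    bin_len_s: float = 0.5

    def __post_init__(self) -> None:
        self.harmonics_hv = np.asarray(self.harmonics_hv, dtype=float)
        self.harmonics_lv = np.asarray(self.harmonics_lv, dtype=float)
        for h in (self.harmonics_hv, self.harmonics_lv):
            if h.shape != (N_HARMONICS, 3):
                raise ValueError(f"expected ({N_HARMONICS}, 3) harmonics, "
                                 f"got {h.shape}")
            if np.any(h[:, 0] < 0) or np.any(h[:, 1] < 0):
                raise ValueError("amplitudes and frequencies must be >= 0")

    def for_label(self, label: str) -> np.ndarray:
        if label == "HV":
            return self.harmonics_hv
        if label == "LV":
            return self.harmonics_lv
        raise ConfigError(f"unknown stimulus label {label!r}")


def derive_stimuli(x_sm) -> np.ndarray:
    """First differences of the estimated state; length K-1."""
    x_sm = np.asarray(x_sm, dtype=float)
    if len(x_sm) < 2:
        raise TooShortError("need at least 2 state samples to difference")
    return np.diff(x_sm)


def select_trials(summaries: list[TrialSummary],
                  n_per_class: int = 6) -> tuple[list[int], list[int]]:
    """Pick the most representative trials per valence class.

    HV trials are ranked by the sum of their (descending) rank by mean and
    rank by standard deviation — the "highest mean and standard deviation"
    rule — and LV trials by the ascending analog.  Ties break by trial id.
    Returns (hv_ids, lv_ids), each of length ``n_per_class``.
    """
    out = []
    for label, descending in (("HV", True), ("LV", False)):
        trials = [t for t in summaries if t.label == label]
        if len(trials) < n_per_class:
            raise InsufficientTrialsError(
                f"need >= {n_per_class} {label} trials, got {len(trials)}")
        sign = -1.0 if descending else 1.0
        means = np.array([sign * t.mean_state for t in trials])
        sds = np.array([sign * t.sd_state for t in trials])
        from scipy.stats import rankdata
        combined = rankdata(means, method="average") + rankdata(
            sds, method="average")
        order = sorted(range(len(trials)),
                       key=lambda i: (combined[i], trials[i].trial_id))
        out.append([trials[i].trial_id for i in order[:n_per_class]])
    return out[0], out[1]


def fit_harmonics(s, n_harmonics: int = N_HARMONICS) -> np.ndarray:
    """Magnitude-ranked DFT fit of the harmonic stimulus model.

    Takes the ``n_harmonics`` largest-magnitude frequency bins of the DFT
    of ``s`` (excluding the zero-frequency term) and converts each to an
    (rho, zeta, phi) triple such that sum rho sin(zeta k + phi) evaluated
    at k = 0..N-1 is the band-limited reconstruction.  If fewer informative
    bins exist, the remainder are zero triples.
    """
    s = np.asarray(s, dtype=float)
    N = len(s)
    if N < 2 * n_harmonics:
        raise TooShortError(
            f"need at least {2 * n_harmonics} samples to support "
            f"{n_harmonics} components, got {N}")
    S = np.fft.rfft(s)
    m = np.arange(1, len(S))  # drop the zero-frequency bin
    # real-signal amplitude of bin m (Nyquist bin is not doubled)
    amp = 2.0 * np.abs(S[m]) / N
    if N % 2 == 0:
        amp[-1] = np.abs(S[m[-1]]) / N
    order = np.argsort(-amp, kind="stable")[:n_harmonics]
    triples = np.zeros((n_harmonics, 3))
    sel = m[order]
    triples[:len(sel), 0] = amp[order]
    triples[:len(sel), 1] = 2.0 * np.pi * sel / N
    # cos(x + theta) = sin(x + theta + pi/2)
    triples[:len(sel), 2] = np.angle(S[sel]) + np.pi / 2.0
    return triples


def evaluate_harmonics(triples: np.ndarray, k) -> np.ndarray:
    """Evaluate sum rho sin(zeta k + phi) at bin indices ``k``."""
    k = np.asarray(k, dtype=float)
    triples = np.asarray(triples, dtype=float)
    active = triples[triples[:, 0] > 0]
    if len(active) == 0:
        return np.zeros_like(k)
    rho = active[:, 0][:, None]
    zeta = active[:, 1][:, None]
    phi = active[:, 2][:, None]
    return np.sum(rho * np.sin(zeta * k[None, :] + phi), axis=0)


def synthesize_schedule(model: StimulusModel,
                        schedule: list[tuple[str, float]]) -> np.ndarray:
    """Build a stimulus sequence from ordered (label, duration_s) segments.

    Each segment replays its class harmonic model from the model's own
    time origin (k restarts at 0 per segment).  Across every boundary the
    first ``transition_s`` worth of bins is a linear blend between the
    outgoing and incoming class signals.
    """
    seg_arrays = []
    for label, dur_s in schedule:
        n_bins = dur_s / model.bin_len_s
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ConfigError(
                f"duration {dur_s} s is not a multiple of the "
                f"{model.bin_len_s}-s bin")
        n_bins = int(round(n_bins))
        triples = model.for_label(label)  # raises ConfigError on bad label
        seg_arrays.append(evaluate_harmonics(triples, np.arange(n_bins)))

    ramp_bins = int(round(model.transition_s / model.bin_len_s))
    out = []
    for i, seg in enumerate(seg_arrays):
        seg = seg.copy()
        if i > 0 and ramp_bins > 0 and len(seg):
            prev_label = schedule[i - 1][0]
            prev_triples = model.for_label(prev_label)
            m = min(ramp_bins, len(seg))
            # evaluate the outgoing class just past its segment end
            prev_len = len(seg_arrays[i - 1])
            cont = evaluate_harmonics(prev_triples,
                                      prev_len + np.arange(m))
            w = (np.arange(1, m + 1)) / (m + 1.0)
            seg[:m] = (1.0 - w) * cont + w * seg[:m]
        out.append(seg)
    return np.concatenate(out) if out else np.zeros(0)


def model_to_frame(model: StimulusModel) -> pd.DataFrame:
    rows = []
    for cls, h in (("HV", model.harmonics_hv), ("LV", model.harmonics_lv)):
        for j, (rho, zeta, phi) in enumerate(h, start=1):
            rows.append({"class": cls, "j": j, "rho": rho, "zeta": zeta,
                         "phi": phi})
    return pd.DataFrame(rows)


def model_from_frame(df: pd.DataFrame, transition_s: float = 0.5,
                     bin_len_s: float = 0.5) -> StimulusModel:
    h = {}
    for cls, grp in df.groupby("class"):
        grp = grp.sort_values("j")
        h[cls] = grp[["rho", "zeta", "phi"]].to_numpy(dtype=float)
    return StimulusModel(harmonics_hv=h["HV"], harmonics_lv=h["LV"],
                         transition_s=transition_s, bin_len_s=bin_len_s)
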