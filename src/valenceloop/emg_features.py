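"""Facial-EMG preprocessing and observation-feature extraction.

Raw zygomaticus EMG is band-passed to 10-250 Hz (3rd-order Butterworth,
applied forward-backward so the envelope is not phase-distorted) and
notched at the 50 Hz mains frequency and its next four harmonics.  The
filtered signal is cut into non-overlapping 0.5-s bins and two aligned
per-bin features are extracted:

* a binary "spike" n_k, drawn as Bernoulli(q_k) where q_k = a * y_k is an
  amplitude-dependent probability built from the Gaussian-smoothed
  rectified signal (globally max-normalised so q_k is a valid
  probability; a defaults to 0.5);
* a continuous feature z_k: the natural log of the 10-250 Hz Welch
  bandpower of the bin, min-max normalised to [0, 1] over the whole
  recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .errors import EmptyInputError, TooShortError, UnrepresentableBandError

__all__ = [
    "RawEMG",
    "FilteredEMG",
    "FeatureSeries",
    "bandpass_notch",
    "bin_signal",
    "extract_binary",
    "extract_continuous",
    "extract_features",
]

log = logging.getLogger(__name__)

BAND_LO_HZ = 10.0
BAND_HI_HZ = 250.0
NOTCH_FREQS_HZ = (50.0, 100.0, 150.0, 200.0, 250.0)
NOTCH_Q = 30.0
GAUSS_SIGMA_S = 0.025  # Gaussian kernel std for envelope smoothing
_BANDPOWER_FLOOR = 1e-300


@dataclass
class RawEMG:
    """Single-channel raw EMG: samples, sampling rate, optional trials.

    ``trial_boundaries`` is a list of (start, end, label) half-open index
    intervals with label in {"HV", "LV", "unknown"}.
    """

    samples: np.ndarray
    fs: float
    trial_boundaries: list[tuple[int, int, str]] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.trial_boundaries:
            prev_end = 0
            for (a, b, lab) in sorted(self.trial_boundaries):
                if not (0 <= a < b <= len(self.samples)):
                    raise ValueError(f"trial interval ({a},{b}) out of bounds")
                if a < prev_end:
                    raise ValueError("trial intervals overlap")
                prev_end = b


@dataclass
class FilteredEMG:
    """Band-passed and notched EMG, still at the raw sampling rate."""

    y: np.ndarray
    fs: float
    bin_len_s: float = 0.5


@dataclass
class FeatureSeries:
    """Aligned per-bin observations: binary spikes n, continuous z, and
    the spike probabilities q they were drawn from."""

    n: np.ndarray
    z: np.ndarray
    q: np.ndarray
    bin_len_s: float = 0.5

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n)
        self.z = np.asarray(self.z, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if not (len(self.n) == len(self.z) == len(self.q)):
            raise ValueError("n, z, q must be aligned")

    @property
    def K(self) -> int:
        return len(self.n)


def _design_cascade(fs: float) -> list[np.ndarray]:
    """Second-order sections of the full band-pass + notch cascade."""
    sos = [signal.butter(3, [BAND_LO_HZ, BAND_HI_HZ], btype="bandpass",
                         fs=fs, output="sos")]
    for f0 in NOTCH_FREQS_HZ:
        b, a = signal.iirnotch(f0, NOTCH_Q, fs=fs)
        sos.append(signal.tf2sos(b, a))
    return sos


def cascade_response(fs: float, freqs_hz) -> np.ndarray:
    """|H(f)|^2-equivalent magnitude of the zero-phase cascade.

    Because each filter runs forward and backward, the effective magnitude
    is the product of the section magnitudes squared.
    """
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    mag = np.ones_like(freqs_hz)
    for sec in _design_cascade(fs):
        _, h = signal.sosfreqz(sec, worN=2 * np.pi * freqs_hz / fs)
        mag *= np.abs(h) ** 2
    return mag


def bandpass_notch(raw: RawEMG) -> FilteredEMG:
    """10-250 Hz Butterworth band-pass then 50..250 Hz notches, zero-phase."""
    if raw.samples.size == 0:
        raise EmptyInputError("raw EMG is empty")
    if raw.fs <= 2 * BAND_HI_HZ:
        raise UnrepresentableBandError(
            f"fs={raw.fs} Hz cannot represent the {BAND_HI_HZ} Hz band edge "
            f"(need fs > {2 * BAND_HI_HZ} Hz)")
    y = raw.samples
    for sec in _design_cascade(raw.fs):
        y = signal.sosfiltfilt(sec, y)
    return FilteredEMG(y=y, fs=raw.fs)


def bin_signal(filtered: FilteredEMG) -> np.ndarray:
    """Cut into non-overlapping bins; the trailing partial bin is dropped.

    Returns a (K, samples_per_bin) view.
    """
    spb = int(round(filtered.fs * filtered.bin_len_s))
    K = len(filtered.y) // spb
    if K < 1:
        raise TooShortError(
            f"signal of {len(filtered.y)} samples is shorter than one "
            f"{filtered.bin_len_s}-s bin ({spb} samples)")
    return filtered.y[:K * spb].reshape(K, spb)


def extract_binary(filtered: FilteredEMG, a: float = 0.5,
                   rng: np.random.Generator | int | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin spike draws from the smoothed rectified amplitude.

    The rectified signal is smoothed with a Gaussian kernel (sigma 25 ms),
    normalised by its global maximum so the per-bin mean amplitude y_k lies
    in [0, 1], and each bin fires with probability q_k = min(a * y_k, 1).
    """
    if a <= 0:
        raise ValueError("scale a must be > 0")
    rng = np.random.default_rng(rng)
    bins = bin_signal(filtered)
    smoothed = gaussian_filter1d(np.abs(filtered.y),
                                 sigma=GAUSS_SIGMA_S * filtered.fs)
    peak = smoothed.max()
    if peak > 0:
        smoothed = smoothed / peak
    spb = bins.shape[1]
    K = bins.shape[0]
    y_k = smoothed[:K * spb].reshape(K, spb).mean(axis=1)
    q = np.clip(a * y_k, 0.0, 1.0)
    n = (rng.random(K) < q).astype(np.int64)
    return n, q


def extract_continuous(filtered: FilteredEMG) -> np.ndarray:
    """Per-bin log Welch bandpower (10-250 Hz), min-max normalised.

    Welch windows are half a bin long with 75% overlap and a Hann taper.
    A degenerate recording (all bins equal) maps to 0.5 everywhere.
    """
    bins = bin_signal(filtered)
    nperseg = bins.shape[1] // 2
    if nperseg < 2:
        raise TooShortError("bins too short for a Welch window")
    freqs, psd = signal.welch(bins, fs=filtered.fs, window="hann",
                              nperseg=nperseg,
                              noverlap=(3 * nperseg) // 4,
                              detrend=False, axis=1)
    mask = (freqs >= BAND_LO_HZ) & (freqs <= BAND_HI_HZ)
    power = np.trapezoid(psd[:, mask], freqs[mask], axis=1)
    if np.any(power <= 0):
        log.warning("zero bandpower in %d bin(s); flooring before log",
                    int(np.sum(power <= 0)))
        power = np.maximum(power, _BANDPOWER_FLOOR)
    logp = np.log(power)
    lo, hi = logp.min(), logp.max()
    if hi - lo < 1e-12:
        return np.full(len(logp), 0.5)
    return (logp - lo) / (hi - lo)


def extract_features(raw: RawEMG, a: float = 0.5,
                     rng: np.random.Generator | int | None = None,
                     ) -> FeatureSeries:
    """Full front end: filter, bin, and extract both observation channels."""
    filtered = bandpass_notch(raw)
    n, q = extract_binary(filtered, a=a, rng=rng)
    z = extract_continuous(filtered)
    return FeatureSeries(n=n, z=z, q=q, bin_len_s=filtered.bin_len_s)


def features_to_frame(fs: FeatureSeries) -> pd.DataFrame:
    k = np.arange(fs.K)
    return pd.DataFrame({
        "k": k,
        "t_start_s": k * fs.bin_len_s,
        "n": fs.n,
        "q": fs.q,
        "z": fs.z,
    })


def read_emg_csv(path, fs: float) -> RawEMG:
    """Load a one-column ``emg`` CSV/TSV (optional ``trial``/``label``
    columns become trial boundaries)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if "emg" not in df.columns:
        raise ValueError("input file must have an 'emg' column")
    boundaries = None
    if "trial" in df.columns:
        boundaries = []
        for tid, grp in df.groupby("trial", sort=True):
            label = "unknown"
            if "label" in df.columns:
                label = str(grp["label"].iloc[0])
            idx = grp.index.to_numpy()
            boundaries.append((int(idx[0]), int(idx[-1]) + 1, label))
    return RawEMG(samples=df["emg"].to_numpy(dtype=float), fs=fs,
                  trial_boundaries=boundaries)
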