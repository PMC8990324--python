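"""Closed-loop scenario orchestration and bank-level evaluation.

Runs a virtual subject (state-space parameters plus a per-class harmonic
stimulus model) through the three scenarios — open loop, inhibitory closed
loop, excitatory closed loop — under either stimulus order (LV then HV, or
HV then LV).  Per bin the loop synthesises the stimulus, emits the two
observation channels from the true state, updates the online mixed filter,
computes the fuzzy control effort from the smoothed filtered state
(suspended during the first minute), and steps the state equation.

Open and closed runs with the same seed consume identical pre-drawn noise,
so any difference between them is attributable to the control effort
alone.  Evaluation follows the spike-count / mean-valence paired t-test
design over a bank of subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import fuzzy_control, stimuli
from .errors import CalibrationError, ConfigError
from .mixed_filter import OnlineMixedFilter
from .valence_ssm import (BIN_LEN_S, ValenceParams, emit_observations,
                          step_state)

__all__ = [
    "ScenarioResult",
    "run_scenario",
    "summarize_halves",
    "calibrate_controller",
    "evaluate_bank",
    "make_subject_bank",
    "run_bank",
]

ORDERS = {"lvhv": ("LV", "HV"), "hvlv": ("HV", "LV")}
DEFAULT_DURATION_S = 600.0
DEFAULT_WARMUP_S = 60.0


@dataclass
class ScenarioResult:
    """One simulated session: true state, observations, filter, control."""

    mode: str
    order: str
    seed: int
    s: np.ndarray
    u: np.ndarray
    x_true: np.ndarray
    n: np.ndarray
    z: np.ndarray
    x_filt: np.ndarray
    v_filt: np.ndarray
    labels: np.ndarray          # per-bin "LV"/"HV"
    warmup_bins: int
    bin_len_s: float = BIN_LEN_S

    def __len__(self) -> int:
        return len(self.x_true)

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(len(self))
        return pd.DataFrame({
            "k": k, "t_s": k * self.bin_len_s, "s": self.s, "u": self.u,
            "x_true": self.x_true, "n": self.n, "z": self.z,
            "x_filt": self.x_filt, "v_filt": self.v_filt,
            "label": self.labels,
        })


def _smoothed_history(x_filt: np.ndarray, window_bins: int) -> np.ndarray:
    """Causal moving average, the controller's input signal."""
    out = np.empty_like(x_filt)
    c = np.cumsum(np.concatenate(([0.0], x_filt)))
    for k in range(len(x_filt)):
        a = max(0, k + 1 - window_bins)
        out[k] = (c[k + 1] - c[a]) / (k + 1 - a)
    return out


def run_scenario(params: ValenceParams, model: stimuli.StimulusModel,
                 mode: str, order: str, seed: int,
                 duration_s: float = DEFAULT_DURATION_S,
                 warmup_s: float = DEFAULT_WARMUP_S,
                 controller: fuzzy_control.FuzzyController | None = None,
                 ) -> ScenarioResult:
    """Simulate one session in the given mode.

    ``mode`` is "open", "inhibitory" or "excitatory"; closed modes need a
    ``controller`` calibrated on this subject's open-loop run with the
    same seed (see :func:`calibrate_controller`).
    """
    if order not in ORDERS:
        raise ConfigError(f"order must be one of {sorted(ORDERS)}")
    if mode not in ("open", "inhibitory", "excitatory"):
        raise ConfigError(f"unknown mode {mode!r}")
    if mode != "open":
        if controller is None:
            raise ConfigError(
                "closed-loop modes need a calibrated controller: run the "
                "open-loop scenario first and call calibrate_controller")
        if controller.mode != mode:
            raise ConfigError(f"controller mode {controller.mode!r} does "
                              f"not match scenario mode {mode!r}")

    half_s = duration_s / 2.0
    schedule = [(lab, half_s) for lab in ORDERS[order]]
    s = stimuli.synthesize_schedule(model, schedule)
    K = len(s)
    half_bins = K // 2
    labels = np.array([ORDERS[order][0]] * half_bins
                      + [ORDERS[order][1]] * (K - half_bins))
    warmup_bins = int(round(warmup_s / model.bin_len_s))

    # Noise is drawn through the same generator calls in the same order as
    # valence_ssm.simulate, one bin at a time.  The draw pattern per bin
    # does not depend on u, so open and closed runs with the same seed
    # consume identical randomness (common random numbers), and an open
    # run reproduces the plain model simulation exactly.
    rng = np.random.default_rng(seed)

    filt = OnlineMixedFilter(params)
    window_bins = 20 if controller is None else max(
        1, int(round(controller.smoothing_window_s / controller.bin_len_s)))

    x = np.empty(K)
    n = np.empty(K, dtype=np.int64)
    z = np.empty(K)
    u = np.zeros(K)
    x_filt = np.empty(K)
    v_filt = np.empty(K)
    xk = params.x0
    recent: list[float] = []
    for k in range(K):
        x[k] = xk
        n[k], z[k] = emit_observations(xk, params, rng)
        xf, vf = filt.step(int(n[k]), float(z[k]))
        x_filt[k] = xf
        v_filt[k] = vf
        recent.append(xf)
        if len(recent) > window_bins:
            recent.pop(0)
        if mode != "open":
            u[k] = fuzzy_control.control_step(recent, controller,
                                              t_s=k * model.bin_len_s)
        xk = step_state(xk, s[k], u[k], params, rng)
    return ScenarioResult(mode=mode, order=order, seed=seed, s=s, u=u,
                          x_true=x, n=n, z=z, x_filt=x_filt, v_filt=v_filt,
                          labels=labels, warmup_bins=warmup_bins,
                          bin_len_s=model.bin_len_s)


def calibrate_controller(open_result: ScenarioResult, mode: str,
                         u_max: float = fuzzy_control.DEFAULT_U_MAX,
                         smoothing_window_s: float =
                         fuzzy_control.DEFAULT_WINDOW_S,
                         warmup_s: float = DEFAULT_WARMUP_S,
                         settle_bins: int = 60,
                         ) -> fuzzy_control.FuzzyController:
    """Build a mode-specific controller from a subject's open-loop run.

    Membership functions are calibrated on the smoothed filtered state
    (the controller's actual input signal).  Warm-up bins and the first
    ``settle_bins`` bins after every label change are excluded: while the
    state travels between class levels the smoothed estimate straddles
    both classes, and including those bins would collapse the gap between
    the observed class ranges.
    """
    if open_result.mode != "open":
        raise ConfigError("calibration requires an open-loop result")
    window_bins = max(1, int(round(smoothing_window_s
                                   / open_result.bin_len_s)))
    v = _smoothed_history(open_result.x_filt, window_bins)
    labels = open_result.labels
    keep = np.arange(len(v)) >= open_result.warmup_bins
    changes = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    for c in changes:
        keep[c:c + settle_bins] = False
    input_mfs, universe = fuzzy_control.calibrate_mfs(
        v[keep], labels[keep])
    return fuzzy_control.make_controller(
        mode, input_mfs, universe, u_max=u_max,
        smoothing_window_s=smoothing_window_s, warmup_s=warmup_s,
        bin_len_s=open_result.bin_len_s)


def summarize_halves(result: ScenarioResult) -> dict[str, dict[str, float]]:
    """Spike count and mean estimated valence per labeled period,
    excluding warm-up bins."""
    out: dict[str, dict[str, float]] = {}
    keep = np.arange(len(result)) >= result.warmup_bins
    for label in np.unique(result.labels):
        m = keep & (result.labels == label)
        out[str(label)] = {
            "spike_count": float(np.sum(result.n[m])),
            "mean_valence": float(np.mean(result.x_filt[m])),
        }
    return out


def paired_ttest(open_vals, closed_vals) -> tuple[float, float]:
    """Two-tailed paired t-test; returns (mean difference, p).

    Degenerate zero-variance differences follow the convention: all-zero
    differences give p = 1 (no effect), a constant nonzero difference
    gives p = 0 (perfectly consistent effect).
    """
    d = np.asarray(closed_vals, dtype=float) - np.asarray(open_vals,
                                                          dtype=float)
    mean_diff = float(np.mean(d))
    if np.ptp(d) == 0.0:
        warnings.warn("zero-variance paired differences", RuntimeWarning)
        return mean_diff, 1.0 if mean_diff == 0.0 else 0.0
    t = stats.ttest_rel(np.asarray(closed_vals, float),
                        np.asarray(open_vals, float))
    return mean_diff, float(t.pvalue)


def evaluate_bank(results: dict[tuple[str, str], list[ScenarioResult]],
                  ) -> pd.DataFrame:
    """Paired open-vs-closed statistics for every cell of the design.

    ``results[(mode, order)]`` is the list of per-subject runs; modes
    "inhibitory"/"excitatory" are each compared against "open" of the
    same order, subject by subject (same seeds).
    """
    rows = []
    for order in sorted({o for (_, o) in results}):
        if ("open", order) not in results:
            raise ConfigError(f"missing open-loop results for order {order}")
        open_sums = [summarize_halves(r) for r in results[("open", order)]]
        for mode in ("inhibitory", "excitatory"):
            if (mode, order) not in results:
                continue
            closed_sums = [summarize_halves(r)
                           for r in results[(mode, order)]]
            if len(closed_sums) != len(open_sums):
                raise ConfigError("open and closed banks differ in size")
            for period in ("LV", "HV"):
                for metric in ("spike_count", "mean_valence"):
                    ov = [s[period][metric] for s in open_sums]
                    cv = [s[period][metric] for s in closed_sums]
                    diff, p = paired_ttest(ov, cv)
                    rows.append({"mode": mode, "order": order,
                                 "period": period, "metric": metric,
                                 "mean_diff": diff, "p_value": p})
    return pd.DataFrame(rows)


def _class_path(level: float, n_bins: int, rng: np.random.Generator,
                rise_bins: int = 60, fall_bins: int = 30,
                wander_frac: float = 0.15) -> np.ndarray:
    """Smooth latent path for one stimulus class: ramps from 0 to the
    class level, wanders around it, and returns to 0 at the end (so its
    first differences integrate to zero over the segment)."""
    k = np.arange(n_bins, dtype=float)

    def smoothstep(r):
        r = np.clip(r, 0.0, 1.0)
        return 3 * r ** 2 - 2 * r ** 3

    w = smoothstep(k / rise_bins) * smoothstep((n_bins - 1 - k) / fall_bins)
    wander = np.zeros(n_bins)
    for _ in range(3):
        period = rng.uniform(80, 300)
        phase = rng.uniform(0, 2 * np.pi)
        amp = wander_frac * abs(level) * rng.uniform(0.5, 1.0)
        wander += amp * np.sin(2 * np.pi * k / period + phase)
    return (level + wander) * w


def make_subject_bank(n_subjects: int, seed: int,
                      level: float = 2.0, half_bins: int = 600,
                      base: ValenceParams | None = None,
                      ) -> list[tuple[ValenceParams, stimuli.StimulusModel]]:
    """Generate virtual subjects with clearly separated HV/LV stimuli.

    Each subject gets jittered state-space parameters and a personal
    harmonic stimulus model fitted (via the stimulus pipeline) to smooth
    class paths targeting +-``level``.
    """
    if base is None:
        base = ValenceParams(alpha=0.3, beta=0.5, sigma_eps2=0.005,
                             sigma_omega2=0.01, gamma=-1.0, x0=0.0)
    rng = np.random.default_rng(seed)
    bank = []
    for _ in range(n_subjects):
        params = ValenceParams(
            alpha=base.alpha * (1 + 0.1 * rng.uniform(-1, 1)),
            beta=base.beta * (1 + 0.1 * rng.uniform(-1, 1)),
            sigma_eps2=base.sigma_eps2 * float(np.exp(0.1 * rng.normal())),
            sigma_omega2=base.sigma_omega2 * float(np.exp(0.1 * rng.normal())),
            gamma=base.gamma + 0.1 * rng.normal(),
            x0=0.0)
        hv = stimuli.fit_harmonics(
            stimuli.derive_stimuli(_class_path(level, half_bins, rng)))
        lv = stimuli.fit_harmonics(
            stimuli.derive_stimuli(_class_path(-level, half_bins, rng)))
        bank.append((params, stimuli.StimulusModel(harmonics_hv=hv,
                                                   harmonics_lv=lv)))
    return bank


def run_bank(n_subjects: int = 10, seed: int = 0,
             duration_s: float = DEFAULT_DURATION_S,
             orders: tuple[str, ...] = ("lvhv", "hvlv"),
             modes: tuple[str, ...] = ("inhibitory", "excitatory"),
             u_max: float = fuzzy_control.DEFAULT_U_MAX,
             max_attempts_factor: int = 4,
             ) -> tuple[dict[tuple[str, str], list[ScenarioResult]],
                        pd.DataFrame]:
    """Run the full scenario grid over a subject bank and evaluate it.

    Candidate subjects whose open-loop run shows no usable LV/HV contrast
    (membership-function calibration fails in any order) are excluded and
    replaced — the analog of dropping participants with a lack of
    emotional response — until ``n_subjects`` valid subjects are analysed.
    """
    max_candidates = max_attempts_factor * n_subjects
    bank = make_subject_bank(max_candidates, seed)
    seeds = np.random.SeedSequence(seed).generate_state(max_candidates)
    seeds = [int(s % (2 ** 31)) for s in seeds]

    accepted: list[dict] = []
    for (params, model), sseed in zip(bank, seeds):
        entry = {"params": params, "model": model, "seed": sseed,
                 "open": {}, "ctrl": {}}
        try:
            for order in orders:
                open_res = run_scenario(params, model, "open", order,
                                        sseed, duration_s=duration_s)
                entry["open"][order] = open_res
                for mode in modes:
                    entry["ctrl"][(mode, order)] = calibrate_controller(
                        open_res, mode, u_max=u_max)
        except CalibrationError:
            continue
        accepted.append(entry)
        if len(accepted) == n_subjects:
            break
    if len(accepted) < n_subjects:
        raise CalibrationError(
            f"only {len(accepted)} of {max_candidates} candidate subjects "
            f"had usable LV/HV contrast")

    results: dict[tuple[str, str], list[ScenarioResult]] = {}
    for order in orders:
        results[("open", order)] = [e["open"][order] for e in accepted]
        for mode in modes:
            results[(mode, order)] = [
                run_scenario(e["params"], e["model"], mode, order,
                             e["seed"], duration_s=duration_s,
                             controller=e["ctrl"][(mode, order)])
                for e in accepted]
    return results, evaluate_bank(results)
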