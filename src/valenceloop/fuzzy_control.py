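"""Mamdani fuzzy controller for inhibitory / excitatory valence regulation.

The controller input is the online-filtered valence estimate, averaged over
a 10-s window; the output is the control effort u_k added to the state
equation.  Inference is classic Mamdani: fuzzify the input against
LowValence / HighValence membership functions, clip (min) each rule's
output membership at the rule's firing degree, aggregate rules by pointwise
max, and defuzzify by the centroid of the aggregate.  Rule bases:

    inhibitory:  LowValence -> Neutral,     HighValence -> Inhibition
    excitatory:  LowValence -> Excitation,  HighValence -> Neutral

so the controller only ever pushes the state toward the targeted class and
is quiescent (Neutral is centred on zero) otherwise.  During the first
minute of a session the controller is suspended so the mixed filter can
converge.

Input membership functions are calibrated per subject from an open-loop
run rather than hand-tuned: the LowValence support covers the observed
LV-period range and HighValence only begins above the largest smoothed
state seen during LV periods, so no inhibitory action can fire while the
subject sits in its own baseline LV regime (and mirrored for excitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ConfigError

__all__ = [
    "MembershipFunction",
    "FuzzyController",
    "smooth_input",
    "fuzzify",
    "infer",
    "defuzzify_centroid",
    "control_step",
    "calibrate_mfs",
    "make_controller",
]

OUTPUT_GRID_POINTS = 20001
DEFAULT_U_MAX = 0.1       # control authority, state-units per 0.5-s step
DEFAULT_WINDOW_S = 10.0   # input smoothing window
DEFAULT_WARMUP_S = 60.0   # controller suspension at session start


@dataclass
class MembershipFunction:
    """Triangle (3 breakpoints) or trapezoid (4 breakpoints) on a universe.

    Degenerate (repeated) breakpoints express one-sided saturation, e.g.
    ``(a, a, b, c)`` is a left-saturated trapezoid.
    """

    shape: str
    breakpoints: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        bp = tuple(float(b) for b in self.breakpoints)
        if self.shape == "triangle" and len(bp) != 3:
            raise ValueError("triangle needs 3 breakpoints")
        if self.shape == "trapezoid" and len(bp) != 4:
            raise ValueError("trapezoid needs 4 breakpoints")
        if self.shape not in ("triangle", "trapezoid"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if any(b2 < b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be ascending")
        self.breakpoints = bp

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        if self.shape == "triangle":
            a, b, c = self.breakpoints
            left = _ramp_up(v, a, b)
            right = _ramp_down(v, b, c)
        else:
            a, b, c, d = self.breakpoints
            left = _ramp_up(v, a, b)
            right = _ramp_down(v, c, d)
        out = np.minimum(left, right)
        return float(out) if out.ndim == 0 else out


def _ramp_up(v, a, b):
    if b == a:
        return np.where(v >= b, 1.0, 0.0)
    return np.clip((v - a) / (b - a), 0.0, 1.0)


def _ramp_down(v, c, d):
    if d == c:
        return np.where(v <= c, 1.0, 0.0)
    return np.clip((d - v) / (d - c), 0.0, 1.0)


@dataclass
class FuzzyController:
    mode: str  # "inhibitory" | "excitatory"
    input_mfs: dict[str, MembershipFunction]
    output_mfs: dict[str, MembershipFunction]
    rules: list[tuple[str, str]]
    u_max: float = DEFAULT_U_MAX
    universe_in: tuple[float, float] = (-1.0, 1.0)
    smoothing_window_s: float = DEFAULT_WINDOW_S
    warmup_s: float = DEFAULT_WARMUP_S
    bin_len_s: float = 0.5
    out_grid: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("inhibitory", "excitatory"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.u_max <= 0:
            raise ConfigError("u_max must be > 0")
        for in_label, out_label in self.rules:
            if in_label not in self.input_mfs:
                raise ConfigError(f"rule references unknown input "
                                  f"label {in_label!r}")
            if out_label not in self.output_mfs:
                raise ConfigError(f"rule references unknown output "
                                  f"label {out_label!r}")
        if self.out_grid is None:
            self.out_grid = np.linspace(-self.u_max, self.u_max,
                                        OUTPUT_GRID_POINTS)


def default_output_mfs(u_max: float) -> dict[str, MembershipFunction]:
    """Neutral centred on zero; Inhibition/Excitation saturate at +-u_max."""
    return {
        "Neutral": MembershipFunction(
            "triangle", (-0.2 * u_max, 0.0, 0.2 * u_max), "Neutral"),
        "Inhibition": MembershipFunction(
            "trapezoid", (-u_max, -u_max, -0.6 * u_max, 0.0), "Inhibition"),
        "Excitation": MembershipFunction(
            "trapezoid", (0.0, 0.6 * u_max, u_max, u_max), "Excitation"),
    }


RULE_BASE = {
    "inhibitory": [("LowValence", "Neutral"), ("HighValence", "Inhibition")],
    "excitatory": [("LowValence", "Excitation"), ("HighValence", "Neutral")],
}


def make_controller(mode: str,
                    input_mfs: dict[str, MembershipFunction],
                    universe_in: tuple[float, float],
                    u_max: float = DEFAULT_U_MAX,
                    smoothing_window_s: float = DEFAULT_WINDOW_S,
                    warmup_s: float = DEFAULT_WARMUP_S,
                    bin_len_s: float = 0.5) -> FuzzyController:
    return FuzzyController(
        mode=mode, input_mfs=input_mfs,
        output_mfs=default_output_mfs(u_max),
        rules=RULE_BASE[mode], u_max=u_max, universe_in=universe_in,
        smoothing_window_s=smoothing_window_s, warmup_s=warmup_s,
        bin_len_s=bin_len_s)


def smooth_input(x_filt_history, window_bins: int = 20) -> float:
    """Mean of the most recent ``window_bins`` filtered-state samples
    (or of everything available when the history is shorter)."""
    h = np.asarray(x_filt_history, dtype=float)
    if h.size == 0:
        raise ValueError("history must contain at least one sample")
    return float(h[-window_bins:].mean())


def fuzzify(v: float, input_mfs: dict[str, MembershipFunction],
            universe_in: tuple[float, float] | None = None,
            ) -> dict[str, float]:
    """Degrees of membership of the (clamped) input value."""
    if universe_in is not None:
        v = min(max(v, universe_in[0]), universe_in[1])
    return {label: float(mf(v)) for label, mf in input_mfs.items()}


def infer(degrees: dict[str, float],
          controller: FuzzyController) -> np.ndarray:
    """Mamdani max-min aggregation on the output grid.

    Each rule's output MF is clipped (min) at the firing degree of its
    input label; rules aggregate by pointwise max.
    """
    grid = controller.out_grid
    agg = np.zeros_like(grid)
    for in_label, out_label in controller.rules:
        d = degrees.get(in_label, 0.0)
        if d <= 0.0:
            continue
        mu = controller.output_mfs[out_label](grid)
        np.maximum(agg, np.minimum(mu, d), out=agg)
    return agg


def defuzzify_centroid(grid: np.ndarray, mu: np.ndarray) -> float:
    """Centroid of the aggregated output MF by trapezoidal quadrature;
    a zero-area aggregate (no active rule) maps to zero action."""
    area = np.trapezoid(mu, grid)
    if area <= 0.0:
        return 0.0
    return float(np.trapezoid(mu * grid, grid) / area)


def control_step(x_filt_history, controller: FuzzyController,
                 t_s: float) -> float:
    """Full control computation for one bin at session time ``t_s``.

    Returns 0 during warm-up; otherwise smooth -> fuzzify -> infer ->
    defuzzify, with the mode's sign constraint enforced (an inhibitory
    controller never excites and vice versa).
    """
    if t_s < controller.warmup_s:
        return 0.0
    window_bins = max(1, int(round(controller.smoothing_window_s
                                   / controller.bin_len_s)))
    v = smooth_input(x_filt_history, window_bins)
    degrees = fuzzify(v, controller.input_mfs, controller.universe_in)
    agg = infer(degrees, controller)
    u = defuzzify_centroid(controller.out_grid, agg)
    if abs(u) < 1e-9 * controller.u_max:
        u = 0.0  # quadrature round-off on a symmetric aggregate
    if controller.mode == "inhibitory":
        return min(u, 0.0)
    return max(u, 0.0)


def calibrate_mfs(open_loop_state, labels,
                  margin_frac: float = 0.05,
                  ) -> tuple[dict[str, MembershipFunction],
                             tuple[float, float]]:
    """Data-driven input membership functions from an open-loop run.

    ``open_loop_state`` is the smoothed filtered state of an open-loop
    session (warm-up excluded) and ``labels`` the per-bin "HV"/"LV" tags.
    The universe is the [q01, q99] state range.  LowValence plateaus over
    the LV-period range; HighValence plateaus over the HV-period range.
    Their sloped edges are both placed inside the gap between the largest
    state observed during LV periods and the smallest observed during HV
    periods, with the HighValence onset below the LowValence cutoff.  Two
    consequences: the controller is exactly silent while the subject sits
    inside its own observed baseline-class range (no rule that moves the
    state can fire there), and the two supports overlap so the centroid
    output is a continuous function of the input.

    Raises :class:`CalibrationError` when the class medians are not
    separated in the expected direction (no usable emotional contrast).
    """
    x = np.asarray(open_loop_state, dtype=float)
    labels = np.asarray(labels)
    lv = x[labels == "LV"]
    hv = x[labels == "HV"]
    if lv.size == 0 or hv.size == 0:
        raise CalibrationError("need both LV and HV periods to calibrate")
    lv_med, hv_med = float(np.median(lv)), float(np.median(hv))
    sep = hv_med - lv_med
    if sep <= 0:
        raise CalibrationError(
            "LV median >= HV median: no emotional contrast between "
            "periods; consider excluding this subject")
    eps = margin_frac * sep
    lo = float(min(np.quantile(x, 0.01), lv_med))
    hi = float(max(np.quantile(x, 0.99), hv_med))

    lv_max, hv_min = float(lv.max()), float(hv.min())
    gap = hv_min - lv_max
    if gap > 2 * eps:
        # clean separation: thirds of the gap
        hv_onset = lv_max + gap / 3.0
        lv_cutoff = hv_min - gap / 3.0
    else:
        # overlapping classes: small symmetric overlap at the midpoint
        mid = 0.5 * (lv_max + hv_min)
        hv_onset = mid - eps
        lv_cutoff = mid + eps
    lv_cutoff = max(lv_cutoff, lv_med + eps)
    hv_onset = min(hv_onset, hv_med - eps)
    hv_onset = max(hv_onset, lv_med + 0.5 * eps)
    if hv_onset >= lv_cutoff:
        hv_onset = lv_cutoff - 0.5 * eps
    hv_plateau = max(hv_med, hv_onset + eps)

    input_mfs = {
        "LowValence": MembershipFunction(
            "trapezoid", (lo - eps, lo - eps, lv_med, lv_cutoff),
            "LowValence"),
        "HighValence": MembershipFunction(
            "trapezoid", (hv_onset, hv_plateau, hi + eps, hi + eps),
            "HighValence"),
    }
    return input_mfs, (lo, hi)
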