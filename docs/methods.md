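# Methods

This note documents the model, the numerical choices, and the design
decisions behind `valenceloop`, together with what the synthetic studies
do and do not demonstrate.

## State-space model

The latent valence state is scalar and evolves at the feature rate (one
step per 0.5-s bin, 2 Hz):

    x_{k+1} = x_k + ε_k + s_k + u_k,     ε_k ~ N(0, σ_ε²)

with environmental stimulus `s_k` and control effort `u_k` (both zero
during estimation from passive recordings).  Two simultaneous observation
channels are tied to the state:

    P(n_k = 1 | x_k) = σ(γ + x_k)            (binary spike channel)
    z_k = α + βx_k + ω_k,  ω_k ~ N(0, σ_ω²)  (continuous bandpower channel)

Assumptions: a single scalar state, Gaussian process noise, a static link
offset γ, and linearity of the continuous channel.  Using both channels
jointly narrows the posterior relative to either alone.

**Identifiability.** The likelihood is exactly invariant under
`x → x − δ, α → α + βδ, γ → γ + δ`: the *level* of the state is not
identifiable from (n, z) data.  The package pins it by fixing γ at the
logit of the empirical spike rate (anchoring p = mean(n) at x = 0) and
never updating it.  Consequences: shape and scale of the trajectory and
the parameters β, σ_ε², σ_ω² are well determined, while α and the
trajectory level carry a common residual shift whose size depends on how
tightly the data pin the mean state.  This is a property of the model
class, not of the optimizer.

## EMG front end

* Band-pass 10–250 Hz, 3rd-order Butterworth, applied forward–backward
  (zero-phase) so the envelope is not phase-distorted; the effective
  attenuation in dB doubles.
* Notches at 50/100/150/200/250 Hz, 2nd-order IIR, quality factor 30,
  also zero-phase.  A Q=30 notch run twice is ≈3 dB down out to about
  2.3·f₀/2Q from the center, so passband flatness is only claimed outside
  ±8 Hz of each notch.
* Bins are non-overlapping 0.5 s; a trailing partial bin is dropped.
* Binary channel: the rectified filtered signal is smoothed with a
  Gaussian kernel (σ = 25 ms, configurable), divided by its global
  maximum, and averaged per bin, giving a per-bin amplitude y_k ∈ [0, 1];
  the spike probability is q_k = min(a·y_k, 1) with a = 0.5.  The global
  max-normalisation is our construction: the amplitude-to-probability map
  needs a scale to produce a valid probability, and the recording maximum
  is the least informative choice.
* Continuous channel: per-bin Welch PSD (Hann windows of half a bin,
  75% overlap, ≥ 4 averaged segments), integrated over 10–250 Hz, natural
  log, then min–max normalised over the recording.  A degenerate
  recording (zero dynamic range) maps to 0.5 everywhere; zero bandpower
  is floored before the log and logged as a warning.

## Mixed filter and smoother

Prediction is the Chapman–Kolmogorov step of the random walk
(`x_pred = x_filt`, `v_pred = v_filt + σ_ε²`).  The update solves

    x = x_pred + C[β(z − α − βx_pred) + σ_ω²(n − σ(γ + x))],
    C = v_pred / (β²v_pred + σ_ω²)

whose solution is exactly the mode of the one-step posterior.  The scalar
equation is monotone, so the root is unique; Newton iteration starts at
`x_pred` (tolerance 1e-10, ≤ 50 iterations) inside the bracket implied by
σ ∈ (0, 1), falling back to bisection whenever a Newton step leaves the
bracket.  The posterior variance is the information form
`[1/v_pred + p(1−p) + β²/σ_ω²]⁻¹` at the solution.

The initial predicted variance v₀ defaults to σ_ε² (configurable).  The
backward pass is the standard fixed-interval smoother; the lag-one
smoothed covariance is `cov(x_{k−1}, x_k | all) = A_{k−1} v_sm[k]` with
`A_k = v_filt[k]/v_pred[k+1]`, and its k = 0 boundary (the x₀/x₁ pair)
uses the prior gain `v₀/v_pred[0]`, which is 1 under the default v₀.
With the binary channel disabled the recursions reduce exactly to the
scalar Kalman filter / RTS smoother; the test suite verifies elementwise
agreement to 1e-10 against an independently written reference.

The sequential recursions are JIT-compiled (numba); filtering and
smoothing 4800 bins costs well under a millisecond after compilation,
which is what makes the EM studies below cheap.

## EM estimation

E-step: filter + smoother + second moments `W_k = v_sm + x_sm²` and
`W_{k−1,k} = cov_cross + x_sm[k−1]·x_sm[k]`.  M-step closed forms: x₀ is
the first smoothed value; (α, β) solve the 2×2 normal equations in
(1, x_sm) weighted by W; σ_ω² is the residual second moment under the new
(α, β); σ_ε² = K⁻¹Σ[W_k − 2W_{k−1,k} + W_{k−1}] with the k = 1 boundary
using W₀ = σ_ε² + x₀².  Variances are floored at 1e-8 and a near-singular
normal system (constant smoothed state) receives a 1e-8 ridge with a
warning.  Convergence is the maximum relative parameter change over
θ = [α, β, σ_ε², σ_ω²] dropping below 1e-6 (scale-free, standard EM
practice), capped at 500 iterations; hitting the cap only flags
`converged=False` — along the weakly identified level/α direction EM
creeps for hundreds of iterations while the fit is already stable.
In the Gaussian sub-model (binary channel disabled) each iteration
provably does not decrease the observed-data likelihood, and the test
suite checks this on the prediction-error decomposition.

**Recovery study conditions.**  The parameter-recovery experiment uses
α = 0.3, β = 0.5, σ_ε² = 0.005, σ_ω² = 0.01, γ = −1, x₀ = 0 and
K = 4800 bins generated as **40 independent one-minute trials** (120 bins
each, state restarting at x₀), mirroring a session of forty separate
one-minute video trials; the EM fits the concatenation as one sequence.
A single continuous 4800-step random walk would be an alternative, but
its path mean has standard deviation ≈ 2.8, which makes α arbitrarily
biased through the level degeneracy; per-trial restarts pin the mean
state near x₀ so that α is recoverable to ~10%.  The price is model
mismatch at the 39 trial boundaries, which (a) inflates σ̂_ε² modestly
and (b) costs a few percentage points of confidence-band coverage even
when smoothing with the true parameters.  Together with the residual
level shift, the pooled 95% band coverage over the recovery runs is
measured at ≈ 0.80 rather than nominal 0.95; the shape of the band is
correct (matched-model coverage on a continuous run is 0.946).  Scripts
and tests report this number as measured.

## Environmental-stimulus model

Stimuli are first differences of the estimated state.  Representative
trials per class are the six with the highest (HV) / lowest (LV) combined
rank of mean and standard deviation of the estimated state (average
ranks, ties broken by trial id).  The class summary is a 100-term
sinusoidal model Σ ρ_j sin(ζ_j k + φ_j), estimated by taking the 100
largest-magnitude DFT bins (excluding the zero-frequency term) — the same
functional form as a nonlinear sinusoid fit but deterministic,
reproducible and free of local minima.  Schedules replay each class model
from its own time origin (k restarts per segment) and bridge boundaries
with a linear blend over one 0.5-s bin.

Because the zero-frequency bin is excluded, a class model can only
sustain a nonzero state level if the source path's differences integrate
to zero over the fitted window.  The virtual-subject bank therefore
builds class paths that rise from 0 to the class level, wander around it,
and return to 0 at the end of the window, so the band-limited
reconstruction preserves the excursion exactly.

## Fuzzy controller

Mamdani inference: the smoothed filtered state (10-s causal moving
average) is fuzzified against LowValence/HighValence trapezoids; each
rule clips (min) its output membership at the firing degree; rules
aggregate by pointwise max; the crisp effort is the centroid of the
aggregate by trapezoidal quadrature on a 20 001-point grid over
[−u_max, u_max].  At that resolution the centroid is within ~1e-9·u_max
of a 10⁶-point quadrature (a 2001-point grid was a factor ~6 short of
the 1e-6·u_max accuracy target, so the grid is denser; the per-step cost
is still ~100 µs).  A zero-area aggregate maps to zero effort, quadrature
round-off below 1e-9·u_max is truncated to exactly zero, and the mode's
sign (inhibitory ≤ 0, excitatory ≥ 0) is enforced as a final guard.

Output memberships: Neutral = triangle (−0.2u_max, 0, 0.2u_max),
Inhibition = trapezoid saturating at −u_max with support ending at 0,
Excitation mirrored.  u_max defaults to 0.1 state-units per 0.5-s step —
enough authority to traverse the typical class separation within a couple
of minutes without overwhelming the dynamics.

**Input calibration.**  Input memberships are calibrated per subject from
an open-loop run, using the controller's actual input signal (the
smoothed filtered state), excluding the 1-min warm-up and the first 30 s
after every class change (while the state travels between levels the
smoothed estimate straddles both classes and would collapse the gap).
LowValence plateaus up to the LV-period median; HighValence plateaus from
the HV-period median.  Their sloped edges are both placed inside the gap
between the observed LV maximum and HV minimum, HighValence onset below
LowValence cutoff.  This placement has two consequences that a naive
median-to-median crossover does not deliver:

* **Exact non-interference** — no state-moving rule can fire while the
  subject sits inside its own observed baseline-class range, so an
  inhibitory controller is *identically* zero during an initial LV period
  (the closed-loop trajectory is bit-identical to the open-loop one).
* **Continuity** — the supports overlap, so at the point where a
  corrective rule starts firing the Neutral rule is still active and the
  centroid moves continuously from zero (max–min–centroid inference is
  otherwise discontinuous at rule-activation boundaries).

If the class medians are not separated in the right direction the
calibration raises an error, the analog of excluding a participant with
no emotional contrast.

## Closed-loop studies

Sessions are 10 min (1200 bins), half per class in either order, with the
controller suspended for the first minute and warm-up bins excluded from
all summaries (the online filter is still converging there).  Per bin the
loop emits (n, z) from the true state, updates the online filter,
computes the control effort from the smoothed estimate, and steps the
state.  Noise is drawn through the same generator calls in the same order
regardless of the control signal, so open and closed runs with the same
seed share randomness and differences are attributable to control alone.

The subject bank jitters the base parameters by ~10% per subject and fits
personal harmonic models to class paths targeting ±2 state-units.
Candidates whose open-loop run yields no usable LV/HV contrast (the
process-noise random walk can drift enough to invert the halves) are
excluded and replaced, as a study would exclude non-responsive
participants.  Evaluation uses two-tailed *paired* t-tests across
subjects (open vs closed share subjects and seeds) on per-period spike
counts and mean *estimated* valence (the controller's and plots' signal;
the true state is exported for diagnostics).  Zero-variance differences
follow the convention p = 1 for all-zero (no effect) and p = 0 for a
constant nonzero shift.

## Synthetic zEMG generator

Emulates: 1-min labeled HV/LV trials at 512 Hz; band-limited (20–240 Hz)
Gaussian carrier noise whose envelope follows exp(latent/2) of a
bin-rate latent path (class target ±1 plus random-walk wander, σ = 0.05
per bin, linearly upsampled); 50 Hz line interference at 10% of carrier
RMS plus weak 100/150 Hz harmonics.  It does **not** emulate motor-unit
physiology, movement artifacts, electrode drift, heteroscedastic or
non-Gaussian noise, or inter-channel effects — so green front-end tests
demonstrate correct signal processing and monotone envelope-to-feature
transfer, not robustness to real-world artifacts.

## Problem sizes and runtimes

Defaults used by the test suite and the reproduction script: 20 seeds ×
4800 bins for EM recovery (~10 s total), 10 virtual subjects × 2 orders ×
3 scenarios × 1200 bins for the closed-loop study (~12 s), 50 × 200-bin
sequences for the Kalman/RTS check, 100 randomized one-step updates
against grid search, 100 random aggregates against 10⁶-point quadrature,
and 20 synthetic recordings of six 1-min trials for the front-end
contrast.  All sequential kernels are numba-compiled; the first call in a
fresh process pays a few seconds of compilation.

## Known limitations

* The state level / α / γ degeneracy discussed above; only differences
  and dynamics of the valence state should be interpreted.
* The smoother's confidence bands condition on point estimates of θ and γ
  and do not account for the trial-restart mismatch, so pooled coverage
  on trialized sessions is below nominal (~0.80 measured).
* The controller is mono-objective: after regulating its target class it
  keeps acting through the other half of a session rather than tracking a
  reference.
* Harmonic stimulus models are band-limited and class-wide; per-trial
  stimulus structure is averaged away.
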