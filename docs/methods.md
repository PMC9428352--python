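# Methods

This note documents the models, parameters, and numerical choices behind
`smrsim`, and what its synthetic experiments do and do not show about
real EEG BCI sessions.

## The simulated system

The simulator replaces a human SMR-BCI user with a generative model:
intention input drives source-level mu-rhythm amplitude, which is
projected to the scalp and decoded by exactly the online pipeline a live
system would run. Because encoding and decoding are both explicit, any
effect of a decoder or task parameter on performance can be attributed
to the parameter itself rather than to subject variability — which is
the point of closed-loop simulation.

### Intention scaling

Raw device velocity is scaled by `input_gain` (default 0.005 per
device-unit/s; scripted controllers emit a few hundred device units/s,
so sustained intention saturates at the unit-norm bound). Vectors whose
scaled norm exceeds 1 are renormalized to unit length, preserving
direction; the bound itself is part of the encoding contract.

### Encoding sigmoids

`A[h,a] = 1/(1 + exp(α[h,a]·(v'_a + k[h,a])))`, strictly inside (0, 1).
The sign pattern is fixed: the horizontal gains are mirrored
(`α[left,x] = +8`, `α[right,x] = −8`), the vertical gains share sign
(`+8`), so rightward intention desynchronizes the left hemisphere and
upward intention desynchronizes both. Defaults (|α| = 8; classic offsets
`∓0.5`, centered offsets 0) are a manual calibration chosen so that

* classic: `A(0) = 0.982 ≈ 1` (no attenuation at rest) and
  `A ≈ 0.018` at full contralateral intention;
* centered: `A(0) = 0.5` exactly, reproducing the 0.5 factor differences
  at full lateral intention.

1D configurations keep one pair only; the pair's axis is `x`
(lateralized control) or `y` (bilateral control, shared-sign gains).

### Source signals

Task carriers are uniform white noise, bandpass-filtered 5–12 Hz by a
Kaiser-window FIR designed from the Kaiser empirical order formula
(60 dB stopband, 2 Hz transitions at 3–5 and 12–14 Hz; ~455 taps at
250 Hz). Because the default 1 s epoch is shorter than the filter, the
generator filters an extended noise segment and keeps the steady-state
tail; a strict mode (`pad_steady_state=False`) instead requires
`epoch_len ≥ numtaps + 1` and raises otherwise. Each epoch is shaped by
a Tukey window (width 0.95 of the epoch, cosine fraction 0.8), then
peak-normalized; per frame the unit carrier is scaled by
`A[h,a] × 100 µV`, and the two axis carriers of a hemisphere are summed
on that hemisphere's hand-knob ROI vertices. Background activity is 500
independent Brownian walks (cumulative white noise, mean-removed and
peak-normalized to 50 µV per epoch; the walks persist across epochs).
The 100/50 µV ratio is the source-level SNR = 2 operating point.

A consequence worth stating: scalp alpha **power** scales with the
**square** of the amplitude factor, and the two axis carriers add in
power. Reasoning about the encoding that is linear in `A` (e.g. "the
centered configuration cancels the vertical component exactly") holds
only approximately: with centered defaults, a pure rightward intention
retains a predictable downward power component (ΔC_y/ΔC_x = −0.5 before
buffer adaptation, ~25–30° of deviation), which is still far smaller
than the classic configuration's ~60–70° up-right bias. The
classic-vs-centered orderings (angle deviation, trajectory length) are
robust under this physics; the pooled cursor-position covariance is not
(see Limitations).

### Forward model

The built-in head model is a three-shell concentric sphere
(brain/skull/scalp radii 0.087/0.092/0.100 m, conductivities
0.33/0.33÷80/0.33 S/m). The dipole potential is expanded in Legendre
series (60 terms; radii scaled by the outer radius for conditioning);
per degree, the layered boundary-value problem is solved by 2×2
transfer-matrix propagation with an insulating outer boundary. The
implementation is validated in the tests against a brute-force
surface-charge (BEM collocation) oracle on the homogeneous sphere
(<1% relative error) and by symmetry/rotation/superposition properties.
Sources sit on a 0.078 m Fibonacci-lattice shell (default 2000 vertices,
radial orientations); hand-knob ROIs are 10° caps at the projections of
C3/C4 (plus caps rotated 10° anterior), ~25 vertices per hemisphere.
Externally computed lead fields (BEM/FEM toolbox exports) can be loaded
from the npz container or a text matrix + JSON sidecar.

Gain columns are normalized so each vertex's best-coupled channel
responds with unit gain ("µV-equivalent" calibration): a 100 µV source
amplitude produces a 100 µV peak at its nearest channel. This makes the
source-level SNR statement operational at the scalp for task and
background sources alike.

### Online decoder

Causal streaming chain with persistent state: IIR notch at 60 Hz
(58–62 Hz bandwidth) then a 251-tap FIR bandpass 2–60 Hz; small
Laplacian (C3 − mean(F3, T7, Cz, P3), mirrored for C4); Burg AR(16)
spectral estimation over the most recent 1.0 s window, alpha power
integrated on a 17-point 8–12 Hz grid; `C_x = P4 − P3`,
`C_y = −P4 − P3`; per-axis Z-score against a rolling history of
`BW × update_rate` values (sample standard deviation, history excludes
the current value, σ = 0 yields 0); `v = S·C'` capped at `CV`; position
integrated per frame (velocity in px/s × frame duration) and clamped to
the 1000×1000 px screen.

Two defaults are this package's own calibrations, both configurable:

* `psd_window_s = 1.0`. With the simulator's 7 Hz-wide alpha carrier,
  0.5 s Burg windows give band-power estimates so variable and
  right-skewed that downward (power-increase) control essentially never
  succeeds and the speed cap rectifies the skew into a systematic drift;
  1.0 s windows yield balanced four-direction control. Real mu rhythms
  are narrower-band, where shorter windows are workable.
* `velocity_gain = 600 px/s` per normalized-control unit. Calibrated so
  that sustained full intention reaches targets within the 6 s window at
  the default SNR; the `CV` cap is then the operative speed limit, which
  matches the observation that `CV` dominates task performance.

The first trial of each buffer-reset run is the calibration trial: it
runs normally but the Z-score uses the partially filled buffer (0 until
two values exist). The buffer is deliberately not pre-filled — the short
calibration is reproduced as-is, including its known dilution of the
`BW` effect. At run boundaries, `NT = 0` resets the buffer (next run
recalibrates); `NT > 0` preserves it; the default sweep orders the NT
block [24, 48] so the NT = 48 run's history genuinely spans two runs,
while the BW and CV blocks are order-randomized within type.

### Task engine

Trials: 3 s rest, 2 s preparation, up to 6 s feedback; outcomes
hit/miss/timeout; targets are bars of thickness 0.0625 normalized units
at the workspace edge (closed boundaries, cursor center point). Frame
cadence is 30 updates/s against 250 Hz EEG (8/8/9-sample frames; phase
durations are exact multiples). Rest and preparation still generate and
record EEG at the resting modulation; decoding is gated to feedback.
Runs hold 24 trials, block-randomized in one-of-each-direction blocks.
Sessions are pure functions of (spec, seed): the seed fans out to the
target shuffler, the source generator, and the controller noise.

Scripted controllers: proportional-to-target, constant-direction (with
an aim-at-target mode for straight-line calibration reaches), and
noisy-proportional (Gaussian directional noise in radians).

### Perturbed-configuration fitting

From recorded sessions, feedback epochs of hit trials are taken, the
continuous recording is preprocessed once with the decoder's own filter
chain (so no per-epoch filter warm-up), the first 0.5 s of each epoch is
dropped (feedback-onset transition), and alpha power at Laplacian C3/C4
is averaged over fixed decoder-length (1 s) Burg windows — the same
estimator the online decoder uses. Powers are averaged per direction,
with the axis-pooled LR/UD baselines weighting the two directions
equally so unbalanced hit counts cannot skew them. Each (hemisphere,
axis) triplet — e.g. (µ_L, µ_UD, µ_R) at v' = (−1, 0, +1) — is
normalized by its maximum and fitted by iterative least squares
(`curve_fit`) to the sigmoid; |α| < 0.5 flags a degenerate (flat) fit.
The vertical assignment follows the task-space convention: upward
intention desynchronizes, so the up-trial mean maps to v'_y = +1.

The recommended calibration protocol is the 1D pair (a 1D-LR and a
1D-UD session): with one-axis generation the off-axis carrier is absent
and the normalized triplets are sigmoid-consistent (measured residuals
< 0.01 at 32 trials/session). A single 2D session also works mechanically,
but its axis-pooled baselines carry the other axis's trial-average power
(quadratic mixing), which makes the triplets near-collinear and leaves
sigmoid residuals around 0.08 regardless of trial count — a structural
property of power-domain encoding, documented here rather than hidden.

## Metrics and statistics

PTC, decision time (timeouts as 6 s) and integrated distance include
all trials. Integrated distance is the per-trial mean distance during
feedback, averaged over trials. Angle deviation is the absolute angle
in [0°, 180°] between ground-truth scaled intention and decoded
velocity; zero-norm samples are excluded and an all-zero trial reports
a missing angle, not 0. Run-level position covariance pools per-frame
positions across the run's feedback phases (sample covariance).
Parameter trends use OLS with a two-sided slope t-test and 95% CI
(statsmodels); condition contrasts use paired t-tests with zero-variance
differences flagged explicitly.

## Problem sizes used by the test suite

Chosen as desk-scale instantiations of the protocols: the
classic-vs-centered comparison runs 3 simulated subjects × 3 runs × 8
2D trials per encoding (paired by seed); the CV sweep runs 16 seeds ×
4 CV values × 4-trial 1D runs with the noisy-proportional controller
(σ = 0.3 rad); perturbed recovery uses 32-trial 1D sessions; the
sweep-structure check runs the full 10 × 24-trial default session twice
and compares bit-for-bit.

## Limitations

* The generated EEG is a two-component caricature (modulated alpha
  carriers + Brownian background): no beta band, no 1/f aperiodic
  mixture at task sites, no eye-blink/EMG artifacts, no inter-trial
  non-stationarity. Passing tests show the closed-loop machinery and
  parameter effects behave as designed, not that conclusions transfer
  quantitatively to human EEG.
* Left-right symmetry of the encoding means the pooled cursor-position
  covariance is zero-mean under both classic and centered
  configurations; the covariance contrast reported for human subjects is
  not a forced effect of the encoding model and is correspondingly
  unstable in simulation (the angle and length contrasts are robust).
* Power-domain quadratic mixing (see above) limits the fidelity of
  linear-in-A reasoning about the centered configuration and of the
  2D-session perturbed-fitting route.
* The spherical head model is a geometric idealization; realistic
  anatomy enters only through loaded lead fields. Dipole orientations in
  the built-in model are radial.
* Session recordings use a native npz + JSON + CSV container; no EDF
  export is provided.
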