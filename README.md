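# smrsim — a closed-loop sensorimotor-rhythm EEG BCI simulator

`smrsim` simulates sensorimotor-rhythm (SMR) brain-computer interface
experiments end to end, in a closed loop, without a subject or an EEG
amplifier. It is aimed at BCI researchers who want to prototype decoder
and task parameters (normalization windows, cursor-speed limits,
calibration schedules) for continuous cursor-control paradigms before —
or instead of — running live sessions.

## How it works

Each display frame closes the loop:

1. **Intention input.** A scripted controller (or pointing device)
   produces a raw velocity `v`, scaled to `v' = S_in·v` with `|v'| ≤ 1`.
2. **Encoding.** Four sigmoids, one per (hemisphere *h*, control axis
   *a*), map intention to amplitude-modulation factors

   ```
   A[h,a] = 1 / (1 + exp(α[h,a]·(v'_a + k[h,a])))
   ```

   `A ≈ 1` is a full resting mu rhythm; `A ≈ 0` is complete
   event-related desynchronization (ERD). The *classic* configuration
   encodes only contralateral ERD (rightward intention suppresses the
   left hemisphere; bilateral ERD drives the cursor up); the *centered*
   configuration is symmetric about `A = 0.5`; a *perturbed*
   configuration is fitted to recorded sessions (`fit_perturbed`).
3. **Source signals.** Alpha-band (5–12 Hz) noise carriers, Kaiser-FIR
   bandpassed and Tukey-windowed, are scaled by `A[h,a]·100 µV` on the
   left/right hand-knob ROIs; Brownian (1/f²) background walks with 50 µV
   peaks sit on 500 random cortical vertices (source-level SNR = 2).
4. **Forward projection.** A lead field (analytic three-shell spherical
   head model, or loaded from file) projects source amplitudes to a
   19-channel 10–20 scalp montage.
5. **Online decoding.** Notch (58–62 Hz) + FIR bandpass (2–60 Hz), small
   Laplacian at C3/C4, Burg AR(16) alpha power (8–12 Hz), raw controls
   `C_x = P_C4 − P_C3`, `C_y = −P_C4 − P_C3`, rolling Z-score over the
   past `BW` seconds, velocity `v = S·C'` capped at `CV` px/s, and a
   per-frame cursor position update.
6. **Task engine.** Center-out trials (3 s rest, 2 s preparation, ≤ 6 s
   feedback) in 1D-LR, 1D-UD, or 2D-LRUD paradigms; 24-trial
   block-randomized runs; 10-run parameter-sweep sessions over
   `BW ∈ {30, 60, 90, 120} s`, `NT ∈ {0, 24, 48}` carried-over trials,
   `CV ∈ {200, 250, 300, 350}` px/s. Everything — EEG, event markers,
   ground-truth intention, trial outcomes — is recorded.

Analysis utilities compute percentage trials correct (PTC), average
decision time (timeouts count as 6 s), integrated distance to target,
cursor-position covariance, true-vs-decoded velocity angle, trajectory
length, OLS parameter trends, and paired t-tests.

## Worked example

```python
import numpy as np
from smrsim import make_centered, make_classic

right = np.array([1.0, 0.0])          # full rightward scaled intention
A = make_centered().modulation(right).A
print(round(A[("right", "x")] - A[("right", "y")], 3))   # 0.5
print(round(A[("left", "y")] - A[("left", "x")], 3))     # 0.5

A0 = make_classic().modulation(np.zeros(2)).A
print(round(A0[("left", "x")], 3))                        # 0.982
```

The centered encoding converts a pure rightward intention into factor
differences of 0.5 per hemisphere — the property that removes the
classic configuration's up-right diagonal bias — while the classic
configuration leaves every factor at ≈ 1 (0.982) when no intention is
present (no desynchronization at rest).

Running a short simulated session from the shell:

```bash
smrsim run --paradigm 1d-lr --controller proportional --runs 1 --trials 24 --seed 3 --out session_out
```

prints the per-run metric table, e.g.

```
subject  run param_name  param_value label       ptc  decision_time  integrated_distance  n_hits  n_misses  n_timeouts
     s0    0         BW         60.0  run0 95.833333       3.548611             0.626092      23         0           1
```

meaning 23 of 24 trials hit the correct target (PTC 95.8%), with a mean
feedback-phase duration of 3.55 s and a mean normalized distance to
target of 0.63. `smrsim sweep` runs the full 10-run parameter sweep,
`smrsim metrics` turns saved recordings into tidy CSVs with trend fits,
and `smrsim fit-encoding` fits a perturbed configuration from a
recording.

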