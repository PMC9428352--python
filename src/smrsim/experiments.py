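"""Pre-packaged simulation experiments.

These harnesses rerun the simulator's headline analyses with scripted
controllers at desk scale: the classic-vs-centered encoding comparison on
2D cardinal reaches, the rest-calibrated rightward-bias probe, and the
maximum-cursor-velocity (CV) sweep.  They are what the acceptance script
and the statistics-level tests execute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import position_covariance, run_metrics, trajectory_metrics
from .encoding import make_centered, make_classic
from .task import (
    ConstantController,
    RunSpec,
    SessionSpec,
    TrialSpec,
    default_stack,
    run_session,
    run_trial,
)

__all__ = [
    "rightward_bias_probe",
    "encoding_comparison",
    "cv_sweep",
]


def rightward_bias_probe(encoding_kind: str = "classic", seed: int = 0,
                         n_trials: int = 3) -> dict:
    """Constant-rightward intention against a rest-calibrated baseline.

    A zero-intention calibration trial fills the normalization buffers with
    resting statistics; subsequent trials drive a constant full-rightward
    intention.  Returns the mean decoded velocity components and the mean
    deviation angle from (1, 0), averaged over the post-calibration trials.
    """
    encoding = {"classic": make_classic, "centered": make_centered}[encoding_kind]()
    stack = default_stack(encoding=encoding)
    root = np.random.SeedSequence((seed, 0x51DE))
    gen_rng, ctrl_rng = (np.random.default_rng(s) for s in root.spawn(2))
    generator = stack.make_generator(gen_rng)

    rest = ConstantController(direction=(1.0, 0.0), speed=0.0)
    right = ConstantController(direction=(1.0, 0.0), speed=400.0)
    run_trial(TrialSpec("2d-lrud", "R", calibration=True), stack, rest,
              generator, ctrl_rng)
    vs = []
    for _ in range(n_trials):
        res = run_trial(TrialSpec("2d-lrud", "R"), stack, right, generator,
                        ctrl_rng)
        vs.append(res.decoded_v)
    v = np.concatenate(vs, axis=0)
    mean_v = v.mean(axis=0)
    angle = float(np.degrees(np.arctan2(mean_v[1], mean_v[0])))
    return {
        "mean_vx": float(mean_v[0]),
        "mean_vy": float(mean_v[1]),
        "angle_from_right_deg": angle,
        "n_frames": len(v),
    }


def _session_spec_2d(seed: int, encoding, n_runs: int, n_trials: int,
                     controller: str = "proportional") -> SessionSpec:
    runs = tuple(
        RunSpec(n_trials=n_trials, paradigm="2d-lrud", label=f"2d-run{r}")
        for r in range(n_runs)
    )
    return SessionSpec(runs=runs, seed=seed, controller=controller,
                       encoding=encoding)


def encoding_comparison(n_subjects: int = 3, n_runs: int = 3,
                        n_trials: int = 8, seed: int = 0) -> pd.DataFrame:
    """Classic vs. centered on 2D cardinal reaches, paired by subject seed.

    Each simulated subject runs the same session (same seed, hence the same
    targets and controller noise stream) under both encodings.  Rows carry
    the per-subject mean angle deviation, mean trajectory length, and the
    mean pooled position covariance across runs.
    """
    rows = []
    for s in range(n_subjects):
        subject_seed = int(np.random.SeedSequence((seed, s)).generate_state(1)[0]
                           % (2**31))
        for kind, factory in (("classic", make_classic), ("centered", make_centered)):
            rec = run_session(
                _session_spec_2d(subject_seed, factory(), n_runs, n_trials)
            )
            trials = [t for t in rec.trial_results if not t.calibration]
            tms = [trajectory_metrics(t) for t in trials]
            angles = [t.mean_angle_deviation for t in tms
                      if t.mean_angle_deviation is not None]
            covs = [
                position_covariance(
                    [t for t in trials if t.run_index == ri]
                )
                for ri in range(n_runs)
            ]
            rows.append(
                {
                    "subject": s,
                    "encoding": kind,
                    "mean_angle_deviation": float(np.mean(angles)),
                    "mean_trajectory_length": float(
                        np.mean([t.trajectory_length for t in tms])
                    ),
                    "mean_position_covariance": float(np.mean(covs)),
                    "ptc": run_metrics(trials).ptc,
                }
            )
    return pd.DataFrame(rows)


def cv_sweep(n_seeds: int = 16, cv_values=(200.0, 250.0, 300.0, 350.0),
             n_trials: int = 4, sigma: float = 0.3,
             seed: int = 0) -> pd.DataFrame:
    """Average decision time against the maximum cursor velocity.

    Each seed simulates one subject running one short 1D LR run per CV
    value with a noisy-proportional controller; rows are
    (seed, cv, decision_time, ptc).
    """
    rows = []
    for s in range(n_seeds):
        subject_seed = int(np.random.SeedSequence((seed, 0xC5, s))
                           .generate_state(1)[0] % (2**31))
        for cv in cv_values:
            runs = (RunSpec(n_trials=n_trials, paradigm="1d-lr", cv=cv,
                            label=f"CV={cv:g}", param_name="CV",
                            param_value=cv),)
            rec = run_session(
                SessionSpec(runs=runs, seed=subject_seed, controller="noisy",
                            controller_kwargs={"sigma": sigma})
            )
            m = run_metrics(rec.trial_results)
            rows.append({"seed": s, "cv": cv,
                         "decision_time": m.avg_decision_time, "ptc": m.ptc})
    return pd.DataFrame(rows)
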