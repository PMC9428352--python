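"""Performance metrics and statistical comparisons.

Run-level metrics: percentage trials correct (PTC, over all trials
including timeouts), average decision time (timeouts counted at the full
6 s feedback limit) and average integrated distance to target (per-trial
mean distance during feedback, averaged over the run's trials).

Trajectory metrics quantify encoding-induced bias: pooled horizontal/
vertical cursor-position covariance, the per-sample angle between true
and decoded velocity, and the trajectory length (decoded speed integrated
over feedback time).

Parameter trends are assessed with an ordinary least squares fit of
metric against parameter value (two-sided slope t-test, 95% CI);
condition contrasts use paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .task import SessionRecording, TrialResult

__all__ = [
    "RunMetrics",
    "TrajectoryMetrics",
    "TrendResult",
    "run_metrics",
    "trajectory_metrics",
    "position_covariance",
    "ols_trend",
    "paired_ttest",
    "session_metrics_table",
]


@dataclass(frozen=True)
class RunMetrics:
    ptc: float  # % of all trials hit
    avg_decision_time: float  # s
    avg_integrated_distance: float  # normalized workspace units
    n_trials: int
    n_hits: int
    n_misses: int
    n_timeouts: int


@dataclass(frozen=True)
class TrajectoryMetrics:
    mean_angle_deviation: float | None  # degrees, None if undefined
    trajectory_length: float  # pixels
    n_samples: int


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    slope_p: float
    points: pd.DataFrame


def run_metrics(results: list[TrialResult],
                feedback_max_s: float = 6.0) -> RunMetrics:
    """Aggregate one run's trial results (all trials included)."""
    if not results:
        raise ValueError("run_metrics requires a non-empty trial list")
    n = len(results)
    hits = sum(r.outcome == "hit" for r in results)
    misses = sum(r.outcome == "miss" for r in results)
    timeouts = sum(r.outcome == "timeout" for r in results)
    times = [feedback_max_s if r.outcome == "timeout" else r.duration_s
             for r in results]
    dists = [float(np.mean(r.distance)) for r in results if len(r.distance)]
    return RunMetrics(
        ptc=100.0 * hits / n,
        avg_decision_time=float(np.mean(times)),
        avg_integrated_distance=float(np.mean(dists)) if dists else float("nan"),
        n_trials=n,
        n_hits=hits,
        n_misses=misses,
        n_timeouts=timeouts,
    )


def trajectory_metrics(result: TrialResult,
                       update_rate: float = 30.0) -> TrajectoryMetrics:
    """Per-trial bias metrics from sample-aligned true/decoded velocities.

    Angle deviation is the absolute angle in [0, 180] degrees between the
    ground-truth scaled intention and the decoded velocity; samples where
    either vector has zero norm are excluded (and the mean is reported as
    missing when no sample survives, never as 0).
    """
    true_v = np.asarray(result.intention, float)
    dec_v = np.asarray(result.decoded_v, float)
    if true_v.shape != dec_v.shape:
        raise ValueError("intention log and decoded velocities must be sample-aligned")
    tn = np.linalg.norm(true_v, axis=1)
    dn = np.linalg.norm(dec_v, axis=1)
    ok = (tn > 0) & (dn > 0)
    if ok.any():
        cosang = np.einsum("ij,ij->i", true_v[ok], dec_v[ok]) / (tn[ok] * dn[ok])
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        mean_ang = float(ang.mean())
    else:
        mean_ang = None
    length = float(dn.sum() / update_rate)
    return TrajectoryMetrics(mean_ang, length, int(ok.sum()))


def position_covariance(results: list[TrialResult]) -> float:
    """Sample covariance of pooled per-frame (x, y) cursor positions
    across the feedback phases of one run (2D paradigm)."""
    pts = [r.trajectory for r in results if len(r.trajectory)]
    if not pts:
        raise ValueError("no trajectory samples")
    xy = np.concatenate(pts, axis=0)
    if len(xy) < 2:
        raise ValueError("need at least 2 pooled position samples")
    return float(np.cov(xy[:, 0], xy[:, 1], ddof=1)[0, 1])


def ols_trend(points: pd.DataFrame, x: str = "param_value",
              y: str = "metric") -> TrendResult:
    """OLS linear fit of a metric against a parameter value.

    ``points`` has one row per (subject-)run.  The slope's two-sided
    t-test p-value and 95% CI are mutually consistent: the CI excludes 0
    exactly when p < 0.05.
    """
    if len(points) < 3:
        raise ValueError("trend fit requires at least 3 points")
    xs = np.asarray(points[x], float)
    ys = np.asarray(points[y], float)
    if len(np.unique(xs)) < 2:
        raise ValueError("trend fit requires at least 2 distinct parameter values")
    model = sm.OLS(ys, sm.add_constant(xs)).fit()
    ci = model.conf_int(alpha=0.05)
    return TrendResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        slope_p=float(model.pvalues[1]),
        points=points[[x, y]].copy(),
    )


def paired_ttest(condition_a, condition_b) -> tuple[float, float, bool]:
    """Two-sided paired t-test; returns (t, p, degenerate).

    Zero-variance differences are flagged degenerate: all-zero differences
    give (0, 1); a non-zero constant difference has an infinite statistic.
    """
    a = np.asarray(condition_a, float)
    b = np.asarray(condition_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired samples must be equal-length 1D arrays, n >= 2")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0, True
        return float(np.sign(d[0]) * np.inf), 0.0, True
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), False


def session_metrics_table(recording: SessionRecording,
                          subject: str = "s0") -> pd.DataFrame:
    """Tidy per-run metric table: one row per run of a recorded session."""
    rows = []
    for ri, spec in enumerate(recording.run_specs):
        trials = [t for t in recording.trial_results if t.run_index == ri]
        m = run_metrics(trials)
        rows.append(
            {
                "subject": subject,
                "run": ri,
                "param_name": spec.param_name,
                "param_value": spec.param_value,
                "label": spec.label,
                "ptc": m.ptc,
                "decision_time": m.avg_decision_time,
                "integrated_distance": m.avg_integrated_distance,
                "n_hits": m.n_hits,
                "n_misses": m.n_misses,
                "n_timeouts": m.n_timeouts,
            }
        )
    return pd.DataFrame(rows)
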