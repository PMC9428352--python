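"""Motor-intention encoding models.

Scaled intention velocity v' (|v'| <= 1) is mapped to four amplitude
modulation factors ``A[h, a]`` — one per (hemisphere, control-axis) pair —
through sigmoids::

    A[h, a] = 1 / (1 + exp(alpha[h, a] * (v'_a + k[h, a])))

A factor multiplies the peak amplitude of that pair's source-level alpha
waveform, so A ~ 1 means full resting mu rhythm and A ~ 0 means complete
event-related desynchronization (ERD).  Three configurations are provided:

* ``classic`` — contralateral-ERD-only: no intention leaves every factor
  near 1; rightward intention suppresses only the left hemisphere
  (Wolpaw-style lateralized control, with bilateral desynchronization
  driving the cursor up).
* ``centered`` — symmetric about A = 0.5, giving orthogonal four-direction
  control at the cost of assuming ipsilateral synchronization.
* ``perturbed`` — sigmoids fitted to a recorded session's C3/C4 alpha
  powers (:func:`fit_perturbed`), making the encoding subject-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import curve_fit

__all__ = [
    "HEMISPHERES",
    "AXES",
    "IntentionSample",
    "ModulationFactors",
    "EncodingConfig",
    "scale_intention",
    "make_classic",
    "make_centered",
    "PerturbedFitData",
    "fit_perturbed",
]

HEMISPHERES = ("left", "right")
AXES = ("x", "y")

#: Default sigmoid steepness.  With |alpha| = 8 the classic configuration
#: gives A(0) ~ 0.982 and A at full contralateral intention ~ 0.018, and the
#: centered configuration reproduces the 0.5 factor difference at v' = (1, 0).
DEFAULT_ALPHA = 8.0
#: Classic offset magnitude; sign is chosen per pair so that A(0) ~ 1.
DEFAULT_CLASSIC_OFFSET = 0.5

#: Fixed sign pattern of the gains: the horizontal pair is mirrored
#: (rightward intention desynchronizes the LEFT hemisphere), the vertical
#: pair is shared-sign (upward intention desynchronizes both hemispheres).
ALPHA_SIGNS = {
    ("left", "x"): +1.0,
    ("right", "x"): -1.0,
    ("left", "y"): +1.0,
    ("right", "y"): +1.0,
}


@dataclass(frozen=True)
class IntentionSample:
    """One intention-velocity sample: raw device units and scaled v'."""

    v_raw: np.ndarray
    v_scaled: np.ndarray
    input_gain: float

    @property
    def dimensionality(self) -> int:
        return len(self.v_scaled)


def scale_intention(v_raw, input_gain: float) -> IntentionSample:
    """Scale raw velocity by the input gain, constraining |v'| <= 1.

    Overflowing vectors are renormalized to unit length (direction
    preserved); the constraint itself is part of the encoding contract.
    """
    if input_gain <= 0:
        raise ValueError("input_gain must be positive")
    v_raw = np.atleast_1d(np.asarray(v_raw, dtype=float))
    if not np.all(np.isfinite(v_raw)):
        raise ValueError("intention velocity must be finite")
    v = input_gain * v_raw
    norm = float(np.linalg.norm(v))
    if norm > 1.0:
        v = v / norm
    return IntentionSample(v_raw=v_raw, v_scaled=v, input_gain=float(input_gain))


@dataclass(frozen=True)
class ModulationFactors:
    """Amplitude modulation factors per (hemisphere, axis), each in (0, 1)."""

    A: dict[tuple[str, str], float]

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.A[key]

    def hemisphere(self, h: str) -> dict[str, float]:
        return {a: v for (hh, a), v in self.A.items() if hh == h}


@dataclass(frozen=True)
class EncodingConfig:
    """Sigmoid parameters (alpha gain, offset k) per (hemisphere, axis).

    A 1D configuration covers a single control axis: ``axis_1d='x'``
    (lateralized left/right control, mirrored gains) or ``axis_1d='y'``
    (bilateral up/down control, shared-sign gains).
    """

    kind: str  # classic | centered | perturbed
    params: dict[tuple[str, str], tuple[float, float]]
    dimensionality: int = 2
    axis_1d: str = "x"

    def __post_init__(self) -> None:
        if self.dimensionality not in (1, 2):
            raise ValueError("dimensionality must be 1 or 2")
        if self.axis_1d not in AXES:
            raise ValueError("axis_1d must be 'x' or 'y'")
        axes = self.axes
        expected = {(h, a) for h in HEMISPHERES for a in axes}
        if set(self.params) != expected:
            raise ValueError(f"params must cover exactly the pairs {sorted(expected)}")
        if "x" in axes:
            alx = self.params[("left", "x")][0]
            arx = self.params[("right", "x")][0]
            if alx * arx >= 0:
                raise ValueError("horizontal gains must have mirrored (opposite) signs")
        if "y" in axes:
            aly = self.params[("left", "y")][0]
            ary = self.params[("right", "y")][0]
            if aly * ary <= 0:
                raise ValueError("vertical gains must share sign")

    @property
    def axes(self) -> tuple[str, ...]:
        if self.dimensionality == 1:
            return (self.axis_1d,)
        return AXES

    def modulation(self, sample: IntentionSample | np.ndarray) -> ModulationFactors:
        """Evaluate the sigmoids at a scaled intention sample."""
        v = sample.v_scaled if isinstance(sample, IntentionSample) else np.atleast_1d(sample)
        if len(v) != self.dimensionality:
            raise ValueError(
                f"intention has dimension {len(v)}, config expects {self.dimensionality}"
            )
        va = dict(zip(self.axes, v))
        A = {
            (h, a): float(1.0 / (1.0 + np.exp(alpha * (va[a] + k))))
            for (h, a), (alpha, k) in self.params.items()
        }
        return ModulationFactors(A)

    # -- persistence (human-readable YAML) -----------------------------

    def save(self, path: str | Path) -> None:
        doc = {
            "kind": self.kind,
            "dimensionality": self.dimensionality,
            "axis_1d": self.axis_1d,
            "params": {
                f"{h}_{a}": {"alpha": float(al), "k": float(k)}
                for (h, a), (al, k) in self.params.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "EncodingConfig":
        doc = yaml.safe_load(Path(path).read_text())
        params = {
            tuple(key.rsplit("_", 1)): (float(v["alpha"]), float(v["k"]))
            for key, v in doc["params"].items()
        }
        return cls(doc["kind"], params, int(doc["dimensionality"]),
                   doc.get("axis_1d", "x"))


def _axes_for(dimensionality: int, axis_1d: str) -> tuple[str, ...]:
    return (axis_1d,) if dimensionality == 1 else AXES


def make_classic(dimensionality: int = 2, axis_1d: str = "x") -> EncodingConfig:
    """Default contralateral-ERD-only configuration.

    Offsets are set to ``-sign(alpha) * 0.5`` so that every factor is ~1 at
    v' = 0 and ~0 at full contralateral intention.
    """
    params = {}
    for h in HEMISPHERES:
        for a in _axes_for(dimensionality, axis_1d):
            alpha = ALPHA_SIGNS[(h, a)] * DEFAULT_ALPHA
            params[(h, a)] = (alpha, -np.sign(alpha) * DEFAULT_CLASSIC_OFFSET)
    return EncodingConfig("classic", params, dimensionality, axis_1d)


def make_centered(dimensionality: int = 2, axis_1d: str = "x") -> EncodingConfig:
    """Symmetric configuration: all offsets zero, so A(0) = 0.5 exactly."""
    params = {
        (h, a): (ALPHA_SIGNS[(h, a)] * DEFAULT_ALPHA, 0.0)
        for h in HEMISPHERES
        for a in _axes_for(dimensionality, axis_1d)
    }
    return EncodingConfig("centered", params, dimensionality, axis_1d)


# -- perturbed configuration fitting -----------------------------------

#: Scaled-intention value assigned to each direction-conditioned mean alpha
#: power, per control axis.  Task-space convention: upward intention
#: (v'_y = +1) desynchronizes both hemispheres, so the up-trial mean maps to
#: +1 on the vertical axis.
MU_ASSIGNMENT = {
    "x": (("L", -1.0), ("UD", 0.0), ("R", +1.0)),
    "y": (("D", -1.0), ("LR", 0.0), ("U", +1.0)),
}

#: |alpha| below this is flagged as a degenerate (flat, no-modulation) fit.
DEGENERATE_ALPHA = 0.5


@dataclass(frozen=True)
class PerturbedFitData:
    """Inspection record of a perturbed-configuration fit."""

    mu: pd.DataFrame  # rows (hemisphere, axis); columns = condition labels
    normalized_mu: pd.DataFrame
    residuals: dict[tuple[str, str], np.ndarray]
    degenerate: dict[tuple[str, str], bool] = field(default_factory=dict)

    def max_residual(self) -> float:
        return max(float(np.abs(r).max()) for r in self.residuals.values())

    def report(self) -> str:
        lines = ["Perturbed encoding fit", "", "Mean alpha powers:",
                 self.mu.to_string(), "", "Normalized:", self.normalized_mu.to_string(), ""]
        for key, res in self.residuals.items():
            flag = "  [degenerate: flat]" if self.degenerate.get(key) else ""
            lines.append(f"residuals {key}: {np.array2string(res, precision=4)}{flag}")
        return "\n".join(lines)


def _sigmoid(v, alpha, k):
    return 1.0 / (1.0 + np.exp(alpha * (v + k)))


def fit_sigmoid(v_points: np.ndarray, mu_points: np.ndarray,
                sign: float) -> tuple[float, float, np.ndarray]:
    """Iterative least-squares fit of (alpha, k) to normalized mu points.

    ``sign`` fixes the direction of modulation expected for the pair (the
    sign pattern is preserved across configurations).  Returns
    (alpha, k, residuals).
    """
    v_points = np.asarray(v_points, float)
    mu_points = np.asarray(mu_points, float)
    spread = mu_points.max() - mu_points.min()
    if spread < 1e-9:
        # flat data: no modulation; return a flat sigmoid through the mean
        level = float(np.clip(mu_points.mean(), 1e-6, 1 - 1e-6))
        return 0.0, float(np.log(1 / level - 1)), mu_points - level

    p0 = (sign * 4.0, 0.0)
    try:
        popt, _ = curve_fit(_sigmoid, v_points, mu_points, p0=p0, maxfev=20000)
    except RuntimeError as err:
        res = mu_points - _sigmoid(v_points, *p0)
        raise RuntimeError(
            f"sigmoid fit did not converge; residuals at start {res}"
        ) from err
    alpha, k = float(popt[0]), float(popt[1])
    residuals = mu_points - _sigmoid(v_points, alpha, k)
    return alpha, k, residuals


def fit_perturbed(session, paradigm: str = "2d-lrud",
                  decoder_params=None) -> tuple[EncodingConfig, PerturbedFitData]:
    """Fit a perturbed EncodingConfig from one or more recorded sessions.

    Pipeline: extract feedback-period epochs of hit trials; preprocess each
    epoch with the decoder's filter chain (notch 58-62 Hz, bandpass FIR
    2-60 Hz); compute Burg alpha power at Laplacian-filtered C3 (h=left)
    and C4 (h=right) per epoch; average per direction and per pooled
    control axis to obtain the 12 mean powers; normalize each
    (hemisphere, axis) triplet by its maximum; fit each sigmoid's
    (alpha, k) to its three (v', mu) points.

    ``session`` is a SessionRecording with 2D LRUD trials, or a sequence of
    recordings (e.g. a 1D LR and a 1D UD session) that are pooled.
    """
    from .decoder import DecoderParams, Preprocessor, burg_alpha_power, laplacian

    recordings = session if isinstance(session, (list, tuple)) else [session]
    params = decoder_params or DecoderParams()

    per_direction: dict[str, list[tuple[float, float]]] = {d: [] for d in "LRUD"}
    settle = int(round(0.5 * params.fs))  # skip the feedback-onset transition
    for rec in recordings:
        # filter the continuous recording once so epoch power is not diluted
        # by per-epoch filter warm-up
        pre = Preprocessor(params, rec.eeg.shape[0])
        filtered = pre.process(np.asarray(rec.eeg, dtype=float))
        c3l, c4l = laplacian(filtered, rec.montage)
        win = params.psd_window  # decoder's own analysis-window length
        for trial in rec.trial_results:
            if trial.outcome != "hit" or trial.calibration:
                continue
            lo = trial.feedback_start + settle
            hi = trial.feedback_end
            if hi - lo < params.ar_order + 2:
                lo = trial.feedback_start
            # fixed-length windows, same estimator as the online decoder, so
            # epoch duration does not bias the spectral estimate
            starts = range(lo, max(hi - win + 1, lo + 1), win)
            p3s, p4s = zip(*(
                (burg_alpha_power(c3l[s : min(s + win, hi)], params),
                 burg_alpha_power(c4l[s : min(s + win, hi)], params))
                for s in starts
            ))
            per_direction[trial.target].append(
                (float(np.mean(p3s)), float(np.mean(p4s)))
            )

    missing = [d for d, v in per_direction.items() if not v]
    if missing:
        raise ValueError(f"no hit trials in direction(s): {missing}")

    def mean_power(dirs: str, hemi_idx: int) -> float:
        # equal weight per direction so unbalanced hit counts cannot skew
        # the axis-pooled (LR / UD) baselines
        per_dir = [
            float(np.mean([p[hemi_idx] for p in per_direction[d]])) for d in dirs
        ]
        return float(np.mean(per_dir))

    conditions = {"L": "L", "R": "R", "U": "U", "D": "D", "LR": "LR", "UD": "UD"}
    mu = pd.DataFrame(
        {
            cond: {
                ("left", "C3"): mean_power(dirs, 0),
                ("right", "C4"): mean_power(dirs, 1),
            }
            for cond, dirs in conditions.items()
        }
    )
    mu.index = pd.Index(["left", "right"], name="hemisphere")

    fitted: dict[tuple[str, str], tuple[float, float]] = {}
    residuals: dict[tuple[str, str], np.ndarray] = {}
    degenerate: dict[tuple[str, str], bool] = {}
    norm_rows = {}
    for h in HEMISPHERES:
        for a in AXES:
            conds_v = MU_ASSIGNMENT[a]
            raw = np.array([mu.loc[h, cond] for cond, _ in conds_v])
            norm = raw / raw.max()
            v_pts = np.array([v for _, v in conds_v])
            sign = ALPHA_SIGNS[(h, a)]
            alpha, k, res = fit_sigmoid(v_pts, norm, sign)
            fitted[(h, a)] = (alpha, k)
            residuals[(h, a)] = res
            degenerate[(h, a)] = abs(alpha) < DEGENERATE_ALPHA
            norm_rows[(h, a)] = dict(zip([c for c, _ in conds_v], norm))

    normalized = pd.DataFrame(norm_rows).T
    normalized.index = pd.MultiIndex.from_tuples(normalized.index,
                                                 names=["hemisphere", "axis"])
    # preserve the canonical sign pattern even if a fit came out flat
    for key, (alpha, k) in fitted.items():
        if alpha == 0.0:
            fitted[key] = (ALPHA_SIGNS[key] * 1e-6, k)

    cfg = EncodingConfig("perturbed", fitted, dimensionality=2)
    data = PerturbedFitData(mu=mu, normalized_mu=normalized,
                            residuals=residuals, degenerate=degenerate)
    return cfg, data
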