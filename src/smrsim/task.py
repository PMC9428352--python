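"""Closed-loop task engine: trials, runs, sessions, scripted controllers.

A session is a sequence of runs; a run is a block-randomized sequence of
center-out trials (3 s rest, 2 s preparation, up to 6 s feedback control).
During feedback, every display frame closes the loop:

    controller -> intention scaling -> encoding sigmoids -> source
    waveforms -> lead-field projection -> online decoder -> cursor update
    -> hit test

Scripted controllers stand in for the pointing-device input of an
interactive run, which makes sessions fully reproducible from a seed.
Everything is recorded: the raw multichannel EEG stream, event markers,
the ground-truth intention log, and per-trial results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .decoder import DecoderParams, NormalizationBuffer, OnlineDecoder, carry_buffer
from .encoding import AXES as AXES_XY
from .encoding import EncodingConfig, make_classic, scale_intention
from .forward_model import (
    LeadField,
    Montage,
    SourceSpace,
    build_spherical_leadfield,
    default_hand_knob_spec,
    label_hand_knob,
)
from .source_signals import SignalGenConfig, SourceGenerator

__all__ = [
    "TARGET_THICKNESS",
    "TrialSpec",
    "RunSpec",
    "SessionSpec",
    "TrialResult",
    "Marker",
    "SessionRecording",
    "hit_test",
    "target_center",
    "block_randomized_targets",
    "ProportionalController",
    "ConstantController",
    "NoisyProportionalController",
    "make_controller",
    "SimulatorStack",
    "default_stack",
    "run_trial",
    "run_session",
    "default_sweep_runs",
]

#: Target bars span this thickness (normalized task-space units) at the
#: workspace edge.
TARGET_THICKNESS = 0.0625

_PARADIGM_TARGETS = {
    "1d-lr": ("L", "R"),
    "1d-ud": ("D", "U"),
    "2d-lrud": ("L", "R", "U", "D"),
}
#: Control-axis index (0 = horizontal, 1 = vertical) of the 1D paradigms.
_PARADIGM_AXIS = {"1d-lr": 0, "1d-ud": 1}


@dataclass(frozen=True)
class TrialSpec:
    paradigm: str = "1d-lr"
    target: str = "R"
    rest_s: float = 3.0
    prep_s: float = 2.0
    feedback_max_s: float = 6.0
    calibration: bool = False

    def __post_init__(self) -> None:
        if self.paradigm not in _PARADIGM_TARGETS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.target not in _PARADIGM_TARGETS[self.paradigm]:
            raise ValueError(
                f"target {self.target!r} invalid for paradigm {self.paradigm!r}"
            )
        if min(self.rest_s, self.prep_s, self.feedback_max_s) <= 0:
            raise ValueError("phase durations must be positive")


@dataclass(frozen=True)
class RunSpec:
    n_trials: int = 24
    paradigm: str = "1d-lr"
    bw: float = 60.0
    nt: int = 0
    cv: float = 250.0
    label: str = "default"
    param_name: str = "BW"
    param_value: float = 60.0

    @property
    def first_trial_is_calibration(self) -> bool:
        return self.nt == 0


@dataclass(frozen=True)
class SessionSpec:
    runs: tuple[RunSpec, ...]
    seed: int = 0
    controller: str = "proportional"
    controller_kwargs: dict = field(default_factory=dict)
    encoding: EncodingConfig | None = None
    gen_config: SignalGenConfig = field(default_factory=SignalGenConfig)
    decoder_defaults: DecoderParams = field(default_factory=DecoderParams)
    n_vertices: int = 2000
    input_gain: float = 0.005
    screen: tuple[float, float] = (1000.0, 1000.0)


def target_center(target: str) -> np.ndarray:
    """Center of a target bar in normalized task space."""
    half = 1.0 - TARGET_THICKNESS / 2
    return {
        "L": np.array([-half, 0.0]),
        "R": np.array([half, 0.0]),
        "U": np.array([0.0, half]),
        "D": np.array([0.0, -half]),
    }[target]


def _contacted(pos_norm: np.ndarray, paradigm: str) -> str | None:
    """Which target bar (if any) the cursor center is inside (closed bounds)."""
    x, y = pos_norm
    inner = 1.0 - TARGET_THICKNESS
    if paradigm == "1d-lr":
        if x <= -inner:
            return "L"
        if x >= inner:
            return "R"
        return None
    if paradigm == "1d-ud":
        if y <= -inner:
            return "D"
        if y >= inner:
            return "U"
        return None
    for lab, inside in (
        ("L", x <= -inner), ("R", x >= inner), ("U", y >= inner), ("D", y <= -inner),
    ):
        if inside:
            return lab
    return None


def hit_test(pos_norm: np.ndarray, target: str,
             paradigm: str = "2d-lrud") -> str | None:
    """Returns None (no contact), 'correct' or 'incorrect'."""
    lab = _contacted(np.asarray(pos_norm, float), paradigm)
    if lab is None:
        return None
    return "correct" if lab == target else "incorrect"


def block_randomized_targets(paradigm: str, n_trials: int,
                             rng: np.random.Generator) -> list[str]:
    """Targets distributed block-wise in a pairwise (1D) / quadruple (2D)
    fashion: each block holds one of each direction, shuffled independently,
    guaranteeing equal per-direction counts within the run."""
    labels = _PARADIGM_TARGETS[paradigm]
    if n_trials % len(labels) != 0:
        raise ValueError(
            f"n_trials={n_trials} not divisible by {len(labels)} targets"
        )
    out: list[str] = []
    for _ in range(n_trials // len(labels)):
        block = list(labels)
        rng.shuffle(block)
        out.extend(block)
    return out


# -- scripted controllers ----------------------------------------------


class ProportionalController:
    """Raw velocity proportional to the cursor-to-target error vector."""

    def __init__(self, gain: float = 600.0):
        self.gain = gain  # device units/s per normalized unit of error

    def step(self, pos_norm: np.ndarray, target: str,
             rng: np.random.Generator) -> np.ndarray:
        return self.gain * (target_center(target) - pos_norm)


class ConstantController:
    """Constant-direction raw velocity, ignoring the cursor position.

    With an explicit ``direction`` the same velocity is emitted on every
    frame of every trial; with ``direction=None`` the controller pushes at
    full speed along the current trial's cardinal target direction — the
    straight-line reaching behavior used for encoder-calibration runs.
    """

    def __init__(self, direction=(1.0, 0.0), speed: float = 300.0):
        if direction is None:
            self.v = None
            self.speed = speed
        else:
            d = np.asarray(direction, float)
            self.v = speed * d / np.linalg.norm(d)

    def step(self, pos_norm, target, rng) -> np.ndarray:
        if self.v is None:
            d = target_center(target)
            return self.speed * d / np.linalg.norm(d)
        return self.v.copy()


class NoisyProportionalController(ProportionalController):
    """Proportional control with Gaussian directional noise (radians)."""

    def __init__(self, gain: float = 600.0, sigma: float = 0.3):
        super().__init__(gain)
        self.sigma = sigma

    def step(self, pos_norm, target, rng) -> np.ndarray:
        v = super().step(pos_norm, target, rng)
        if self.sigma > 0:
            ang = rng.normal(0.0, self.sigma)
            c, s = np.cos(ang), np.sin(ang)
            v = np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])
        return v


_CONTROLLERS = {
    "proportional": ProportionalController,
    "constant": ConstantController,
    "noisy": NoisyProportionalController,
}


def make_controller(name: str, **kwargs):
    try:
        cls = _CONTROLLERS[name]
    except KeyError:
        raise ValueError(
            f"unknown controller policy {name!r}; choose from {sorted(_CONTROLLERS)}"
        ) from None
    return cls(**kwargs)


# -- recording containers ----------------------------------------------


@dataclass(frozen=True)
class Marker:
    sample: int
    kind: str  # rest | prep | feedback | outcome | run_start | run_end
    info: str = ""


@dataclass
class TrialResult:
    outcome: str  # hit | miss | timeout
    target: str
    duration_s: float  # feedback-phase duration
    trajectory: np.ndarray  # (n_frames, 2) cursor positions, pixels
    decoded_v: np.ndarray  # (n_frames, 2) pixels/s
    intention: np.ndarray  # (n_frames, 2) scaled ground-truth intention v'
    distance: np.ndarray  # (n_frames,) normalized distance to correct target
    calibration: bool = False
    run_index: int = 0
    feedback_start: int = 0  # sample index into the session EEG stream
    feedback_end: int = 0


@dataclass
class SessionRecording:
    """One recorded session: EEG stream, markers, ground truth, results."""

    eeg: np.ndarray  # (n_channels, n_samples) float32, uV
    fs: float
    montage: Montage
    markers: list[Marker]
    intention_log: pd.DataFrame
    trial_results: list[TrialResult]
    run_specs: list[RunSpec]
    parameters: dict
    truncated: bool = False

    def feedback_eeg(self, trial: TrialResult) -> np.ndarray:
        return np.asarray(self.eeg[:, trial.feedback_start : trial.feedback_end],
                          dtype=float)

    def validate_markers(self) -> None:
        samples = [m.sample for m in self.markers]
        if any(b < a for a, b in zip(samples, samples[1:])):
            raise ValueError("marker sample indices must be non-decreasing")
        if samples and samples[-1] > self.eeg.shape[1]:
            raise ValueError("marker beyond the end of the EEG stream")

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(
            d / "eeg.npz",
            eeg=self.eeg.astype(np.float32),
            fs=self.fs,
            channel_names=np.array(self.montage.channel_names),
            channel_positions=self.montage.channel_positions,
        )
        self.intention_log.to_csv(d / "intention.csv", index=False)
        sidecar = {
            "parameters": self.parameters,
            "truncated": self.truncated,
            "markers": [[m.sample, m.kind, m.info] for m in self.markers],
            "run_specs": [vars(r) for r in self.run_specs],
            "trials": [
                {
                    k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in vars(t).items()
                }
                for t in self.trial_results
            ],
        }
        (d / "session.json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, directory: str | Path) -> "SessionRecording":
        d = Path(directory)
        with np.load(d / "eeg.npz") as data:
            eeg = data["eeg"]
            fs = float(data["fs"])
            montage = Montage(
                tuple(str(n) for n in data["channel_names"]),
                np.asarray(data["channel_positions"], float),
            )
        sidecar = json.loads((d / "session.json").read_text())
        trials = []
        for t in sidecar["trials"]:
            for k in ("trajectory", "decoded_v", "intention", "distance"):
                t[k] = np.asarray(t[k], float)
            trials.append(TrialResult(**t))
        return cls(
            eeg=eeg,
            fs=fs,
            montage=montage,
            markers=[Marker(int(s), k, i) for s, k, i in sidecar["markers"]],
            intention_log=pd.read_csv(d / "intention.csv"),
            trial_results=trials,
            run_specs=[RunSpec(**r) for r in sidecar["run_specs"]],
            parameters=sidecar["parameters"],
            truncated=sidecar["truncated"],
        )


# -- the closed-loop stack ---------------------------------------------


@dataclass
class SimulatorStack:
    """Everything a trial needs: montage, calibrated lead field, labeled
    source space, encoding config, generator config, decoder."""

    montage: Montage
    leadfield: LeadField
    source_space: SourceSpace
    encoding: EncodingConfig
    gen_config: SignalGenConfig
    decoder: OnlineDecoder
    input_gain: float = 0.005

    def __post_init__(self) -> None:
        if self.leadfield.n_channels != len(self.montage):
            raise ValueError("lead field channel count does not match the montage")
        if self.leadfield.n_vertices != self.source_space.n_vertices:
            raise ValueError("lead field vertex count does not match the source space")
        for name in ("left_hand_knob", "right_hand_knob"):
            if name not in self.source_space.roi_labels:
                raise ValueError(f"source space is missing the {name!r} ROI")

    def make_generator(self, rng) -> SourceGenerator:
        return SourceGenerator(
            self.gen_config,
            self.source_space.roi_labels,
            self.source_space.n_vertices,
            rng,
            axes=self.encoding.axes,
        )

    def project(self, frame) -> np.ndarray:
        return self.leadfield.gain[:, frame.vertex_indices] @ frame.amplitudes


_LEADFIELD_CACHE: dict[tuple, LeadField] = {}


def default_stack(
    encoding: EncodingConfig | None = None,
    decoder_params: DecoderParams | None = None,
    gen_config: SignalGenConfig | None = None,
    n_vertices: int = 2000,
    screen: tuple[float, float] = (1000.0, 1000.0),
    input_gain: float = 0.005,
) -> SimulatorStack:
    """Build the built-in spherical-model stack (lead field memoized)."""
    montage = Montage.standard_1020()
    key = ("spherical", n_vertices)
    if key not in _LEADFIELD_CACHE:
        ss = SourceSpace.fibonacci_sphere(n_vertices)
        ss = label_hand_knob(ss, default_hand_knob_spec(montage))
        lf = build_spherical_leadfield(montage, ss).normalize_columns()
        _LEADFIELD_CACHE[key] = replace(lf, source_space=ss)
    lf = _LEADFIELD_CACHE[key]
    params = decoder_params or DecoderParams()
    return SimulatorStack(
        montage=montage,
        leadfield=lf,
        source_space=lf.source_space,
        encoding=encoding or make_classic(),
        gen_config=gen_config or SignalGenConfig(),
        decoder=OnlineDecoder(params, montage, screen=screen),
        input_gain=input_gain,
    )


def _frame_lengths(fs: float, update_rate: float, n_frames: int,
                   start_frame: int = 0) -> np.ndarray:
    k = np.arange(start_frame, start_frame + n_frames + 1)
    bounds = np.floor(k * fs / update_rate + 0.5).astype(int)
    return np.diff(bounds)


def _px_to_norm(pos_px: np.ndarray, screen) -> np.ndarray:
    return 2.0 * pos_px / np.asarray(screen, float) - 1.0


class _SessionState:
    """Mutable accumulation of the session stream and logs."""

    def __init__(self) -> None:
        self.eeg_chunks: list[np.ndarray] = []
        self.n_samples = 0
        self.markers: list[Marker] = []
        self.log_rows: list[dict] = []

    def push(self, frame: np.ndarray) -> None:
        self.eeg_chunks.append(frame.astype(np.float32))
        self.n_samples += frame.shape[1]


def run_trial(
    trial: TrialSpec,
    stack: SimulatorStack,
    controller,
    generator: SourceGenerator,
    rng: np.random.Generator,
    state: _SessionState | None = None,
    run_index: int = 0,
) -> TrialResult:
    """Execute one closed-loop trial through the full stack."""
    state = state or _SessionState()
    params = stack.decoder.params
    fs, ur = params.fs, params.update_rate
    n_rest = int(round(trial.rest_s * ur))
    n_prep = int(round(trial.prep_s * ur))
    n_fb = int(round(trial.feedback_max_s * ur))
    lens = _frame_lengths(fs, ur, n_rest + n_prep + n_fb)
    axis_1d = _PARADIGM_AXIS.get(trial.paradigm)  # None for 2D
    enc = stack.encoding
    if axis_1d is not None and enc.dimensionality == 1:
        if enc.axes[0] != AXES_XY[axis_1d]:
            raise ValueError(
                f"1D encoding controls axis {enc.axes[0]!r} but the paradigm "
                f"{trial.paradigm!r} needs {AXES_XY[axis_1d]!r}"
            )
    zero = np.zeros(enc.dimensionality)
    rest_factors = stack.encoding.modulation(
        scale_intention(zero, stack.input_gain)
    )

    def emit(n_samp, factors):
        src = generator.next_frame(n_samp, factors)
        scalp = stack.project(src)
        state.push(scalp)
        return scalp

    state.markers.append(Marker(state.n_samples, "rest", trial.target))
    for k in range(n_rest):
        stack.decoder.ingest(emit(lens[k], rest_factors))
    state.markers.append(Marker(state.n_samples, "prep", trial.target))
    for k in range(n_rest, n_rest + n_prep):
        stack.decoder.ingest(emit(lens[k], rest_factors))

    stack.decoder.reset_cursor()
    fb_start = state.n_samples
    state.markers.append(Marker(fb_start, "feedback", trial.target))
    trajectory, decoded, intent, dist = [], [], [], []
    outcome = "timeout"
    tgt = target_center(trial.target)
    frames_used = 0
    for k in range(n_rest + n_prep, n_rest + n_prep + n_fb):
        pos_norm = _px_to_norm(stack.decoder.cursor.position, stack.decoder.screen)
        v_raw = np.asarray(controller.step(pos_norm, trial.target, rng), float)
        if axis_1d is not None:
            # 1D paradigm: only the paradigm's control axis reaches the encoder
            comp = v_raw[axis_1d]
            if enc.dimensionality == 1:
                v_raw = np.array([comp])
            else:
                v_raw = np.zeros(2)
                v_raw[axis_1d] = comp
        sample = scale_intention(v_raw, stack.input_gain)
        factors = enc.modulation(sample)
        scalp = emit(lens[k], factors)
        out = stack.decoder.decode_frame(scalp, calibration=trial.calibration,
                                         move_cursor=False)
        v = out.v.copy()
        if axis_1d is not None:
            v[1 - axis_1d] = 0.0
        stack.decoder.cursor.position += v / ur
        stack.decoder.cursor.clamp()
        frames_used += 1

        pos_norm = _px_to_norm(stack.decoder.cursor.position, stack.decoder.screen)
        v_scaled_2d = np.zeros(2)
        if enc.dimensionality == 1:
            v_scaled_2d[axis_1d if axis_1d is not None else 0] = sample.v_scaled[0]
        else:
            v_scaled_2d[:] = sample.v_scaled
        trajectory.append(stack.decoder.cursor.position.copy())
        decoded.append(v)
        intent.append(v_scaled_2d)
        dist.append(float(np.linalg.norm(pos_norm - tgt)))
        state.log_rows.append(
            {
                "sample": state.n_samples,
                "run": run_index,
                "target": trial.target,
                "vraw_x": v_raw[0] if len(v_raw) == 2 else
                (v_raw[0] if axis_1d in (0, None) else 0.0),
                "vraw_y": v_raw[1] if len(v_raw) == 2 else
                (v_raw[0] if axis_1d == 1 else 0.0),
                "vprime_x": v_scaled_2d[0],
                "vprime_y": v_scaled_2d[1],
                "vdec_x": v[0],
                "vdec_y": v[1],
                "pos_x": stack.decoder.cursor.position[0],
                "pos_y": stack.decoder.cursor.position[1],
            }
        )
        contact = hit_test(pos_norm, trial.target, trial.paradigm)
        if contact is not None:
            outcome = "hit" if contact == "correct" else "miss"
            break

    fb_end = state.n_samples
    state.markers.append(Marker(fb_end, "outcome", outcome))
    return TrialResult(
        outcome=outcome,
        target=trial.target,
        duration_s=frames_used / ur,
        trajectory=np.array(trajectory).reshape(-1, 2),
        decoded_v=np.array(decoded).reshape(-1, 2),
        intention=np.array(intent).reshape(-1, 2),
        distance=np.asarray(dist, float),
        calibration=trial.calibration,
        run_index=run_index,
        feedback_start=fb_start,
        feedback_end=fb_end,
    )


def run_session(spec: SessionSpec) -> SessionRecording:
    """Execute all runs of a session spec and return the full recording."""
    root = np.random.SeedSequence(spec.seed)
    ss_targets, ss_gen, ss_ctrl = root.spawn(3)
    target_rng = np.random.default_rng(ss_targets)
    ctrl_rng = np.random.default_rng(ss_ctrl)

    stack = default_stack(
        encoding=spec.encoding,
        decoder_params=spec.decoder_defaults,
        gen_config=spec.gen_config,
        n_vertices=spec.n_vertices,
        screen=spec.screen,
        input_gain=spec.input_gain,
    )
    generator = stack.make_generator(np.random.default_rng(ss_gen))
    controller = make_controller(spec.controller, **spec.controller_kwargs)

    state = _SessionState()
    results: list[TrialResult] = []
    for ri, run in enumerate(spec.runs):
        params = replace(stack.decoder.params, bw=run.bw, nt=run.nt, cv=run.cv)
        stack.decoder.params = params
        if run.nt == 0:
            for a in ("x", "y"):
                stack.decoder.buffers[a] = NormalizationBuffer(params.buffer_capacity)
        else:
            for a in ("x", "y"):
                stack.decoder.buffers[a] = carry_buffer(stack.decoder.buffers[a],
                                                        run.nt)
        state.markers.append(Marker(state.n_samples, "run_start", run.label))
        targets = block_randomized_targets(run.paradigm, run.n_trials, target_rng)
        for ti, tgt in enumerate(targets):
            trial = TrialSpec(
                paradigm=run.paradigm,
                target=tgt,
                calibration=(ti == 0 and run.first_trial_is_calibration),
            )
            results.append(
                run_trial(trial, stack, controller, generator, ctrl_rng,
                          state=state, run_index=ri)
            )
        state.markers.append(Marker(state.n_samples, "run_end", run.label))

    eeg = (np.concatenate(state.eeg_chunks, axis=1)
           if state.eeg_chunks else np.zeros((len(stack.montage), 0), np.float32))
    rec = SessionRecording(
        eeg=eeg,
        fs=stack.decoder.params.fs,
        montage=stack.montage,
        markers=state.markers,
        intention_log=pd.DataFrame(state.log_rows),
        trial_results=results,
        run_specs=list(spec.runs),
        parameters={
            "seed": spec.seed,
            "controller": spec.controller,
            "encoding": spec.encoding.kind if spec.encoding else "classic",
            "input_gain": spec.input_gain,
        },
    )
    rec.validate_markers()
    return rec


def default_sweep_runs(seed: int = 0, n_trials: int = 24,
                       paradigm: str = "1d-lr") -> tuple[RunSpec, ...]:
    """The 10-run parameter sweep: 4 BW runs + 2 NT runs + 4 CV runs.

    The NT = 0 condition is jointly represented by the BW = 60 s default
    run.  Values are randomized within each parameter type, except the NT
    block which always runs [24, 48] so that the NT = 48 run's
    normalization history genuinely spans the two preceding runs.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB10C)))
    bw_vals = [30.0, 60.0, 90.0, 120.0]
    cv_vals = [200.0, 250.0, 300.0, 350.0]
    rng.shuffle(bw_vals)
    rng.shuffle(cv_vals)
    runs = [
        RunSpec(n_trials=n_trials, paradigm=paradigm, bw=v, nt=0, cv=250.0,
                label=f"BW={v:g}s", param_name="BW", param_value=v)
        for v in bw_vals
    ]
    runs += [
        RunSpec(n_trials=n_trials, paradigm=paradigm, bw=60.0, nt=v, cv=250.0,
                label=f"NT={v}", param_name="NT", param_value=float(v))
        for v in (24, 48)
    ]
    runs += [
        RunSpec(n_trials=n_trials, paradigm=paradigm, bw=60.0, nt=0, cv=v,
                label=f"CV={v:g}px/s", param_name="CV", param_value=v)
        for v in cv_vals
    ]
    return tuple(runs)
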