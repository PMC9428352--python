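"""Source-level waveform generation.

Each update frame composes two signal families on the cortical source
space:

* four task signals — alpha-band (5-12 Hz) noise carriers, one per
  (hemisphere, axis) pair, Kaiser-FIR bandpassed, Tukey-windowed per epoch
  and peak-normalized; each frame is scaled by the current amplitude
  modulation factor ``A[h, a] * task_peak_amp`` and the two axis signals of
  a hemisphere are summed onto that hemisphere's hand-knob ROI vertices;
* background activity — independent Brownian (1/f^2) walks on a random set
  of vertices, mean-removed and peak-normalized per epoch.

Amplitudes are in microvolt-equivalent units: with a column-calibrated
lead field (see ``LeadField.normalize_columns``), a source of amplitude 100
produces a 100 uV peak at its best-coupled channel, making the default
100/50 task-to-background ratio the operational SNR statement.

Signals are generated in fixed-length epochs and consumed frame-by-frame;
the Brownian walks persist across epochs so the background has no
resets at epoch boundaries (beyond the per-epoch normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import firwin, kaiserord, lfilter
from scipy.signal.windows import tukey

from .encoding import AXES, HEMISPHERES, ModulationFactors

__all__ = [
    "SignalGenConfig",
    "SourceFrame",
    "design_task_filter",
    "gen_task_epoch",
    "gen_background",
    "SourceGenerator",
]


@dataclass(frozen=True)
class SignalGenConfig:
    """Parameters of the source-signal generator."""

    fs: float = 250.0
    epoch_len: int = 250  # samples per generated epoch (1 s default)
    passband: tuple[float, float] = (5.0, 12.0)
    transition_low: tuple[float, float] = (3.0, 5.0)
    transition_high: tuple[float, float] = (12.0, 14.0)
    stopband_atten_db: float = 60.0
    tukey_width_frac: float = 0.95
    tukey_cosine_frac: float = 0.8
    task_peak_amp: float = 100.0  # uV-equivalent
    noise_peak_amp: float = 50.0  # uV-equivalent
    n_noise_vertices: int = 500
    pad_steady_state: bool = True

    def __post_init__(self) -> None:
        if self.epoch_len < 2:
            raise ValueError("epoch_len must be at least 2 samples")


def design_task_filter(cfg: SignalGenConfig) -> np.ndarray:
    """Kaiser-window FIR bandpass for the task carrier.

    Cutoffs at the transition-band midpoints with the transition width and
    stopband attenuation fed to the Kaiser empirical order formula, so the
    passband/stopband edges land on the configured 3-5 / 12-14 Hz
    transitions.
    """
    width = min(
        cfg.transition_low[1] - cfg.transition_low[0],
        cfg.transition_high[1] - cfg.transition_high[0],
    )
    numtaps, beta = kaiserord(cfg.stopband_atten_db, width / (cfg.fs / 2))
    numtaps |= 1  # odd length keeps a type-I linear-phase bandpass
    lo = (cfg.transition_low[0] + cfg.transition_low[1]) / 2
    hi = (cfg.transition_high[0] + cfg.transition_high[1]) / 2
    return firwin(numtaps, [lo, hi], window=("kaiser", beta),
                  pass_zero=False, fs=cfg.fs)


def _tukey_mask(cfg: SignalGenConfig) -> np.ndarray:
    """Tukey taper spanning the central width-fraction of the epoch."""
    width = max(2, int(round(cfg.tukey_width_frac * cfg.epoch_len)))
    win = tukey(width, alpha=cfg.tukey_cosine_frac)
    mask = np.zeros(cfg.epoch_len)
    start = (cfg.epoch_len - width) // 2
    mask[start : start + width] = win
    return mask


def _unit_task_epoch(cfg: SignalGenConfig, taps: np.ndarray, mask: np.ndarray,
                     rng: np.random.Generator, n_signals: int = 1) -> np.ndarray:
    """Peak-one task carrier epochs, shape (n_signals, epoch_len)."""
    numtaps = len(taps)
    if cfg.pad_steady_state:
        n = cfg.epoch_len + numtaps
        noise = rng.uniform(-1.0, 1.0, size=(n_signals, n))
        x = lfilter(taps, 1.0, noise, axis=1)[:, numtaps:]
    else:
        if cfg.epoch_len < numtaps + 1:
            raise ValueError(
                f"epoch_len={cfg.epoch_len} too short for the designed filter; "
                f"minimum is {numtaps + 1} samples (or use pad_steady_state)"
            )
        noise = rng.uniform(-1.0, 1.0, size=(n_signals, cfg.epoch_len))
        x = lfilter(taps, 1.0, noise, axis=1)
    x = x * mask
    peak = np.abs(x).max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    return x / peak


def gen_task_epoch(cfg: SignalGenConfig, A_value: float,
                   rng: np.random.Generator) -> np.ndarray:
    """One amplitude-modulated task epoch with peak ``A_value * task_peak_amp``."""
    if not 0.0 < A_value < 1.0:
        raise ValueError("A_value must lie strictly in (0, 1)")
    taps = design_task_filter(cfg)
    wave = _unit_task_epoch(cfg, taps, _tukey_mask(cfg), rng)[0]
    return wave * (A_value * cfg.task_peak_amp)


def gen_background(cfg: SignalGenConfig, n_vertices_total: int,
                   rng: np.random.Generator,
                   walk_state: np.ndarray | None = None):
    """Brownian background epoch on randomly chosen vertices.

    Returns ``(vertex_indices, waveforms, walk_end)``: each waveform is a
    cumulative sum of white noise (continued from ``walk_state`` when
    given), mean-removed and peak-normalized to ``noise_peak_amp``.
    """
    if cfg.n_noise_vertices > n_vertices_total:
        raise ValueError("n_noise_vertices exceeds the number of source vertices")
    idx = rng.choice(n_vertices_total, size=cfg.n_noise_vertices, replace=False)
    start = np.zeros((cfg.n_noise_vertices, 1)) if walk_state is None else \
        np.asarray(walk_state, float).reshape(-1, 1)
    steps = rng.standard_normal((cfg.n_noise_vertices, cfg.epoch_len))
    walk = start + np.cumsum(steps, axis=1)
    centered = walk - walk.mean(axis=1, keepdims=True)
    peak = np.abs(centered).max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    waveforms = centered * (cfg.noise_peak_amp / peak)
    return np.sort(idx), waveforms[np.argsort(idx)], walk[np.argsort(idx), -1]


@dataclass
class SourceFrame:
    """Active-vertex amplitude block for one update frame."""

    vertex_indices: np.ndarray  # (n_active,)
    amplitudes: np.ndarray  # (n_active, n_samples)
    n_vertices: int
    components: dict = field(default_factory=dict)

    def dense(self) -> np.ndarray:
        out = np.zeros((self.n_vertices, self.amplitudes.shape[1]))
        out[self.vertex_indices] = self.amplitudes
        return out


class SourceGenerator:
    """Streaming, deterministic source-frame generator.

    The generator is a pure function of (config, ROI labels, seed,
    modulation sequence): epochs of the four task carriers and of the
    background walks are produced lazily, and :meth:`next_frame` serves
    consecutive sample spans, scaling task slices by the most recent
    modulation factors.
    """

    def __init__(self, cfg: SignalGenConfig, roi_labels: dict, n_vertices: int,
                 rng: np.random.Generator | int,
                 axes: tuple[str, ...] = AXES):
        for name in ("left_hand_knob", "right_hand_knob"):
            if name not in roi_labels or len(roi_labels[name]) == 0:
                raise ValueError(f"roi_labels must contain a non-empty {name!r} set")
        self.cfg = cfg
        self.axes = tuple(axes)
        self.roi = {h: np.asarray(roi_labels[f"{h}_hand_knob"], int)
                    for h in HEMISPHERES}
        self.n_vertices = n_vertices
        self.rng = np.random.default_rng(rng)
        self._taps = design_task_filter(cfg)
        self._mask = _tukey_mask(cfg)
        self._pos = 0  # sample position within the current epoch
        self._walk_state: np.ndarray | None = None
        self._noise_idx: np.ndarray | None = None
        self._new_epoch()
        # active vertex bookkeeping (noise vertices are drawn once per epoch)
        self._roi_all = np.unique(np.concatenate([self.roi["left"], self.roi["right"]]))

    def _new_epoch(self) -> None:
        n_task = len(HEMISPHERES) * len(self.axes)
        waves = _unit_task_epoch(self.cfg, self._taps, self._mask, self.rng, n_task)
        keys = [(h, a) for h in HEMISPHERES for a in self.axes]
        self._task = dict(zip(keys, waves))
        if self.cfg.noise_peak_amp > 0 and self.cfg.n_noise_vertices > 0:
            self._noise_idx, self._noise, self._walk_state = gen_background(
                self.cfg, self.n_vertices, self.rng, self._walk_state
            )
        else:
            self._noise_idx = np.array([], dtype=int)
            self._noise = np.zeros((0, self.cfg.epoch_len))
        self._pos = 0

    def next_frame(self, n_samples: int, factors: ModulationFactors) -> SourceFrame:
        """Compose the next ``n_samples`` of source activity."""
        chunks: list[SourceFrame] = []
        remaining = n_samples
        while remaining > 0:
            take = min(remaining, self.cfg.epoch_len - self._pos)
            chunks.append(self._slice(take, factors))
            remaining -= take
            if self._pos >= self.cfg.epoch_len:
                self._new_epoch()
        if len(chunks) == 1:
            return chunks[0]
        idx = chunks[0].vertex_indices
        if all(np.array_equal(c.vertex_indices, idx) for c in chunks[1:]):
            amp = np.concatenate([c.amplitudes for c in chunks], axis=1)
            return SourceFrame(idx, amp, self.n_vertices)
        # noise vertices changed at an epoch boundary: splice densely
        dense = np.concatenate([c.dense() for c in chunks], axis=1)
        active = np.nonzero(np.abs(dense).sum(axis=1))[0]
        return SourceFrame(active, dense[active], self.n_vertices)

    def _slice(self, n: int, factors: ModulationFactors) -> SourceFrame:
        sl = slice(self._pos, self._pos + n)
        hemi_wave = {}
        for h in HEMISPHERES:
            w = np.zeros(n)
            for a in self.axes:
                A = factors[(h, a)]
                w = w + (A * self.cfg.task_peak_amp) * self._task[(h, a)][sl]
            hemi_wave[h] = w
        idx_parts = [self.roi["left"], self.roi["right"], self._noise_idx]
        idx = np.concatenate(idx_parts)
        amp = np.zeros((len(idx), n))
        nl, nr = len(self.roi["left"]), len(self.roi["right"])
        amp[:nl] = hemi_wave["left"]
        amp[nl : nl + nr] = hemi_wave["right"]
        if len(self._noise_idx):
            amp[nl + nr :] = self._noise[:, sl]
        self._pos += n
        # collapse duplicate vertices (a noise vertex may fall inside an ROI)
        order = np.argsort(idx, kind="stable")
        idx_sorted = idx[order]
        amp_sorted = amp[order]
        uniq, first = np.unique(idx_sorted, return_index=True)
        if len(uniq) != len(idx_sorted):
            out = np.add.reduceat(amp_sorted, first, axis=0)
        else:
            out = amp_sorted
        return SourceFrame(
            uniq, out, self.n_vertices,
            components={"task": hemi_wave, "noise_vertices": self._noise_idx},
        )
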