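"""Online SMR decoding chain.

Raw multichannel EEG frames are turned into cursor velocity through the
classic sensorimotor-rhythm pipeline:

1. causal preprocessing — 58-62 Hz notch, then 2-60 Hz FIR bandpass, with
   persistent per-channel filter state so streaming equals batch filtering;
2. small spatial Laplacian at C3 and C4 (center minus the unweighted mean
   of its four neighbors);
3. Burg autoregressive estimation of 8-12 Hz alpha power over the most
   recent analysis window;
4. raw control signals  C_x = P_C4 - P_C3,  C_y = -P_C4 - P_C3;
5. per-axis Z-scoring against a rolling history of the past BW seconds;
6. velocity  v = S * C'  with the speed capped at CV (direction kept);
7. cursor position integration (v in pixels/s times the frame duration),
   clamped to the screen bounds.

BW (bin width, s), NT (carried-over normalization trials, multiples of 24)
and CV (max cursor speed, pixels/s) are the swept decoder/task parameters.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.signal import firwin, iirnotch, lfilter, sosfilt, tf2sos

from .forward_model import LAPLACIAN_NEIGHBORS, Montage

__all__ = [
    "DecoderParams",
    "Preprocessor",
    "laplacian",
    "burg_ar",
    "burg_psd",
    "burg_alpha_power",
    "epoch_alpha_powers",
    "raw_control",
    "NormalizationBuffer",
    "carry_buffer",
    "velocity",
    "CursorState",
    "update_position",
    "ControlOutput",
    "OnlineDecoder",
]


@dataclass(frozen=True)
class DecoderParams:
    fs: float = 250.0
    notch_band: tuple[float, float] = (58.0, 62.0)
    bandpass: tuple[float, float] = (2.0, 60.0)
    bandpass_numtaps: int = 251
    alpha_band: tuple[float, float] = (8.0, 12.0)
    ar_order: int = 16
    psd_window_s: float = 1.0
    bw: float = 60.0  # normalization bin width, seconds
    nt: int = 0  # carried-over trials (multiples of 24)
    cv: float = 250.0  # max cursor speed, pixels/s
    velocity_gain: float = 600.0  # pixels/s per unit of normalized control
    update_rate: float = 30.0  # control updates (display frames) per second

    def __post_init__(self) -> None:
        if self.bw <= 0 or self.cv <= 0:
            raise ValueError("BW and CV must be positive")
        if not (self.bandpass[0] <= self.alpha_band[0]
                and self.alpha_band[1] <= self.bandpass[1]):
            raise ValueError("alpha band must lie within the bandpass")
        if self.nt % 24 != 0:
            raise ValueError("NT must be a multiple of 24 trials")

    @property
    def psd_window(self) -> int:
        return int(round(self.psd_window_s * self.fs))

    @property
    def buffer_capacity(self) -> int:
        return int(round(self.bw * self.update_rate))


class Preprocessor:
    """Streaming notch + FIR bandpass with persistent per-channel state."""

    def __init__(self, params: DecoderParams, n_channels: int):
        self.params = params
        self.n_channels = n_channels
        f0 = (params.notch_band[0] + params.notch_band[1]) / 2
        bw = params.notch_band[1] - params.notch_band[0]
        b, a = iirnotch(f0, f0 / bw, fs=params.fs)
        self._sos = tf2sos(b, a)
        self._taps = firwin(params.bandpass_numtaps, list(params.bandpass),
                            pass_zero=False, fs=params.fs)
        self._zi_notch = np.zeros((self._sos.shape[0], n_channels, 2))
        self._zi_fir = np.zeros((n_channels, len(self._taps) - 1))

    def process(self, frame: np.ndarray) -> np.ndarray:
        """Filter one (n_channels, n_samples) frame causally."""
        frame = np.asarray(frame, dtype=float)
        if frame.shape[0] != self.n_channels:
            raise ValueError(
                f"frame has {frame.shape[0]} channels, expected {self.n_channels}"
            )
        y, self._zi_notch = sosfilt(self._sos, frame, axis=1, zi=self._zi_notch)
        y, self._zi_fir = lfilter(self._taps, 1.0, y, axis=1, zi=self._zi_fir)
        return y

    def reset(self) -> None:
        self._zi_notch[:] = 0.0
        self._zi_fir[:] = 0.0


def laplacian(frame: np.ndarray, montage: Montage) -> tuple[np.ndarray, np.ndarray]:
    """Small-Laplacian surrogate channels C3l, C4l.

    Center minus the unweighted mean of its four 10-20 neighbors; rejects
    signals common to the center and its neighborhood.
    """
    frame = np.asarray(frame, dtype=float)
    out = []
    for center, neighbors in LAPLACIAN_NEIGHBORS.items():
        ci = montage.index(center)
        ni = [montage.index(n) for n in neighbors]
        out.append(frame[ci] - frame[ni].mean(axis=0))
    return out[0], out[1]


def burg_ar(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Burg reflection-coefficient recursion, vectorized over rows.

    ``x`` is (n_samples,) or (n_series, n_samples); rows are demeaned.
    Returns (coeffs, sigma2) where ``coeffs`` are the AR polynomial
    coefficients a_1..a_p of  x[t] = -sum a_k x[t-k] + e[t]  (so the PSD
    denominator polynomial is [1, a_1, ..., a_p]) and sigma2 the driving
    noise variance per row.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1]
    if n < order + 1:
        raise ValueError(f"window of {n} samples too short for AR order {order}")
    x = x - x.mean(axis=1, keepdims=True)
    f = x.copy()
    b = x.copy()
    a = np.zeros((x.shape[0], order))
    sigma2 = (x * x).sum(axis=1) / n
    for m in range(order):
        fm = f[:, m + 1 :]
        bm = b[:, m : n - 1]
        num = -2.0 * (fm * bm).sum(axis=1)
        den = (fm * fm).sum(axis=1) + (bm * bm).sum(axis=1)
        k = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        a_new = np.empty((x.shape[0], m + 1))
        a_new[:, m] = k
        if m > 0:
            a_new[:, :m] = a[:, :m] + k[:, None] * a[:, m - 1 :: -1]
        a[:, : m + 1] = a_new
        f_next = fm + k[:, None] * bm
        b_next = bm + k[:, None] * fm
        f[:, m + 1 :] = f_next
        b[:, m + 1 :] = b_next
        sigma2 = sigma2 * (1.0 - k * k)
    return a, sigma2


def burg_psd(x: np.ndarray, order: int, fs: float,
             freqs: np.ndarray) -> np.ndarray:
    """One-sided AR power spectral density on a frequency grid."""
    a, sigma2 = burg_ar(x, order)
    poly = np.concatenate([np.ones((a.shape[0], 1)), a], axis=1)
    z = np.exp(-2j * np.pi * np.asarray(freqs, float) / fs)
    zp = z[None, :] ** np.arange(order + 1)[:, None]
    denom = np.abs(poly @ zp) ** 2
    psd = 2.0 * sigma2[:, None] / (fs * np.where(denom > 0, denom, np.inf))
    return psd


def burg_alpha_power(x: np.ndarray, params: DecoderParams,
                     n_freqs: int = 17) -> float:
    """Alpha-band power of one window via Burg AR spectral estimation.

    Returns 0 for a constant (zero-variance) window rather than dividing
    by zero inside the recursion.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0
    lo, hi = params.alpha_band
    freqs = np.linspace(lo, hi, n_freqs)
    psd = burg_psd(x, params.ar_order, params.fs, freqs)[0]
    return float(np.trapezoid(psd, freqs))


def epoch_alpha_powers(eeg: np.ndarray, montage: Montage,
                       params: DecoderParams) -> tuple[float, float]:
    """Offline helper: alpha power at Laplacian C3/C4 for one raw epoch.

    Applies the decoder's own preprocessing chain (fresh filter state) so
    offline fitting pipelines see the same spectra the online decoder sees.
    """
    pre = Preprocessor(params, eeg.shape[0])
    filtered = pre.process(eeg)
    c3l, c4l = laplacian(filtered, montage)
    return (burg_alpha_power(c3l, params), burg_alpha_power(c4l, params))


def raw_control(psd_c3: float, psd_c4: float) -> tuple[float, float]:
    """Raw control signals: C_x = P4 - P3 (lateralization),
    C_y = -P4 - P3 (bilateral desynchronization drives the cursor up)."""
    return psd_c4 - psd_c3, -psd_c4 - psd_c3


class NormalizationBuffer:
    """Rolling history of raw control values covering the past BW seconds.

    Z-scores an incoming value against the buffer contents (sample
    standard deviation, ddof=1) *before* appending it, matching the
    history-only normalization window.  A zero-sigma history yields 0: a
    degenerate history carries no directional information.
    """

    def __init__(self, capacity: int):
        if capacity < 2:
            raise ValueError("buffer capacity must be at least 2")
        self.capacity = capacity
        self._values: deque[float] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._values)

    @property
    def values(self) -> np.ndarray:
        return np.array(self._values)

    def append(self, value: float) -> None:
        self._values.append(float(value))

    def statistics(self) -> tuple[float, float]:
        arr = self.values
        if len(arr) < 2:
            return (float(arr.mean()) if len(arr) else 0.0, 0.0)
        return float(arr.mean()), float(arr.std(ddof=1))

    def normalize(self, value: float, allow_partial: bool = False) -> float:
        if len(self._values) == 0:
            if not allow_partial:
                raise RuntimeError(
                    "normalization buffer is empty; run a calibration trial first"
                )
            self.append(value)
            return 0.0
        mean, sd = self.statistics()
        z = 0.0 if sd == 0 else (value - mean) / sd
        self.append(value)
        return z


def carry_buffer(buffer: NormalizationBuffer, nt: int) -> NormalizationBuffer:
    """Run-boundary semantics for the normalization history.

    NT = 0 resets the buffer (the next run recalibrates); NT > 0 preserves
    the contents across the boundary (NT = 48 spans two boundaries simply
    by being applied at each of them).
    """
    if nt % 24 != 0 or nt < 0:
        raise ValueError("NT must be a non-negative multiple of 24 trials")
    if nt == 0:
        return NormalizationBuffer(buffer.capacity)
    return buffer


def velocity(c_prime_x: float, c_prime_y: float,
             params: DecoderParams) -> np.ndarray:
    """Velocity v = S * C', speed-capped at CV preserving direction."""
    v = params.velocity_gain * np.array([c_prime_x, c_prime_y], dtype=float)
    speed = float(np.linalg.norm(v))
    if speed > params.cv:
        v *= params.cv / speed
    return v


@dataclass
class CursorState:
    """Cursor position in pixels within rectangular screen bounds."""

    position: np.ndarray
    bounds: tuple[float, float, float, float] = (0.0, 0.0, 1000.0, 1000.0)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.clamp()

    def clamp(self) -> None:
        x0, y0, x1, y1 = self.bounds
        self.position[0] = min(max(self.position[0], x0), x1)
        self.position[1] = min(max(self.position[1], y0), y1)


def update_position(state: CursorState, v: np.ndarray,
                    params: DecoderParams) -> CursorState:
    """Integrate velocity over one update frame and clamp to the screen."""
    new = CursorState(state.position + np.asarray(v, float) / params.update_rate,
                      state.bounds)
    return new


@dataclass(frozen=True)
class ControlOutput:
    psd_c3: float
    psd_c4: float
    c_x: float
    c_y: float
    c_prime_x: float
    c_prime_y: float
    v: np.ndarray


class OnlineDecoder:
    """Stateful frame-by-frame decoder: EEG frames in, ControlOutput out."""

    def __init__(self, params: DecoderParams, montage: Montage,
                 screen: tuple[float, float] = (1000.0, 1000.0)):
        self.params = params
        self.montage = montage
        self.screen = screen
        self.pre = Preprocessor(params, len(montage))
        self._lap_buf = np.zeros((2, params.psd_window))
        self._lap_fill = 0
        self.buffers = {
            "x": NormalizationBuffer(params.buffer_capacity),
            "y": NormalizationBuffer(params.buffer_capacity),
        }
        self.cursor = self.centered_cursor()

    def centered_cursor(self) -> CursorState:
        w, h = self.screen
        return CursorState(np.array([w / 2, h / 2]), (0.0, 0.0, float(w), float(h)))

    def reset_cursor(self) -> None:
        self.cursor = self.centered_cursor()

    def end_run(self) -> None:
        """Apply the NT carry rule at a run boundary."""
        for a in ("x", "y"):
            self.buffers[a] = carry_buffer(self.buffers[a], self.params.nt)

    def ingest(self, eeg_frame: np.ndarray) -> None:
        """Preprocess a frame and append its Laplacian samples (no decode)."""
        filtered = self.pre.process(eeg_frame)
        c3l, c4l = laplacian(filtered, self.montage)
        n = len(c3l)
        w = self.params.psd_window
        if n >= w:
            self._lap_buf[0] = c3l[-w:]
            self._lap_buf[1] = c4l[-w:]
        else:
            self._lap_buf = np.roll(self._lap_buf, -n, axis=1)
            self._lap_buf[0, -n:] = c3l
            self._lap_buf[1, -n:] = c4l
        self._lap_fill = min(self._lap_fill + n, w)

    def decode_frame(self, eeg_frame: np.ndarray, calibration: bool = False,
                     move_cursor: bool = True) -> ControlOutput:
        """Full chain for one frame: filter, alpha powers, control, velocity."""
        self.ingest(eeg_frame)
        if self._lap_fill >= max(self.params.ar_order + 1, self.params.psd_window):
            window = self._lap_buf
            if np.ptp(window[0]) == 0 and np.ptp(window[1]) == 0:
                p3 = p4 = 0.0
            else:
                lo, hi = self.params.alpha_band
                freqs = np.linspace(lo, hi, 17)
                psd = burg_psd(window, self.params.ar_order, self.params.fs, freqs)
                p3 = float(np.trapezoid(psd[0], freqs))
                p4 = float(np.trapezoid(psd[1], freqs))
        else:
            p3 = p4 = 0.0
        c_x, c_y = raw_control(p3, p4)
        cpx = self.buffers["x"].normalize(c_x, allow_partial=calibration)
        cpy = self.buffers["y"].normalize(c_y, allow_partial=calibration)
        v = velocity(cpx, cpy, self.params)
        if move_cursor:
            self.cursor = update_position(self.cursor, v, self.params)
        return ControlOutput(p3, p4, c_x, c_y, cpx, cpy, v)
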