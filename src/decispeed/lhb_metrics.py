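"""Left-hemisphere beta (20-35 Hz) power via temporal spectral evolution.

Epochs are band-pass filtered, rectified, trimmed by 200 ms at each end to
drop filter warm-up, then smoothed with a 100 ms moving window advancing in
50 ms increments. Scalars: latency = most negative-going point of the
stimulus-locked baselined trace between 0 and 1000 ms at C3; slope = OLS
fit over -300..-50 ms pre-response; amplitude = mean of the 100 ms window
centered on the response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from decispeed.containers import EpochSet
from decispeed.preprocess import RESPONSE_BASELINE_MS, STIM_BASELINE_MS

BETA_BAND_HZ = (20.0, 35.0)
TRIM_MS = 200.0
SMOOTH_WINDOW_MS = 100.0
SMOOTH_STEP_MS = 50.0
LATENCY_SEARCH_MS = (0.0, 1000.0)
SLOPE_WINDOW_MS = (-300.0, -50.0)
AMP_WINDOW_MS = (-50.0, 50.0)


@dataclass
class TsePower:
    """Trials x time rectified-smoothed band amplitude on a 50 ms grid."""

    power: np.ndarray
    time_ms: np.ndarray
    band_hz: tuple[float, float]
    electrode: str
    alignment: str
    baselined: bool = False

    def mean_trace(self) -> np.ndarray:
        return self.power.mean(axis=0)

    def grid_indices(self, start_ms: float, stop_ms: float) -> np.ndarray:
        return np.flatnonzero(
            (self.time_ms >= start_ms - 1e-9) & (self.time_ms <= stop_ms + 1e-9)
        )


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    nyq = fs / 2.0
    if band[1] >= nyq:
        raise ValueError(f"band {band} exceeds Nyquist {nyq} Hz")
    # long enough for ~unit gain mid-band (25 Hz); zero-phase reflect padding
    # keeps edge transients small ahead of the 200 ms trims
    n_taps = int(round(0.4 * fs))
    n_taps += 1 - n_taps % 2
    taps = signal.firwin(n_taps, band, pass_zero="bandpass", window="hamming", fs=fs)
    half = (n_taps - 1) // 2
    x2 = np.pad(x, [(0, 0), (half, half)], mode="reflect")
    return signal.oaconvolve(x2, taps[np.newaxis, :], mode="valid", axes=-1)


def tse_power(
    epochs: EpochSet,
    electrode: str = "C3",
    band_hz: tuple[float, float] = BETA_BAND_HZ,
    baseline: bool = True,
) -> TsePower:
    """Band-pass -> rectify -> trim 200 ms -> 100 ms boxcar at 50 ms steps.

    Stimulus-locked output is baselined (by subtraction) to -100..0 ms and
    response-locked output to -450..-350 ms pre-response when ``baseline``
    is set and the window survives trimming.
    """
    x = epochs.channel_data(electrode)[epochs.valid_mask()]
    if x.shape[0] == 0:
        raise ValueError("no valid trials for TSE")
    fs = epochs.sampling_rate
    step_ms = 1000.0 / fs
    rect = np.abs(_bandpass(x, fs, band_hz))

    n_trim = int(round(TRIM_MS / step_ms))
    if rect.shape[1] <= 2 * n_trim:
        raise ValueError("epoch too short to survive the 200 ms trims")
    rect = rect[:, n_trim:-n_trim]
    t_ms = epochs.time_ms[n_trim:-n_trim]

    win = int(round(SMOOTH_WINDOW_MS / step_ms))
    win += 1 - win % 2  # odd length so window centers land on the sample grid
    step = int(round(SMOOTH_STEP_MS / step_ms))
    # trapezoid weights: half-weight endpoints give an effective span of
    # exactly SMOOTH_WINDOW_MS, cancelling rectification ripple of carriers
    # whose half-period divides the window
    w = np.ones(win)
    w[0] = w[-1] = 0.5
    w /= w.sum()
    starts = np.arange(0, rect.shape[1] - win + 1, step)
    power = np.stack([rect[:, s : s + win] @ w for s in starts], axis=1)
    centers = t_ms[starts] + (win - 1) * step_ms / 2.0

    tse = TsePower(
        power=power,
        time_ms=centers,
        band_hz=band_hz,
        electrode=electrode,
        alignment=epochs.alignment,
    )
    if baseline:
        window = STIM_BASELINE_MS if epochs.alignment == "stimulus" else RESPONSE_BASELINE_MS
        idx = tse.grid_indices(*window)
        if idx.size:
            base = tse.power[:, idx].mean(axis=1, keepdims=True)
            tse = TsePower(
                power=tse.power - base,
                time_ms=tse.time_ms,
                band_hz=band_hz,
                electrode=electrode,
                alignment=epochs.alignment,
                baselined=True,
            )
        else:
            warnings.warn(f"TSE baseline window {window} lost to trimming; skipped")
    return tse


def lhb_latency(
    tse: TsePower, search_ms: tuple[float, float] = LATENCY_SEARCH_MS
) -> float:
    """Time (ms) of the most negative-going point of the averaged trace.

    Operates on the stimulus-locked (typically baselined) TSE between 0 and
    1000 ms; ties resolve to the earliest grid point.
    """
    if tse.alignment != "stimulus":
        raise ValueError("latency is defined on the stimulus-locked TSE")
    idx = tse.grid_indices(*search_ms)
    if idx.size == 0:
        raise ValueError(f"search window {search_ms} outside TSE grid")
    trace = tse.mean_trace()[idx]
    if np.ptp(trace) == 0:
        warnings.warn("flat TSE in latency search window; returning window start")
        return float(tse.time_ms[idx[0]])
    return float(tse.time_ms[idx[np.argmin(trace)]])


def lhb_slope(tse: TsePower, window_ms: tuple[float, float] = SLOPE_WINDOW_MS) -> float:
    """OLS slope (power/ms) of the response-locked trace over -300..-50 ms."""
    if tse.alignment != "response":
        raise ValueError("slope is defined on the response-locked TSE")
    idx = tse.grid_indices(*window_ms)
    if idx.size < 2:
        raise ValueError(f"fewer than 2 grid points in window {window_ms}")
    return float(np.polyfit(tse.time_ms[idx], tse.mean_trace()[idx], 1)[0])


def lhb_amplitude(tse: TsePower, window_ms: tuple[float, float] = AMP_WINDOW_MS) -> float:
    """Mean of the response-locked trace over the 100 ms around the response."""
    if tse.alignment != "response":
        raise ValueError("amplitude is defined on the response-locked TSE")
    idx = tse.grid_indices(*window_ms)
    if idx.size == 0:
        raise ValueError(f"no grid points in window {window_ms}")
    return float(tse.mean_trace()[idx].mean())
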