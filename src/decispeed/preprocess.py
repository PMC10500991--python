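"""Filtering, epoching, baselining, and trial exclusion.

The filter chain is detrend -> notch (50/100/150 Hz) -> high-pass 0.1 Hz ->
low-pass 35 Hz, each a Hamming windowed-sinc FIR applied zero-phase by
symmetric convolution. Stimulus epochs span -200..1500 ms, baselined to
-100..0 ms; response-locked epochs are re-sliced from stimulus-locked data
at each trial's RT and baselined to -450..-350 ms pre-response. Trials are
excluded for RT <= 150 ms, RT >= 1800 ms, or any channel amplitude
exceeding (strictly) 100 µV between 100 ms before target onset and 100 ms
after the response.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from decispeed.containers import EpochSet, SubjectBehavior

STIM_WINDOW_MS = (-200.0, 1500.0)
STIM_BASELINE_MS = (-100.0, 0.0)
RESPONSE_BASELINE_MS = (-450.0, -350.0)
RT_MIN_MS = 150.0
RT_MAX_MS = 1800.0
ARTIFACT_UV = 100.0


@dataclass
class FilterSpec:
    """Design parameters of the FIR chain; transition widths in Hz."""

    notch_freqs: tuple[float, ...] = (50.0, 100.0, 150.0)
    notch_halfwidth: float = 1.0
    notch_transition: float = 1.0
    highpass: float = 0.1
    highpass_transition: float = 0.1
    lowpass: float = 35.0
    lowpass_transition: float = 8.75
    attenuation_factor: float = 3.3  # taps ~ factor * fs / transition (Hamming)

    def n_taps(self, fs: float, transition: float) -> int:
        n = int(np.ceil(self.attenuation_factor * fs / transition))
        return n + 1 if n % 2 == 0 else n


def _fir_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric (linear-phase) FIR with zero net delay.

    Edges are handled by reflect-padding half the kernel on each side so
    steady-state sinusoids keep unit passband gain up to the boundaries.
    """
    half = (taps.size - 1) // 2
    x2 = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(half, half)], mode="reflect")
    y = signal.oaconvolve(x2, taps[np.newaxis, :] if x.ndim == 2 else taps, mode="valid", axes=-1)
    return y


def filter_continuous(
    continuous: np.ndarray,
    sampling_rate: float,
    spec: FilterSpec | None = None,
) -> np.ndarray:
    """Detrend then notch/high-pass/low-pass a channels x time signal.

    Raises ``ValueError`` when the signal is shorter than the longest filter.
    """
    spec = spec or FilterSpec()
    x = np.atleast_2d(np.asarray(continuous, dtype=float))
    fs = float(sampling_rate)
    nyq = fs / 2.0

    longest = max(
        spec.n_taps(fs, spec.notch_transition),
        spec.n_taps(fs, spec.highpass_transition),
        spec.n_taps(fs, spec.lowpass_transition),
    )
    if x.shape[-1] < longest:
        raise ValueError(
            f"signal length {x.shape[-1]} shorter than filter length {longest}"
        )

    x = signal.detrend(x, axis=-1, type="linear")

    for f0 in spec.notch_freqs:
        if f0 >= nyq:
            continue
        taps = signal.firwin(
            spec.n_taps(fs, spec.notch_transition),
            [f0 - spec.notch_halfwidth, f0 + spec.notch_halfwidth],
            pass_zero="bandstop",
            window="hamming",
            fs=fs,
        )
        x = _fir_zero_phase(x, taps)

    taps = signal.firwin(
        spec.n_taps(fs, spec.highpass_transition),
        spec.highpass,
        pass_zero="highpass",
        window="hamming",
        fs=fs,
    )
    x = _fir_zero_phase(x, taps)

    taps = signal.firwin(
        spec.n_taps(fs, spec.lowpass_transition),
        spec.lowpass,
        pass_zero="lowpass",
        window="hamming",
        fs=fs,
    )
    x = _fir_zero_phase(x, taps)

    return x if np.asarray(continuous).ndim == 2 else x[0]


def extract_epochs(
    continuous: np.ndarray,
    sampling_rate: float,
    channel_labels: Sequence[str],
    events_ms: Sequence[float],
    trial_meta: pd.DataFrame,
    alignment: str = "stimulus",
    window_ms: tuple[float, float] = STIM_WINDOW_MS,
    baseline_ms: Optional[tuple[float, float]] = STIM_BASELINE_MS,
) -> tuple[EpochSet, pd.DataFrame]:
    """Cut epochs around lock events and subtract the baseline mean.

    Events whose window would exceed the recording are dropped; the returned
    log has one row per input event with a ``kept`` flag and reason.
    """
    x = np.atleast_2d(np.asarray(continuous, dtype=float))
    fs = float(sampling_rate)
    step_ms = 1000.0 / fs
    n_samples = x.shape[-1]
    pre = int(round(window_ms[0] / step_ms))
    post = int(round(window_ms[1] / step_ms))
    time_ms = np.arange(pre, post + 1) * step_ms

    epochs, kept_rows, log_rows = [], [], []
    for i, ev in enumerate(events_ms):
        center = int(round(ev / step_ms))
        lo, hi = center + pre, center + post
        if lo < 0 or hi >= n_samples:
            log_rows.append({"event_index": i, "kept": False, "reason": "edge"})
            continue
        epochs.append(x[:, lo : hi + 1])
        kept_rows.append(i)
        log_rows.append({"event_index": i, "kept": True, "reason": ""})

    data = np.stack(epochs) if epochs else np.empty((0, x.shape[0], time_ms.size))
    meta = trial_meta.iloc[kept_rows].reset_index(drop=True)
    out = EpochSet(
        data=data,
        time_ms=time_ms,
        alignment=alignment,  # type: ignore[arg-type]
        sampling_rate=fs,
        channel_labels=list(channel_labels),
        trial_meta=meta,
        baseline_window=baseline_ms,
    )
    if baseline_ms is not None and out.n_trials:
        out = apply_baseline(out, baseline_ms)
    return out, pd.DataFrame(log_rows)


def apply_baseline(epochs: EpochSet, baseline_ms: tuple[float, float]) -> EpochSet:
    """Subtract the per-trial/channel mean over the baseline window."""
    idx = epochs.time_indices(*baseline_ms)
    if idx.size == 0:
        raise ValueError(f"baseline window {baseline_ms} outside epoch")
    base = epochs.data[:, :, idx].mean(axis=2, keepdims=True)
    return dataclasses.replace(
        epochs, data=epochs.data - base, baseline_window=tuple(baseline_ms)
    )


def exclude_trials(
    epochs: EpochSet,
    artifact_uv: float = ARTIFACT_UV,
    rt_min_ms: float = RT_MIN_MS,
    rt_max_ms: float = RT_MAX_MS,
) -> tuple[EpochSet, pd.DataFrame]:
    """Flag invalid trials; returns the flagged set plus an exclusion log.

    A trial is invalid iff RT <= ``rt_min_ms``, RT >= ``rt_max_ms``, or any
    channel's absolute amplitude strictly exceeds ``artifact_uv`` inside
    [-100 ms, RT + 100 ms]. Amplitudes of exactly the threshold are kept.
    The operation is idempotent: reasons are recomputed from scratch.
    """
    if epochs.alignment != "stimulus":
        raise ValueError("trial exclusion expects stimulus-aligned epochs")
    meta = epochs.trial_meta.copy()
    reasons = []
    for i in range(epochs.n_trials):
        rt = meta.iloc[i]["rt_ms"]
        responded = bool(meta.iloc[i]["responded"])
        reason = ""
        if not responded or not np.isfinite(rt):
            reason = "no_response"
        elif rt <= rt_min_ms:
            reason = "rt_fast"
        elif rt >= rt_max_ms:
            reason = "rt_slow"
        else:
            idx = epochs.time_indices(-100.0, rt + 100.0)
            if np.any(np.abs(epochs.data[i][:, idx]) > artifact_uv):
                reason = "artifact"
        reasons.append(reason)
    meta["exclusion_reason"] = reasons
    meta["valid"] = [r == "" for r in reasons]
    flagged = dataclasses.replace(epochs, trial_meta=meta)
    log = pd.DataFrame(
        {
            "trial": np.arange(epochs.n_trials),
            "valid": meta["valid"].to_numpy(),
            "reason": reasons,
        }
    )
    return flagged, log


def response_locked(
    epochs: EpochSet,
    window_ms: tuple[float, float] = (-600.0, 300.0),
    baseline_ms: Optional[tuple[float, float]] = RESPONSE_BASELINE_MS,
    valid_only: bool = True,
) -> EpochSet:
    """Re-slice stimulus-locked epochs around each trial's response.

    Only trials whose response window fits inside the stimulus epoch are
    kept. Baselining (default -450..-350 ms pre-response) is applied after
    slicing; pass ``baseline_ms=None`` to keep the stimulus baseline.
    """
    if epochs.alignment != "stimulus":
        raise ValueError("response_locked expects stimulus-aligned epochs")
    step_ms = 1000.0 / epochs.sampling_rate
    pre = int(round(window_ms[0] / step_ms))
    post = int(round(window_ms[1] / step_ms))
    time_ms = np.arange(pre, post + 1) * step_ms

    rows, slices = [], []
    for i in range(epochs.n_trials):
        row = epochs.trial_meta.iloc[i]
        if valid_only and not bool(row["valid"]):
            continue
        rt = row["rt_ms"]
        if not np.isfinite(rt):
            continue
        center = int(round((rt - epochs.time_ms[0]) / step_ms))
        lo, hi = center + pre, center + post
        if lo < 0 or hi >= epochs.time_ms.size:
            continue
        slices.append(epochs.data[i][:, lo : hi + 1])
        rows.append(i)

    data = (
        np.stack(slices)
        if slices
        else np.empty((0, len(epochs.channel_labels), time_ms.size))
    )
    out = EpochSet(
        data=data,
        time_ms=time_ms,
        alignment="response",
        sampling_rate=epochs.sampling_rate,
        channel_labels=list(epochs.channel_labels),
        trial_meta=epochs.trial_meta.iloc[rows].reset_index(drop=True),
        baseline_window=baseline_ms,
        csd_transformed=epochs.csd_transformed,
    )
    if baseline_ms is not None and out.n_trials:
        out = apply_baseline(out, baseline_ms)
    return out


def iqr_outlier_flags(values: Sequence[float], k: float = 3.0) -> np.ndarray:
    """True where a value falls outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear-interpolation (type-7) quantiles. Requires at least
    four values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for IQR outlier detection")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    return (v < q1 - k * iqr) | (v > q3 + k * iqr)
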