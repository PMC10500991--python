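"""Target-selection (N2c) and evidence-accumulation (CPP) scalar metrics.

The N2c is averaged contralateral to the target hemifield at P7/P8; its
latency is the most negative point between 150 and 400 ms post-stimulus and
its amplitude the mean in a 100 ms window centered on the cohort grand
average peak. The CPP is measured at Pz: onset from running one-sample
t tests of a 25 ms sliding window against zero (first point significant at
0.05 for 90 consecutive samples), build-up rate as the OLS slope of the
response-locked average over -150..+50 ms, and amplitude as the mean over
-50..+50 ms around the response.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import stats

from decispeed.containers import EpochSet, Waveform

N2C_SEARCH_MS = (150.0, 400.0)
N2C_MEAN_HALFWIDTH_MS = 50.0
CPP_SLOPE_WINDOW_MS = (-150.0, 50.0)
CPP_AMP_WINDOW_MS = (-50.0, 50.0)
ONSET_T_WINDOW_MS = 25.0
ONSET_RUN_SAMPLES = 90
ONSET_ALPHA = 0.05
ONSET_SEARCH_MS = (0.0, 1000.0)


def n2c_waveform(epochs: EpochSet) -> Waveform:
    """Average contralateral to the target: P8 for left-field, P7 for right.

    The two hemifield averages are computed separately then averaged with
    equal weight (average of averages), so unbalanced trial counts do not
    bias the collapsed trace toward one hemifield.
    """
    if epochs.alignment != "stimulus":
        raise ValueError("N2c requires stimulus-aligned epochs")
    mask = epochs.valid_mask()
    hemi = epochs.trial_meta["hemifield"].to_numpy()
    p7 = epochs.channel_data("P7")
    p8 = epochs.channel_data("P8")
    left = mask & (hemi == "left")
    right = mask & (hemi == "right")
    parts = []
    n_used = 0
    if left.any():
        parts.append(p8[left].mean(axis=0))
        n_used += int(left.sum())
    if right.any():
        parts.append(p7[right].mean(axis=0))
        n_used += int(right.sum())
    if not parts:
        raise ValueError("no valid trials for N2c averaging")
    amplitude = np.mean(parts, axis=0)
    return Waveform(
        amplitude=amplitude,
        time_ms=epochs.time_ms,
        alignment="stimulus",
        electrode="P7/P8 (contralateral)",
        n_trials=n_used,
    )


def n2c_latency(wave: Waveform, search_ms: tuple[float, float] = N2C_SEARCH_MS) -> float:
    """Time (ms) of the most negative amplitude in the search window.

    Ties take the earliest sample; a flat segment warns and returns the
    earliest sample of the window.
    """
    if wave.alignment != "stimulus":
        raise ValueError("N2c latency requires a stimulus-aligned waveform")
    t, a = wave.window(*search_ms)
    if t.size == 0:
        raise ValueError(f"search window {search_ms} outside waveform")
    if np.ptp(a) == 0:
        warnings.warn("flat waveform in N2c search window; returning window start")
        return float(t[0])
    return float(t[np.argmin(a)])


def n2c_amplitude(
    wave: Waveform, grand_peak_ms: float, halfwidth_ms: float = N2C_MEAN_HALFWIDTH_MS
) -> float:
    """Mean amplitude in a 100 ms window centered on the grand-average peak.

    ``grand_peak_ms`` is computed once per cohort (see
    :func:`grand_average_peak`). Windows reaching past the epoch edge are
    truncated with a warning.
    """
    lo, hi = grand_peak_ms - halfwidth_ms, grand_peak_ms + halfwidth_ms
    if lo < wave.time_ms[0] or hi > wave.time_ms[-1]:
        warnings.warn("N2c amplitude window truncated at epoch edge")
    _, a = wave.window(lo, hi)
    if a.size == 0:
        raise ValueError("N2c amplitude window outside epoch")
    return float(a.mean())


def grand_average_peak(
    waves: list[Waveform], search_ms: tuple[float, float] = N2C_SEARCH_MS
) -> float:
    """Latency of the cohort grand-average N2c trough (trial-count weighted)."""
    if not waves:
        raise ValueError("no waveforms provided")
    weights = np.array([w.n_trials for w in waves], dtype=float)
    stack = np.stack([w.amplitude for w in waves])
    grand = Waveform(
        amplitude=np.average(stack, axis=0, weights=weights),
        time_ms=waves[0].time_ms,
        alignment="stimulus",
        electrode=waves[0].electrode,
        n_trials=int(weights.sum()),
    )
    return n2c_latency(grand, search_ms)


def _running_ttest_pvalues(
    trials_by_time: np.ndarray, time_ms: np.ndarray, sampling_rate: float,
    window_ms: float = ONSET_T_WINDOW_MS,
) -> np.ndarray:
    """Two-sided one-sample t-test p-value per sample of the windowed means.

    Each sample's statistic is computed across trials on the mean of a
    centered window of ~``window_ms``. Zero-variance columns get p = 0 when
    the mean is nonzero and p = 1 when it is exactly zero (the degenerate
    noiseless case).
    """
    step_ms = 1000.0 / sampling_rate
    half = max(int(round(window_ms / 2.0 / step_ms)), 1)
    n_t = time_ms.size
    # windowed mean per trial; edges shrink to the available samples
    sums = np.apply_along_axis(
        lambda r: np.convolve(r, np.ones(2 * half + 1), mode="same"), 1, trials_by_time
    )
    counts = np.convolve(np.ones(n_t), np.ones(2 * half + 1), mode="same")
    win_means = sums / counts
    mean = win_means.mean(axis=0)
    sd = win_means.std(axis=0, ddof=1)
    n = trials_by_time.shape[0]
    p = np.ones(n_t)
    nz = sd > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = mean[nz] / (sd[nz] / np.sqrt(n))
        p[nz] = 2.0 * stats.t.sf(np.abs(tstat), df=n - 1)
    degenerate = ~nz & (np.abs(mean) > 0)
    p[degenerate] = 0.0
    return p


def cpp_onset(
    epochs: EpochSet,
    electrode: str = "Pz",
    search_ms: tuple[float, float] = ONSET_SEARCH_MS,
    run_samples: int = ONSET_RUN_SAMPLES,
    alpha: float = ONSET_ALPHA,
) -> Optional[float]:
    """Onset (ms) of the accumulation trace, or ``None`` when undetected.

    Runs sample-point-by-sample-point t tests against zero on 25 ms sliding
    window means across trials; onset is the first sample whose p-value
    stays below ``alpha`` for ``run_samples`` consecutive samples.
    """
    if epochs.alignment != "stimulus":
        raise ValueError("onset detection requires stimulus-aligned epochs")
    x = epochs.channel_data(electrode)[epochs.valid_mask()]
    if x.shape[0] < 10:
        raise ValueError(f"need >= 10 valid trials, got {x.shape[0]}")
    p = _running_ttest_pvalues(x, epochs.time_ms, epochs.sampling_rate)
    idx = epochs.time_indices(*search_ms)
    sig = p[idx] < alpha
    run = 0
    for j, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= run_samples:
            return float(epochs.time_ms[idx[j - run_samples + 1]])
    # allow a run that starts inside the window and completes after it
    tail = p[idx[-1] + 1 :] < alpha if idx[-1] + 1 < p.size else np.array([], bool)
    run = 0
    start: Optional[int] = None
    for j, s in enumerate(np.concatenate([sig, tail])):
        if s:
            if start is None:
                start = j
            run += 1
            if run >= run_samples and start < sig.size:
                return float(epochs.time_ms[idx[0] + start])
        else:
            run, start = 0, None
    return None


def _mean_response_wave(epochs: EpochSet, electrode: str) -> Waveform:
    if epochs.alignment != "response":
        raise ValueError("expected response-aligned epochs")
    x = epochs.channel_data(electrode)[epochs.valid_mask()]
    if x.shape[0] == 0:
        raise ValueError("no valid trials")
    return Waveform(
        amplitude=x.mean(axis=0),
        time_ms=epochs.time_ms,
        alignment="response",
        electrode=electrode,
        n_trials=x.shape[0],
    )


def cpp_slope(
    epochs: EpochSet,
    electrode: str = "Pz",
    window_ms: tuple[float, float] = CPP_SLOPE_WINDOW_MS,
) -> float:
    """OLS slope (µV/ms) of the response-locked average over -150..+50 ms."""
    wave = _mean_response_wave(epochs, electrode)
    t, a = wave.window(*window_ms)
    if t.size < 3:
        raise ValueError(f"fewer than 3 samples in slope window {window_ms}")
    return float(np.polyfit(t, a, 1)[0])


def cpp_amplitude(
    epochs: EpochSet,
    electrode: str = "Pz",
    window_ms: tuple[float, float] = CPP_AMP_WINDOW_MS,
) -> float:
    """Mean amplitude (µV) of the response-locked average over -50..+50 ms."""
    wave = _mean_response_wave(epochs, electrode)
    t, a = wave.window(*window_ms)
    if t.size < 3:
        raise ValueError(f"fewer than 3 samples in amplitude window {window_ms}")
    return float(a.mean())
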