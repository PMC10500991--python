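"""Minimum-trial subsampling reliability and the task-time budget calculator.

For each subject and each bin size N, draw N trials without replacement
from a fixed pool, recompute mean RT and the build-up-rate slope on the
subsampled response-locked average, and repeat the draw many times. SNR is
mean/SD of an estimate over draws; the cross-subject Pearson correlation
between slope and mean RT is computed per draw and summarized per bin with
a one-sample JZS Bayes factor against a threshold effect size.

The task-time budget inflates a required count of valid trials first for
behavioral misses, then for EEG cleaning rejections (nearest-integer
rounding at each step), and converts presented trials into coherent- and
random-motion screen time.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from decispeed.cohort_stats import bf10_from_t
from decispeed.containers import EpochSet

DEFAULT_BIN_SIZES = (20, 40, 60, 80, 100, 120)
DEFAULT_POOL_SIZE = 129
EFFECT_THRESHOLD = -0.55


@dataclass
class SubsamplingResult:
    bin_sizes: tuple[int, ...]
    subjects: list[str]
    #: subject x bin x permutation arrays
    rt_estimates: np.ndarray
    slope_estimates: np.ndarray
    #: subject x bin SNR (mean/SD over permutations); NaN where SD == 0
    rt_snr: np.ndarray
    slope_snr: np.ndarray
    #: bin x permutation cross-subject Pearson r(slope, RT)
    r_by_bin: np.ndarray
    skipped: list[str] = field(default_factory=list)

    def snr_table(self) -> pd.DataFrame:
        rows = []
        for bi, n in enumerate(self.bin_sizes):
            rows.append(
                {
                    "bin_size": n,
                    "rt_snr_mean": float(np.nanmean(self.rt_snr[:, bi])),
                    "slope_snr_mean": float(np.nanmean(self.slope_snr[:, bi])),
                    "r_mean": float(np.mean(self.r_by_bin[bi])),
                    "r_sd": float(np.std(self.r_by_bin[bi], ddof=1)),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class TaskTimingPlan:
    required_valid: int
    accuracy: float
    rejection_fraction: float
    post_accuracy_trials: int
    presented_trials: int
    coherent_seconds: float
    random_seconds: float
    total_seconds: float


def _slope_vector(epochs: EpochSet, electrode: str, window_ms: tuple[float, float]) -> np.ndarray:
    """Per-trial OLS slope over the window; slope of a mean trace equals the
    mean of these per-trial slopes, which makes subsampled slopes cheap."""
    idx = epochs.time_indices(*window_ms)
    t = epochs.time_ms[idx]
    x = epochs.channel_data(electrode)[:, idx]
    tc = t - t.mean()
    return (x @ tc) / (tc @ tc)


def subsample_estimates(
    epochs_by_subject: dict[str, EpochSet],
    bin_sizes: Sequence[int] = DEFAULT_BIN_SIZES,
    n_perm: int = 1000,
    pool_size: int = DEFAULT_POOL_SIZE,
    seed: Optional[int] = None,
    electrode: str = "Pz",
    slope_window_ms: tuple[float, float] = (-150.0, 50.0),
) -> SubsamplingResult:
    """Subsample response-locked trials and re-estimate RT and slope.

    ``epochs_by_subject`` maps subject id to a *response-aligned* EpochSet
    whose trial metadata carries ``rt_ms``. Subjects with fewer than
    ``pool_size`` valid trials are skipped and logged. Each permutation
    draws exactly N distinct trials from the first ``pool_size`` valid
    trials; draws are independent across permutations.
    """
    bin_sizes = tuple(int(b) for b in bin_sizes)
    if max(bin_sizes) > pool_size:
        raise ValueError("bin sizes cannot exceed the pool size")
    rng = np.random.default_rng(seed)

    kept: list[str] = []
    skipped: list[str] = []
    rts_pool: list[np.ndarray] = []
    slopes_pool: list[np.ndarray] = []
    for sid, ep in epochs_by_subject.items():
        if ep.alignment != "response":
            raise ValueError(f"subject {sid}: epochs must be response-aligned")
        valid = ep.valid_mask()
        if valid.sum() < pool_size:
            skipped.append(sid)
            continue
        ep_v = ep.select_trials(valid)
        take = np.arange(pool_size)
        rts_pool.append(ep_v.trial_meta["rt_ms"].to_numpy(float)[take])
        slopes_pool.append(_slope_vector(ep_v, electrode, slope_window_ms)[take])
        kept.append(sid)
    if len(kept) < 3:
        raise ValueError(f"need at least 3 subjects with {pool_size} trials; have {len(kept)}")

    n_sub = len(kept)
    n_bins = len(bin_sizes)
    rt_est = np.empty((n_sub, n_bins, n_perm))
    sl_est = np.empty((n_sub, n_bins, n_perm))
    for si in range(n_sub):
        rts = rts_pool[si]
        slopes = slopes_pool[si]
        for bi, nb in enumerate(bin_sizes):
            # vectorized sampling without replacement: argsort of uniforms
            order = np.argsort(rng.random((n_perm, pool_size)), axis=1)[:, :nb]
            rt_est[si, bi] = rts[order].mean(axis=1)
            sl_est[si, bi] = slopes[order].mean(axis=1)

    def snr(est: np.ndarray) -> np.ndarray:
        sd = est.std(axis=2, ddof=1)
        mean = est.mean(axis=2)
        # SD indistinguishable from 0 (pool-exhausted bins) -> SNR undefined
        degenerate = sd <= 1e-9 * np.maximum(np.abs(mean), 1e-30)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(~degenerate, np.abs(mean) / sd, np.nan)
        return out

    # cross-subject correlation per bin and permutation
    r_by_bin = np.empty((n_bins, n_perm))
    for bi in range(n_bins):
        a = sl_est[:, bi, :]
        b = rt_est[:, bi, :]
        az = a - a.mean(axis=0)
        bz = b - b.mean(axis=0)
        r_by_bin[bi] = (az * bz).sum(axis=0) / np.sqrt(
            (az**2).sum(axis=0) * (bz**2).sum(axis=0)
        )

    return SubsamplingResult(
        bin_sizes=bin_sizes,
        subjects=kept,
        rt_estimates=rt_est,
        slope_estimates=sl_est,
        rt_snr=snr(rt_est),
        slope_snr=snr(sl_est),
        r_by_bin=r_by_bin,
        skipped=skipped,
    )


def distribution_shift_tests(result: SubsamplingResult) -> pd.DataFrame:
    """Two-sample KS tests between estimate distributions of adjacent bins,
    plus a linear-contrast trend on SNR across bins (per measure)."""
    rows = []
    for bi in range(len(result.bin_sizes) - 1):
        for name, est in (("rt", result.rt_estimates), ("slope", result.slope_estimates)):
            x = est[:, bi, :].ravel()
            y = est[:, bi + 1, :].ravel()
            ks = stats.ks_2samp(x, y)
            rows.append(
                {
                    "measure": name,
                    "bin_a": result.bin_sizes[bi],
                    "bin_b": result.bin_sizes[bi + 1],
                    "ks_stat": float(ks.statistic),
                    "ks_p": float(ks.pvalue),
                }
            )
    out = pd.DataFrame(rows)
    for name, snr in (("rt", result.rt_snr), ("slope", result.slope_snr)):
        contrast = np.arange(len(result.bin_sizes), dtype=float)
        contrast -= contrast.mean()
        ok = ~np.isnan(snr).any(axis=1)
        scores = snr[ok] @ contrast
        t, p = stats.ttest_1samp(scores, 0.0)
        out.attrs[f"trend_t_{name}"] = float(t)
        out.attrs[f"trend_p_{name}"] = float(p)
    return out


def effect_size_by_bin(
    result: SubsamplingResult,
    threshold: float = EFFECT_THRESHOLD,
    direction: str = "two-sided",
) -> pd.DataFrame:
    """Per bin: mean/SD of the permutation r values and the JZS BF10 for the
    r distribution against the threshold effect size."""
    rows = []
    for bi, n in enumerate(result.bin_sizes):
        r = result.r_by_bin[bi]
        t_obs = (r.mean() - threshold) / (r.std(ddof=1) / np.sqrt(r.size))
        bf = bf10_from_t(float(t_obs), float(r.size), r.size - 1, direction=direction)
        rows.append(
            {
                "bin_size": n,
                "r_mean": float(r.mean()),
                "r_sd": float(r.std(ddof=1)),
                "bf10_vs_threshold": bf,
            }
        )
    return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def task_time_budget(
    required_valid: int = 40,
    accuracy: float = 0.96,
    rejection_fraction: float = 0.15,
    coherent_s: float = 3.0,
    itis: Sequence[float] = (1.8, 2.8, 3.8),
) -> TaskTimingPlan:
    """Presented-trial counts and screen time needed for N valid trials.

    Inflate first for behavioral misses (x (1 + (1 - accuracy))), then for
    EEG cleaning rejections (x (1 + rejection_fraction)), rounding to the
    nearest integer at each step. Presented targets are split equally across
    the random-motion intervals, any remainder assigned to the shortest
    intervals first.
    """
    if not (0 < accuracy <= 1):
        raise ValueError("accuracy must be in (0, 1]")
    if not (0 <= rejection_fraction < 1):
        raise ValueError("rejection_fraction must be in [0, 1)")
    post_acc = _round_half_up(required_valid * (1.0 + (1.0 - accuracy)))
    presented = _round_half_up(post_acc * (1.0 + rejection_fraction))
    coherent = presented * coherent_s
    itis = sorted(itis)
    per = presented // len(itis)
    rem = presented % len(itis)
    counts = [per + (1 if i < rem else 0) for i in range(len(itis))]
    random_s = float(sum(c * d for c, d in zip(counts, itis)))
    return TaskTimingPlan(
        required_valid=required_valid,
        accuracy=accuracy,
        rejection_fraction=rejection_fraction,
        post_accuracy_trials=post_acc,
        presented_trials=presented,
        coherent_seconds=coherent,
        random_seconds=random_s,
        total_seconds=coherent + random_s,
    )


def enumerate_trial_types(
    itis: Sequence[float] = (1.8, 2.8, 3.8),
    locations: Sequence[str] = ("left", "right"),
    directions: Sequence[str] = ("up", "down"),
) -> tuple[int, list[tuple]]:
    """Cartesian product of interval x location x direction."""
    types = list(itertools.product(itis, locations, directions))
    return len(types), types
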