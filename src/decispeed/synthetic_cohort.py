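"""Synthetic cohort generator with the statistical structure the analysis assumes.

Subjects carry true diffusion parameters (a, v, t0), planted EEG component
parameters, and enrichment scores. Subject mean RT follows the
between-subject moderation equation

    RT_mean = i1 + b1*slope + b2*EE + b3*slope*EE + noise,

and per-trial RTs are drawn from the same one-boundary diffusion that the
fitting stage assumes (shifted-Wald first-passage law, or an
Euler–Maruyama path simulation in oracle mode), with misses past the
deadline. Epochs plant a linear CPP ramp at Pz, a contralateral Gaussian
N2c at P7/P8, and a 25 Hz beta carrier at C3 with a V-shaped
desynchronization envelope bottoming at the response.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from decispeed.containers import EpochSet, NeuralMetrics, SubjectBehavior
from decispeed.ddm_gsquare import simulate_ddm

EPOCH_WINDOW_MS = (-200.0, 1500.0)
N2C_SIGMA_MS = 42.0  # Gaussian bump width (~100 ms FWHM)
CPP_FALL_MS = 300.0
CPP_PEAK_DELAY_MS = 50.0  # ramp keeps rising to the end of the slope window
LHB_FALL_MS = 400.0
LHB_CARRIER_HZ = 25.0


@dataclass
class SubjectParams:
    """Ground-truth generative parameters for one subject."""

    subject_id: str
    group: str  # "older" | "younger"
    age: float
    v: float
    a: float
    t0: float
    cpp_slope_true: float  # µV/ms
    cpp_onset_true: float  # ms post-stimulus
    n2c_latency_true: float  # ms
    n2c_amp_true: float  # µV (negative)
    lhb_depth_true: float  # µV envelope depth
    cri_leisure: float
    cri_education: float
    cri_occupation: float
    noise_sd: float
    mean_rt_target: float = np.nan  # ms, implied by the moderation equation

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("bound a must be positive")
        if self.t0 < 0:
            raise ValueError("t0 must be non-negative")
        if self.v <= 0:
            raise ValueError("drift v must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.cpp_onset_true < 1800):
            raise ValueError("cpp_onset_true must lie in [0, 1800) ms")

    @property
    def cri_composite(self) -> float:
        return (self.cri_leisure + self.cri_education + self.cri_occupation) / 3.0


@dataclass
class CohortConfig:
    """Cohort-level generator settings."""

    n_older: int = 41
    n_younger: int = 31
    trials_per_subject: int = 120
    sampling_rate: float = 500.0
    channels: tuple[str, ...] = ("Pz", "C3", "P7", "P8")
    iti_set: tuple[float, ...] = (1.8, 2.8, 3.8)
    target_duration_s: float = 3.0
    deadline_ms: float = 1800.0
    # (i1, b1, b2, b3): RT_mean = i1 + b1*slope + b2*EE + b3*slope*EE
    moderation_coeffs: tuple[float, float, float, float] = (
        1259.45,
        -5420.91,
        -4.34,
        32.00,
    )
    rt_noise_sd: float = 90.0
    noise_sd: float = 0.0  # per-sample EEG noise, µV
    pink_noise: bool = False
    lhb_baseline_uv: float = 4.0
    behavior_method: str = "wald"  # or "euler" (path-simulation oracle)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_older, self.n_younger, self.trials_per_subject) <= 0:
            raise ValueError("counts must be positive")
        if self.trials_per_subject % 12 != 0:
            raise ValueError(
                "trials_per_subject must be divisible by 12 (balanced design)"
            )
        required = {"Pz", "C3", "P7", "P8"}
        if not required.issubset(set(self.channels)):
            raise ValueError(f"channels must include {sorted(required)}")


def _subject_rng(config: CohortConfig, subject_id: str) -> np.random.Generator:
    tag = zlib.crc32(subject_id.encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def draw_cohort(config: CohortConfig) -> list[SubjectParams]:
    """Draw subject-level parameters; reproducible under ``config.seed``.

    Older subjects get shallower CPP build-up rates and, through the
    moderation equation tying mean RT to slope and enrichment, lower drifts.
    The drift is back-solved from the target mean RT via the Wald mean
    ``E[RT] = t0 + a/v``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _COHORT_STREAM]))
    i1, b1, b2, b3 = config.moderation_coeffs
    subjects: list[SubjectParams] = []
    specs = [("older", config.n_older), ("younger", config.n_younger)]
    for group, n in specs:
        for k in range(n):
            sid = f"{group[0]}{k:03d}"
            if group == "older":
                age = float(np.clip(rng.normal(72.4, 5.6), 63, 90))
                slope = float(np.clip(rng.normal(0.0724, 0.0690), 0.005, 0.30))
                n2c_lat = float(np.clip(rng.normal(300.0, 45.0), 160.0, 390.0))
            else:
                age = float(np.clip(rng.normal(23.7, 2.9), 18, 30))
                slope = float(np.clip(rng.normal(0.1100, 0.0500), 0.010, 0.35))
                n2c_lat = float(np.clip(rng.normal(275.0, 45.0), 160.0, 390.0))
            leisure = float(np.clip(rng.normal(135.0, 22.0), 70.0, 220.0))
            education = float(np.clip(rng.normal(115.0, 15.0), 70.0, 180.0))
            occupation = float(np.clip(rng.normal(118.0, 18.0), 70.0, 190.0))

            rt_target = (
                i1
                + b1 * slope
                + b2 * leisure
                + b3 * slope * leisure
                + rng.normal(0.0, config.rt_noise_sd)
            )
            if group == "younger":
                # the moderation equation describes the older cohort; younger
                # subjects respond ~150 ms faster at matched slope/enrichment
                rt_target -= 150.0
            rt_target = float(np.clip(rt_target, 250.0, config.deadline_ms - 200.0))
            # accumulation must begin well before the typical response, so the
            # planted onset is a fraction of the subject's target mean RT
            onset = float(np.clip(rng.uniform(0.40, 0.55) * rt_target, 100.0, 800.0))

            a = float(np.clip(rng.normal(2.77 if group == "older" else 1.98, 0.6), 0.8, 6.0))
            t0 = float(np.clip(rng.normal(0.11 if group == "older" else 0.10, 0.03), 0.02, 0.25))
            decision_s = max(rt_target / 1000.0 - t0, 0.1)
            v = a / decision_s

            subjects.append(
                SubjectParams(
                    subject_id=sid,
                    group=group,
                    age=age,
                    v=v,
                    a=a,
                    t0=t0,
                    cpp_slope_true=slope,
                    cpp_onset_true=onset,
                    n2c_latency_true=n2c_lat,
                    n2c_amp_true=float(np.clip(rng.normal(-3.0, 0.8), -6.0, -1.0)),
                    lhb_depth_true=float(np.clip(rng.normal(2.0, 0.4), 0.8, 3.5)),
                    cri_leisure=leisure,
                    cri_education=education,
                    cri_occupation=occupation,
                    noise_sd=config.noise_sd,
                    mean_rt_target=rt_target,
                )
            )
    return subjects


# stream tag keeping cohort-level draws distinct from per-subject streams
_COHORT_STREAM = 7919


def simulate_behavior(subject: SubjectParams, config: CohortConfig) -> SubjectBehavior:
    """Per-trial RTs from the one-boundary diffusion, balanced over trial types.

    Trial types are the Cartesian product ITI x hemifield x direction, each
    occurring ``trials_per_subject / 12`` times in pseudorandom order. RTs
    are first-passage times of the subject's diffusion; no crossing before
    the deadline is a miss.
    """
    rng = _subject_rng(config, subject.subject_id)
    n = config.trials_per_subject
    types = [
        (iti, hemi, direction)
        for iti in config.iti_set
        for hemi in ("left", "right")
        for direction in ("up", "down")
    ]
    reps = n // len(types)
    schedule = types * reps
    order = rng.permutation(n)
    schedule = [schedule[i] for i in order]

    beh = simulate_ddm(
        subject.a,
        subject.v,
        subject.t0,
        n,
        deadline_ms=config.deadline_ms,
        seed=rng,
        method=config.behavior_method,
    )
    trials = beh.trials
    trials["iti_s"] = [s[0] for s in schedule]
    trials["hemifield"] = [s[1] for s in schedule]
    trials["direction"] = [s[2] for s in schedule]
    return SubjectBehavior(trials=trials, subject_id=subject.subject_id)


def _cpp_trace(t_ms: np.ndarray, onset: float, slope: float, rt: float) -> np.ndarray:
    """Zero, then ramp at ``slope`` to RT + peak delay, then linear fall."""
    peak_t = rt + CPP_PEAK_DELAY_MS
    peak_v = slope * (peak_t - onset)
    ramp = np.clip(slope * (t_ms - onset), 0.0, None)
    fall = peak_v * np.clip(1.0 - (t_ms - peak_t) / CPP_FALL_MS, 0.0, 1.0)
    return np.where(t_ms <= peak_t, np.where(t_ms >= onset, ramp, 0.0), fall)


def _lhb_envelope(t_ms: np.ndarray, rt: float, base: float, depth: float) -> np.ndarray:
    """V-shaped envelope: baseline, dipping linearly to base - depth at RT."""
    return base - depth * np.clip(1.0 - np.abs(t_ms - rt) / LHB_FALL_MS, 0.0, 1.0)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    pink *= sd / pink.std()
    return pink


def synthesize_epochs(
    subject: SubjectParams, behavior: SubjectBehavior, config: CohortConfig
) -> EpochSet:
    """Stimulus-locked epochs (-200..1500 ms) for every responded trial.

    Pz carries the CPP ramp, P7/P8 the contralateral N2c bump (P8 for
    left-hemifield targets), C3 the beta carrier whose envelope bottoms out
    at the response. Gaussian (or pink) noise of ``subject.noise_sd`` is
    added per sample and channel.
    """
    rng = _subject_rng(config, subject.subject_id + ":eeg")
    step_ms = 1000.0 / config.sampling_rate
    t_ms = np.arange(
        round(EPOCH_WINDOW_MS[0] / step_ms), round(EPOCH_WINDOW_MS[1] / step_ms) + 1
    ) * step_ms

    responded = behavior.trials["responded"].astype(bool).to_numpy()
    rows = behavior.trials.loc[responded].reset_index(drop=True)
    n_trials = len(rows)
    channels = list(config.channels)
    data = np.zeros((n_trials, len(channels), t_ms.size))

    i_pz = channels.index("Pz")
    i_c3 = channels.index("C3")
    i_p7 = channels.index("P7")
    i_p8 = channels.index("P8")

    for i in range(n_trials):
        rt = float(rows.loc[i, "rt_ms"])
        hemi = rows.loc[i, "hemifield"]
        data[i, i_pz] = _cpp_trace(
            t_ms, subject.cpp_onset_true, subject.cpp_slope_true, rt
        )
        bump = subject.n2c_amp_true * np.exp(
            -((t_ms - subject.n2c_latency_true) ** 2) / (2.0 * N2C_SIGMA_MS**2)
        )
        data[i, i_p8 if hemi == "left" else i_p7] += bump
        carrier = np.sin(2.0 * np.pi * LHB_CARRIER_HZ * (t_ms - rt) / 1000.0)
        data[i, i_c3] = (
            _lhb_envelope(t_ms, rt, config.lhb_baseline_uv, subject.lhb_depth_true)
            * carrier
        )

    if subject.noise_sd > 0:
        if config.pink_noise:
            data += _pink_noise(rng, data.shape, subject.noise_sd)
        else:
            data += rng.normal(0.0, subject.noise_sd, size=data.shape)

    meta = rows.copy()
    meta["valid"] = True
    meta["exclusion_reason"] = ""
    return EpochSet(
        data=data,
        time_ms=t_ms,
        alignment="stimulus",
        sampling_rate=config.sampling_rate,
        channel_labels=channels,
        trial_meta=meta,
    )


def expected_metrics(
    subject: SubjectParams, behavior: SubjectBehavior, config: CohortConfig
) -> NeuralMetrics:
    """Analytic metric values implied by the planted components.

    Computed from the generator's closed forms (not by running the
    extraction pipeline), so noiseless round-trip tests have an independent
    target. LHB expectations account for the discrete rectified-carrier
    mean and the 100 ms boxcar smoothing of the V-shaped envelope.
    """
    step_ms = 1000.0 / config.sampling_rate
    rts = behavior.rts
    mean_rt = float(np.mean(rts))

    # N2c amplitude: discrete mean of the Gaussian bump over +/-50 ms around
    # the (grid-snapped) planted latency
    lat = round(subject.n2c_latency_true / step_ms) * step_ms
    offs = np.arange(-50.0, 50.0 + step_ms, step_ms)
    bump = subject.n2c_amp_true * np.exp(
        -((lat + offs - subject.n2c_latency_true) ** 2) / (2.0 * N2C_SIGMA_MS**2)
    )

    # discrete rectified-carrier mean under the trapezoid smoothing weights
    win = int(round(100.0 / step_ms))
    win += 1 - win % 2
    weights = np.ones(win)
    weights[0] = weights[-1] = 0.5
    weights /= weights.sum()
    phase = np.arange(win) * step_ms
    rect_factor = float(
        weights @ np.abs(np.sin(2.0 * np.pi * LHB_CARRIER_HZ * phase / 1000.0))
    )

    # smoothed envelope values on the 50 ms response-locked grid
    half = (win - 1) // 2
    def smoothed_env(center_ms: float) -> float:
        tt = center_ms + np.arange(-half, half + 1) * step_ms
        env = _lhb_envelope(tt + mean_rt, mean_rt, config.lhb_baseline_uv, subject.lhb_depth_true)
        return float(weights @ env)

    amp_grid = [smoothed_env(c) for c in (-50.0, 0.0, 50.0)]
    slope_grid_t = np.arange(-300.0, -50.0 + 1e-9, 50.0)
    slope_grid = np.array([smoothed_env(c) for c in slope_grid_t])
    lhb_slope_exp = float(np.polyfit(slope_grid_t, rect_factor * slope_grid, 1)[0])
    # response-locked TSE is baselined to -450..-350 ms (grid centers -450/-400/-350)
    baseline_env = float(np.mean([smoothed_env(c) for c in (-450.0, -400.0, -350.0)]))

    return NeuralMetrics(
        n2c_latency=lat,
        n2c_amplitude=float(bump.mean()),
        cpp_onset=subject.cpp_onset_true,
        cpp_slope=subject.cpp_slope_true,
        cpp_amplitude=subject.cpp_slope_true * (mean_rt - subject.cpp_onset_true),
        lhb_latency=round(mean_rt / 50.0) * 50.0,
        lhb_slope=lhb_slope_exp,
        lhb_amplitude=rect_factor * (float(np.mean(amp_grid)) - baseline_env),
    )


def subject_table(subjects: list[SubjectParams]) -> pd.DataFrame:
    """TSV-ready table of subject-level parameters."""
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "cri_composite": s.cri_composite,
                "cri_leisure": s.cri_leisure,
                "cri_education": s.cri_education,
                "cri_occupation": s.cri_occupation,
                "true_a": s.a,
                "true_v": s.v,
                "true_t0": s.t0,
                "true_cpp_slope": s.cpp_slope_true,
                "true_cpp_onset": s.cpp_onset_true,
                "mean_rt_target": s.mean_rt_target,
            }
        )
    return pd.DataFrame(rows)
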