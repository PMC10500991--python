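"""Pipeline orchestration: stage graph, configuration, and format glue.

Stages (``simulate -> preprocess -> metrics -> ddm -> stats``) communicate
through files in a run directory: subject/behavior tables as TSV, epochs as
HDF5 with a JSON sidecar, statistical results as JSON. Every table and
JSON result embeds the hash of the run configuration, and re-running a
stage from persisted intermediates reproduces downstream outputs exactly
(no timestamps enter result files; they live in the run log only).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from decispeed import cohort_stats, ddm_gsquare, erp_metrics, lhb_metrics, preprocess
from decispeed.containers import EpochSet, NeuralMetrics, SubjectBehavior, metrics_table
from decispeed.synthetic_cohort import (
    CohortConfig,
    SubjectParams,
    draw_cohort,
    simulate_behavior,
    subject_table,
    synthesize_epochs,
)

logger = logging.getLogger("decispeed")

STAGE_ORDER = ["simulate", "preprocess", "metrics", "ddm", "stats"]

#: response-locked windows: ERP scalars need -150..+50; the beta TSE needs
#: margin for the 200 ms trims and the -450..-350 ms baseline
ERP_RESPONSE_WINDOW_MS = (-400.0, 200.0)
BETA_RESPONSE_WINDOW_MS = (-700.0, 300.0)


@dataclass
class RunConfig:
    """Validated run configuration; round-trips losslessly through YAML."""

    stages: list[str]
    out_dir: str
    cohort: CohortConfig = field(default_factory=CohortConfig)
    deadline_ms: float = 1800.0
    n_boot: int = 5000
    bootstrap_seed: Optional[int] = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = sorted(self.stages, key=STAGE_ORDER.index)
        if "stats" in self.stages and self.bootstrap_seed is None:
            raise ValueError("stats stage requires an explicit bootstrap_seed")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["cohort"]["channels"] = list(self.cohort.channels)
        d["cohort"]["iti_set"] = list(self.cohort.iti_set)
        d["cohort"]["moderation_coeffs"] = list(self.cohort.moderation_coeffs)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            for key in ("channels", "iti_set", "moderation_coeffs"):
                if key in cohort:
                    cohort[key] = tuple(cohort[key])
            cohort = CohortConfig(**cohort)
        return cls(cohort=cohort, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths and stage list excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("stages", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as f:
        f.write(f"# config_hash: {config_hash}\n")
        df.to_csv(f, sep="\t", index=False)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _epoch_path(out: Path, sid: str) -> Path:
    return out / "epochs" / f"{sid}.h5"


def stage_simulate(config: RunConfig, out: Path) -> None:
    subjects = draw_cohort(config.cohort)
    (out / "epochs").mkdir(parents=True, exist_ok=True)
    behaviors = []
    for s in subjects:
        beh = simulate_behavior(s, config.cohort)
        epochs = synthesize_epochs(s, beh, config.cohort)
        epochs.to_hdf5(_epoch_path(out, s.subject_id))
        b = beh.trials.copy()
        b.insert(0, "subject_id", s.subject_id)
        behaviors.append(b)
        logger.info("simulate: %s (%d trials, %d responded)", s.subject_id, beh.n_trials, beh.n_valid)
    _write_tsv(subject_table(subjects), out / "subjects.tsv", config.config_hash)
    _write_tsv(pd.concat(behaviors, ignore_index=True), out / "behavior.tsv", config.config_hash)


def _load_behaviors(out: Path) -> dict[str, SubjectBehavior]:
    table = _read_tsv(out / "behavior.tsv")
    out_d: dict[str, SubjectBehavior] = {}
    for sid, sub in table.groupby("subject_id", sort=False):
        t = sub.drop(columns=["subject_id"]).reset_index(drop=True)
        t["responded"] = t["responded"].astype(bool)
        out_d[str(sid)] = SubjectBehavior(trials=t, subject_id=str(sid))
    return out_d


def stage_preprocess(config: RunConfig, out: Path) -> None:
    subjects = _read_tsv(out / "subjects.tsv")["subject_id"].tolist()
    logs = []
    for sid in subjects:
        epochs = EpochSet.from_hdf5(_epoch_path(out, sid))
        flagged, log = preprocess.exclude_trials(epochs)
        flagged.to_hdf5(_epoch_path(out, sid))
        log.insert(0, "subject_id", sid)
        logs.append(log)
        n_bad = int((~flagged.trial_meta["valid"]).sum())
        logger.info("preprocess: %s excluded %d trials", sid, n_bad)
    _write_tsv(pd.concat(logs, ignore_index=True), out / "exclusions.tsv", config.config_hash)


def subject_neural_metrics(
    epochs: EpochSet, grand_peak_ms: float
) -> NeuralMetrics:
    """All eight scalars for one subject from stimulus-aligned epochs."""
    wave = erp_metrics.n2c_waveform(epochs)
    erp_resp = preprocess.response_locked(epochs, ERP_RESPONSE_WINDOW_MS, baseline_ms=None)
    beta_resp = preprocess.response_locked(epochs, BETA_RESPONSE_WINDOW_MS, baseline_ms=None)
    onset = erp_metrics.cpp_onset(epochs)
    tse_stim = lhb_metrics.tse_power(epochs)
    metrics = NeuralMetrics(
        n2c_latency=erp_metrics.n2c_latency(wave),
        n2c_amplitude=erp_metrics.n2c_amplitude(wave, grand_peak_ms),
        cpp_onset=np.nan if onset is None else onset,
        cpp_slope=erp_metrics.cpp_slope(erp_resp),
        cpp_amplitude=erp_metrics.cpp_amplitude(erp_resp),
        lhb_latency=lhb_metrics.lhb_latency(tse_stim),
    )
    if beta_resp.n_trials >= 1:
        tse_resp = lhb_metrics.tse_power(beta_resp)
        metrics.lhb_slope = lhb_metrics.lhb_slope(tse_resp)
        metrics.lhb_amplitude = lhb_metrics.lhb_amplitude(tse_resp)
    return metrics


def stage_metrics(config: RunConfig, out: Path) -> None:
    subjects = _read_tsv(out / "subjects.tsv")["subject_id"].tolist()
    all_epochs = {sid: EpochSet.from_hdf5(_epoch_path(out, sid)) for sid in subjects}
    waves = [erp_metrics.n2c_waveform(ep) for ep in all_epochs.values()]
    grand_peak = erp_metrics.grand_average_peak(waves)
    rows = {}
    for sid, ep in all_epochs.items():
        rows[sid] = subject_neural_metrics(ep, grand_peak)
        logger.info("metrics: %s done", sid)
    table = metrics_table(rows)
    table["n2c_grand_peak_ms"] = grand_peak
    _write_tsv(table, out / "metrics.tsv", config.config_hash)


def stage_ddm(config: RunConfig, out: Path) -> None:
    behaviors = _load_behaviors(out)
    table = ddm_gsquare.fit_table(behaviors, deadline_ms=config.deadline_ms)
    _write_tsv(table, out / "ddm.tsv", config.config_hash)


def build_cohort_table(out: Path) -> pd.DataFrame:
    """Join subjects, behavior summaries, neural metrics and DDM fits."""
    subjects = _read_tsv(out / "subjects.tsv")
    behaviors = _load_behaviors(out)
    summaries = pd.DataFrame(
        [
            {
                "subject_id": sid,
                "mean_rt": float(np.mean(b.rts)) if b.n_valid else np.nan,
                "accuracy": b.accuracy,
            }
            for sid, b in behaviors.items()
        ]
    )
    table = subjects.merge(summaries, on="subject_id")
    metrics_path = out / "metrics.tsv"
    if metrics_path.exists():
        table = table.merge(_read_tsv(metrics_path), on="subject_id", how="left")
    ddm_path = out / "ddm.tsv"
    if ddm_path.exists():
        table = table.merge(_read_tsv(ddm_path), on="subject_id", how="left")
    table["age_centered"] = table["age"] - table["age"].mean()
    return table


def stage_stats(config: RunConfig, out: Path) -> None:
    table = build_cohort_table(out)
    _write_tsv(table, out / "cohort.tsv", config.config_hash)
    results: dict[str, Any] = {"config_hash": config.config_hash}

    results["group_rt"] = cohort_stats.group_compare(
        table["mean_rt"].to_numpy(), table["group"].to_numpy()
    )

    if "cpp_slope" in table.columns:
        complete = table.dropna(subset=["cpp_slope", "cpp_amplitude", "lhb_latency", "mean_rt"])
        blocks = [
            ("age", ["age_centered"]),
            ("accumulation", ["cpp_slope", "cpp_amplitude"]),
            ("motor", ["lhb_latency"]),
        ]
        steps = cohort_stats.hierarchical_regression(complete, "mean_rt", blocks)
        results["hierarchical"] = [
            {
                "label": s.label,
                "r2": s.r2,
                "adj_r2": s.adj_r2,
                "r2_change": s.r2_change,
                "f_change": s.f_change,
                "p_change": s.p_change,
            }
            for s in steps
        ]

        older = complete[complete["group"] == "older"]
        if len(older) >= 10:
            mod = cohort_stats.moderation(
                older, outcome="mean_rt", predictor="cri_leisure", moderator="cpp_slope"
            )
            results["moderation"] = {
                "coefficients": mod.coefficients.reset_index().to_dict(orient="records"),
                "conditional_effects": mod.conditional_effects.reset_index().to_dict(
                    orient="records"
                ),
                "r2": mod.r2,
                "mse": mod.mse,
            }
            med = cohort_stats.mediation_bootstrap(
                complete,
                x="cpp_slope",
                mediator="cpp_amplitude",
                y="mean_rt",
                n_boot=config.n_boot,
                seed=config.bootstrap_seed,
            )
            results["mediation"] = {
                "indirect": med.indirect,
                "boot_se": med.boot_se,
                "ci": [med.ci_low, med.ci_high],
                "n_boot": med.n_boot,
            }

    (out / "stats.json").write_text(json.dumps(results, indent=2, sort_keys=True))


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "metrics": stage_metrics,
    "ddm": stage_ddm,
    "stats": stage_stats,
}

STAGE_INPUTS = {
    "simulate": [],
    "preprocess": ["subjects.tsv", "behavior.tsv"],
    "metrics": ["subjects.tsv"],
    "ddm": ["behavior.tsv"],
    "stats": ["subjects.tsv", "behavior.tsv"],
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in order; fail fast on missing inputs.

    Returns the run directory. A ``run_log.json`` records per-stage trial
    counts; result files are byte-stable for a fixed config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    for stage in config.stages:
        for artifact in STAGE_INPUTS[stage]:
            if stage != "simulate" and "simulate" not in config.stages and not (out / artifact).exists():
                raise FileNotFoundError(
                    f"stage {stage!r} requires missing artifact {artifact!r}"
                )
        logger.info("running stage %s", stage)
        STAGE_FUNCS[stage](config, out)
    return out
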