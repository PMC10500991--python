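"""Core data containers shared across the pipeline stages.

``EpochSet`` holds a trials x channels x time block with per-trial metadata,
``SubjectBehavior`` the per-trial response records, ``Waveform`` a single
averaged trace, and ``NeuralMetrics`` the eight per-subject scalars. HDF5
round-tripping for epochs and TSV round-tripping for behavior live here so
every stage reads and writes the same on-disk layout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import h5py
import numpy as np
import pandas as pd

Alignment = Literal["stimulus", "response"]

#: Columns every trial-metadata table carries, in canonical order.
TRIAL_META_COLUMNS = [
    "rt_ms",
    "responded",
    "hemifield",
    "direction",
    "iti_s",
    "valid",
    "exclusion_reason",
]


@dataclass
class SubjectBehavior:
    """Per-trial behavioral records for one subject.

    ``trials`` has one row per trial with columns ``rt_ms`` (NaN when the
    deadline passed without a response), ``responded``, ``hemifield``
    (``left``/``right``), ``direction`` (``up``/``down``) and ``iti_s``.
    """

    trials: pd.DataFrame
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        t = self.trials
        missing = {"rt_ms", "responded", "hemifield", "direction", "iti_s"} - set(t.columns)
        if missing:
            raise ValueError(f"behavior table missing columns: {sorted(missing)}")
        responded = t["responded"].astype(bool)
        if (responded & t["rt_ms"].isna()).any() or (~responded & t["rt_ms"].notna()).any():
            raise ValueError("rt_ms must be present iff responded")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_valid(self) -> int:
        return int(self.trials["responded"].sum())

    @property
    def accuracy(self) -> float:
        """Proportion of targets answered before the deadline."""
        if self.n_trials == 0:
            return float("nan")
        return self.n_valid / self.n_trials

    @property
    def rts(self) -> np.ndarray:
        """RTs (ms) of responded trials only."""
        return self.trials.loc[self.trials["responded"].astype(bool), "rt_ms"].to_numpy(float)

    def to_tsv(self, path: str | Path) -> None:
        out = self.trials.copy()
        out.insert(0, "subject_id", self.subject_id)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, subject_id: Optional[str] = None) -> "SubjectBehavior":
        t = pd.read_csv(path, sep="\t")
        if subject_id is not None and "subject_id" in t.columns:
            t = t[t["subject_id"] == subject_id]
        sid = subject_id or (str(t["subject_id"].iloc[0]) if "subject_id" in t.columns else "s0")
        t = t.drop(columns=[c for c in ("subject_id",) if c in t.columns]).reset_index(drop=True)
        t["responded"] = t["responded"].astype(bool)
        return cls(trials=t, subject_id=sid)


@dataclass
class EpochSet:
    """Trials x channels x time EEG block with alignment and metadata.

    ``time_ms`` is strictly increasing and uniformly spaced at
    ``1000 / sampling_rate``; sample 0 of stimulus-aligned sets is the lock
    event. ``trial_meta`` carries the columns in :data:`TRIAL_META_COLUMNS`.
    """

    data: np.ndarray
    time_ms: np.ndarray
    alignment: Alignment
    sampling_rate: float
    channel_labels: list[str]
    trial_meta: pd.DataFrame
    baseline_window: Optional[tuple[float, float]] = None
    csd_transformed: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        n_tr, n_ch, n_t = self.data.shape
        if n_ch != len(self.channel_labels):
            raise ValueError("channel_labels length mismatch")
        if n_t != self.time_ms.size:
            raise ValueError("time axis length mismatch")
        step = 1000.0 / self.sampling_rate
        if n_t > 1 and not np.allclose(np.diff(self.time_ms), step, rtol=0, atol=1e-6):
            raise ValueError("time_ms must be uniform at 1/sampling_rate")
        if len(self.trial_meta) != n_tr:
            raise ValueError("trial_meta length mismatch")
        meta = self.trial_meta.copy()
        if "valid" not in meta.columns:
            meta["valid"] = True
        if "exclusion_reason" not in meta.columns:
            meta["exclusion_reason"] = ""
        meta["exclusion_reason"] = meta["exclusion_reason"].fillna("")
        self.trial_meta = meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present (have {self.channel_labels})")

    def channel_data(self, label: str) -> np.ndarray:
        """Trials x time matrix for one channel."""
        return self.data[:, self.channel_index(label), :]

    def valid_mask(self) -> np.ndarray:
        return self.trial_meta["valid"].to_numpy(bool)

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return dataclasses.replace(
            self,
            data=self.data[mask],
            trial_meta=self.trial_meta.loc[mask].reset_index(drop=True),
        )

    def time_indices(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Indices of samples inside the closed window [start_ms, stop_ms]."""
        return np.flatnonzero((self.time_ms >= start_ms - 1e-9) & (self.time_ms <= stop_ms + 1e-9))

    # -- persistence ----------------------------------------------------

    def to_hdf5(self, path: str | Path) -> None:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("time_ms", data=self.time_ms)
            f.attrs["alignment"] = self.alignment
            f.attrs["sampling_rate"] = self.sampling_rate
            f.attrs["csd_transformed"] = self.csd_transformed
            if self.baseline_window is not None:
                f.attrs["baseline_window"] = list(self.baseline_window)
            f.create_dataset(
                "trial_meta_json", data=self.trial_meta.to_json(orient="split")
            )
        sidecar = {
            "channels": self.channel_labels,
            "sampling_rate": self.sampling_rate,
            "alignment": self.alignment,
            "n_trials": int(self.n_trials),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "EpochSet":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            time_ms = f["time_ms"][()]
            alignment = str(f.attrs["alignment"])
            sampling_rate = float(f.attrs["sampling_rate"])
            csd = bool(f.attrs.get("csd_transformed", False))
            baseline = f.attrs.get("baseline_window")
            import io

            meta = pd.read_json(
                io.StringIO(f["trial_meta_json"][()].decode()), orient="split"
            )
        return cls(
            data=data,
            time_ms=time_ms,
            alignment=alignment,  # type: ignore[arg-type]
            sampling_rate=sampling_rate,
            channel_labels=list(sidecar["channels"]),
            trial_meta=meta,
            baseline_window=tuple(baseline) if baseline is not None else None,
            csd_transformed=csd,
        )


@dataclass
class Waveform:
    """A single averaged trace at one electrode."""

    amplitude: np.ndarray
    time_ms: np.ndarray
    alignment: Alignment
    electrode: str
    n_trials: int

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.amplitude.shape != self.time_ms.shape:
            raise ValueError("amplitude/time shape mismatch")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")

    def window(self, start_ms: float, stop_ms: float) -> tuple[np.ndarray, np.ndarray]:
        idx = np.flatnonzero(
            (self.time_ms >= start_ms - 1e-9) & (self.time_ms <= stop_ms + 1e-9)
        )
        return self.time_ms[idx], self.amplitude[idx]


@dataclass
class NeuralMetrics:
    """The eight per-subject scalars extracted from the EEG."""

    n2c_latency: float = np.nan
    n2c_amplitude: float = np.nan
    cpp_onset: float = np.nan  # NaN encodes "undetected"
    cpp_slope: float = np.nan
    cpp_amplitude: float = np.nan
    lhb_latency: float = np.nan
    lhb_slope: float = np.nan
    lhb_amplitude: float = np.nan

    FIELDS = (
        "n2c_latency",
        "n2c_amplitude",
        "cpp_onset",
        "cpp_slope",
        "cpp_amplitude",
        "lhb_latency",
        "lhb_slope",
        "lhb_amplitude",
    )

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.FIELDS}


def metrics_table(metrics: dict[str, NeuralMetrics]) -> pd.DataFrame:
    """One row per subject from a ``subject_id -> NeuralMetrics`` mapping."""
    rows = []
    for sid, m in metrics.items():
        row = {"subject_id": sid}
        row.update(m.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
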