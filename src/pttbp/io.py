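"""Record container and on-disk format.

A record is a set of time-aligned single-channel waveforms (ECG, PPG and,
when available, invasive ABP for reference labels) sampled at a common rate.
On disk a record is a three-column CSV (``ecg,ppg,abp``) next to a JSON
sidecar ``<stem>.json`` holding the sampling rate and, for synthetic
records, the generator's ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SignalRecord", "save_record", "load_record", "read_record"]


@dataclass
class SignalRecord:
    """Time-aligned ECG/PPG(/ABP) sample sequences plus sampling rate."""

    ecg: np.ndarray
    ppg: np.ndarray
    abp: np.ndarray | None
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        if self.abp is not None:
            self.abp = np.asarray(self.abp, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n = len(self.ecg)
        lengths = {"ecg": n, "ppg": len(self.ppg)}
        if self.abp is not None:
            lengths["abp"] = len(self.abp)
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def has_abp(self) -> bool:
        return self.abp is not None


def save_record(record: SignalRecord, path: str | Path) -> Path:
    """Write a record as ``<path>.csv`` plus JSON sidecar; returns the CSV path."""
    path = Path(path)
    csv_path = path if path.suffix == ".csv" else path.with_suffix(".csv")
    abp = record.abp if record.abp is not None else np.full(record.n_samples, np.nan)
    pd.DataFrame({"ecg": record.ecg, "ppg": record.ppg, "abp": abp}).to_csv(
        csv_path, index=False
    )
    sidecar = {"fs": record.fs, "meta": _jsonable(record.meta)}
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def load_record(path: str | Path) -> SignalRecord:
    """Read a record written by :func:`save_record`."""
    csv_path = Path(path)
    if csv_path.suffix != ".csv":
        csv_path = csv_path.with_suffix(".csv")
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    df = pd.read_csv(csv_path)
    missing = {"ecg", "ppg"} - set(df.columns)
    if missing:
        raise ValueError(
            f"record {csv_path} lacks channel(s) {sorted(missing)}; "
            f"available: {list(df.columns)}"
        )
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path} (holds fs)")
    sidecar = json.loads(sidecar_path.read_text())
    abp = None
    if "abp" in df.columns and not df["abp"].isna().all():
        abp = df["abp"].to_numpy()
    return SignalRecord(
        ecg=df["ecg"].to_numpy(),
        ppg=df["ppg"].to_numpy(),
        abp=abp,
        fs=float(sidecar["fs"]),
        meta=sidecar.get("meta", {}),
    )


def read_record(path: str | Path, format: str = "csv") -> SignalRecord:
    """Load a waveform record.

    Only the package's CSV format is supported in this build; ``format='wfdb'``
    raises with a pointer to convert PhysioNet records to CSV externally.
    """
    if format == "csv":
        return load_record(path)
    if format == "wfdb":
        raise NotImplementedError(
            "WFDB reading is not bundled; export the record's ECG/PPG/ABP channels "
            "to the three-column CSV format (see pttbp.io.save_record) instead."
        )
    raise ValueError(f"unknown record format {format!r}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
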