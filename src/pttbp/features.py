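"""Per-beat feature computation and the feature dataset container.

Fourteen features are computed per beat from the ECG R-peak, the five PPG
landmarks and the pulse cycle:

* three transit times PTTb, PTTa, PTTc (R-peak to onset / maximum-slope
  point / systolic peak, seconds);
* the K value, the normalized mean height of the pulse cycle,
  ``K = (mean - onset) / (peak - onset)``, a dimensionless area-shape index
  tied to peripheral resistance;
* heart rate from the R-R interval (beats/min);
* nine waveform-shape quantities: relative rise and fall times
  Tupr = Tup/T and Tdownr = Tdown/T, main-wave rising slope
  Cslope = Hc/Tup, relative landmark heights Har, Her, Hgr, and the
  relative systolic/diastolic areas S1, S2 (each a fraction of the whole
  cycle area, so S1 + S2 = 1) with their ratio S1/S2.

Features are min–max normalized to [0, 1] before modeling; the published
protocol pools training and test rows when computing the per-feature
ranges, and a leak-free alternative restricted to the training rows is
provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fiducials import Beat

__all__ = [
    "FEATURE_NAMES",
    "FeatureDataset",
    "Scaler",
    "compute_ptt",
    "compute_k",
    "compute_hr",
    "compute_morphology",
    "extract_features",
    "minmax_normalize",
]

#: fixed column order of the 14-feature table
FEATURE_NAMES = [
    "PTTb", "PTTa", "PTTc", "K", "HR", "Tupr", "Tdownr",
    "Cslope", "Har", "Her", "Hgr", "S1", "S2", "S1_over_S2",
]

LABEL_NAMES = ["SBP", "DBP"]


@dataclass
class FeatureDataset:
    """An n-by-14 feature table with SBP/DBP labels and per-row provenance."""

    features: pd.DataFrame
    labels: pd.DataFrame
    provenance: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.features.columns) != FEATURE_NAMES:
            raise ValueError(
                f"feature columns must be exactly {FEATURE_NAMES} in order"
            )
        if self.features.isna().any().any() or self.labels.isna().any().any():
            raise ValueError("missing values are not allowed")
        if len(self.features) < 1:
            raise ValueError("dataset must contain at least one row")
        if len(self.labels) != len(self.features):
            raise ValueError("labels and features disagree in length")
        if not self.provenance:
            self.provenance = ["unknown"] * len(self.features)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def y(self, target: str) -> np.ndarray:
        return self.labels[target].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.concat([self.features, self.labels], axis=1)
        df["provenance"] = self.provenance
        df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureDataset":
        df = pd.read_csv(path)
        prov = (
            df.pop("provenance").astype(str).tolist()
            if "provenance" in df.columns
            else []
        )
        labels = df[[c for c in LABEL_NAMES if c in df.columns]]
        return cls(features=df[FEATURE_NAMES], labels=labels, provenance=prov)

    def subset(self, idx: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels.iloc[idx].reset_index(drop=True),
            provenance=[self.provenance[i] for i in np.atleast_1d(idx)],
            meta=dict(self.meta),
        )


@dataclass
class Scaler:
    """Per-feature min/max of a fitted min–max normalization."""

    mins: pd.Series
    maxs: pd.Series

    def __post_init__(self) -> None:
        if (self.maxs < self.mins).any():
            raise ValueError("per-feature max must be >= min")

    def transform(self, features: pd.DataFrame, clip: bool = False) -> pd.DataFrame:
        out = (features - self.mins) / (self.maxs - self.mins)
        return out.clip(0.0, 1.0) if clip else out

    def inverse(self, normalized: pd.DataFrame) -> pd.DataFrame:
        return normalized * (self.maxs - self.mins) + self.mins


def compute_ptt(beat: Beat, fs: float) -> tuple[float, float, float]:
    """(PTTb, PTTa, PTTc) in seconds: R-peak to onset/max-slope/peak delays."""
    lm = beat.landmarks
    if lm.i_b <= beat.r_index:
        raise ValueError("pulse onset must follow the R-peak (non-causal beat)")
    return (
        (lm.i_b - beat.r_index) / fs,
        (lm.i_a - beat.r_index) / fs,
        (lm.i_c - beat.r_index) / fs,
    )


def compute_k(ppg_cycle: np.ndarray) -> float:
    """K = (mean - onset value) / (peak value - onset value) over one cycle.

    The cycle mean approximates the time integral (1/T) * int PPG dt by the
    sample mean; a flat cycle has no defined K.
    """
    x = np.asarray(ppg_cycle, dtype=float)
    onset = x[0]
    peak = x.max()
    if peak <= onset:
        raise ValueError("flat or inverted pulse cycle: peak must exceed onset value")
    return float((x.mean() - onset) / (peak - onset))


def compute_hr(rr_s: float) -> float:
    """Heart rate in beats/min from the R-R interval in seconds."""
    if rr_s <= 0:
        raise ValueError("rr_s must be positive")
    return 60.0 / rr_s


def compute_morphology(
    beat: Beat, ppg: np.ndarray, fs: float
) -> tuple[float, float, float, float, float, float, float, float, float]:
    """(Tupr, Tdownr, Cslope, Har, Her, Hgr, S1, S2, S1/S2) for one beat.

    Systole is taken as [onset, minimum-slope point) and diastole as the
    rest of the cycle; S1 and S2 are trapezoidal areas of the
    onset-referenced waveform, each divided by the whole-cycle area so that
    S1 + S2 = 1 by construction.
    """
    lm = beat.landmarks
    lo, hi = beat.cycle
    x = np.asarray(ppg, dtype=float)
    if hi >= x.size:
        raise ValueError("cycle extends past the end of the signal")
    T = (hi - lo) / fs
    tup = (lm.i_c - lm.i_b) / fs
    if T <= 0 or tup <= 0:
        raise ValueError("degenerate cycle timing")
    tupr = tup / T
    tdownr = 1.0 - tupr
    if lm.h_c <= 0:
        raise ValueError("non-positive systolic height")
    cslope = lm.h_c / tup
    har = lm.h_a / lm.h_c
    her = lm.h_e / lm.h_c
    hgr = lm.h_g / lm.h_c
    y = x[lo : hi + 1] - x[lm.i_b]
    s1_abs = np.trapezoid(y[: lm.i_e - lo + 1])
    s2_abs = np.trapezoid(y[lm.i_e - lo :])
    total = s1_abs + s2_abs
    if total <= 0:
        raise ValueError("non-positive cycle area")
    s1 = float(s1_abs / total)
    s2 = float(s2_abs / total)
    if s2 == 0:
        raise ValueError("zero diastolic area")
    return tupr, tdownr, cslope, har, her, hgr, s1, s2, s1 / s2


def extract_features(
    beats: list[Beat], ppg: np.ndarray, fs: float, provenance: str = "record"
) -> FeatureDataset:
    """Build the per-beat feature table; beats with degenerate geometry are
    skipped (mirroring the removal of irregular segments upstream)."""
    rows = []
    sbp, dbp = [], []
    for beat in beats:
        if beat.sbp_ref is None or beat.dbp_ref is None:
            continue
        try:
            pttb, ptta, pttc = compute_ptt(beat, fs)
            k = compute_k(np.asarray(ppg)[beat.cycle[0] : beat.cycle[1]])
            hr = compute_hr(beat.rr_s)
            morph = compute_morphology(beat, ppg, fs)
        except ValueError:
            continue
        rows.append((pttb, ptta, pttc, k, hr, *morph))
        sbp.append(beat.sbp_ref)
        dbp.append(beat.dbp_ref)
    if not rows:
        raise ValueError("no usable beats: every beat failed feature extraction")
    features = pd.DataFrame(rows, columns=FEATURE_NAMES)
    labels = pd.DataFrame({"SBP": sbp, "DBP": dbp})
    return FeatureDataset(
        features=features, labels=labels, provenance=[provenance] * len(rows)
    )


def minmax_normalize(
    data: FeatureDataset,
    mode: str = "paper",
    train_idx: np.ndarray | None = None,
) -> tuple[FeatureDataset, Scaler]:
    """Min–max normalize each feature to [0, 1].

    ``mode='paper'`` computes the per-feature ranges over all rows (train and
    test pooled, as in the published protocol); ``mode='leakfree'`` computes
    them over ``train_idx`` only and clips the remaining rows into [0, 1].
    A constant feature cannot be scaled and raises, naming the column.
    """
    if len(data) < 2:
        raise ValueError("need at least 2 rows to normalize")
    if mode == "paper":
        ref = data.features
    elif mode == "leakfree":
        if train_idx is None:
            raise ValueError("leakfree mode requires train_idx")
        ref = data.features.iloc[train_idx]
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    mins, maxs = ref.min(), ref.max()
    constant = mins.index[(maxs - mins) <= 0]
    if len(constant):
        raise ValueError(f"constant feature(s) cannot be normalized: {list(constant)}")
    scaler = Scaler(mins=mins, maxs=maxs)
    normalized = scaler.transform(data.features, clip=(mode == "leakfree"))
    out = FeatureDataset(
        features=normalized,
        labels=data.labels.copy(),
        provenance=list(data.provenance),
        meta=dict(data.meta),
    )
    return out, scaler
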