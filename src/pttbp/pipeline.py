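"""End-to-end experiment orchestration.

For each target (SBP, DBP) the pipeline performs the published workflow:
a seeded 80/20 row split, min–max normalization, a GA-optimized ε-SVR on
all 14 features, MIV analysis of that model, retention of the features
within the cumulative-contribution threshold, a second GA-optimized ε-SVR
on the reduced feature set (the GA-MIV-SVR model), and reference baselines
(multiple linear regression on the same reduced features, and a GA-tuned
SVR on PTTc alone), all evaluated on the held-out test rows.

Everything is reproducible from ``RunConfig.seed``: the split, the GA runs
and the CV folds all draw their seeds from it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fiducials, preprocess
from .evaluation import evaluate
from .features import (
    FEATURE_NAMES,
    FeatureDataset,
    extract_features,
    minmax_normalize,
)
from .io import SignalRecord, read_record
from .miv import compute_miv, contribution_table, select_features
from .models import GAConfig, fit_mlr, fit_svr, ga_optimize, predict_svr
from .simgen import SimConfig, simulate_feature_dataset, simulate_subject

__all__ = ["RunConfig", "run_pipeline", "prepare_record", "dataset_from_records"]

log = logging.getLogger(__name__)

MIN_BEATS = 50


@dataclass
class RunConfig:
    """Configuration of one full estimation experiment."""

    source: str = "features"  # "features" | "signals" | "records"
    n_beats: int = 1000
    effect: str = "nonlinear"
    noise_sigma: float = 1.0
    sim: SimConfig | None = None
    record_paths: list[str] = field(default_factory=list)
    train_frac: float = 0.8
    norm_mode: str = "paper"
    ga: GAConfig = field(default_factory=GAConfig)
    miv_threshold_pct: float = 90.0
    targets: tuple[str, ...] = ("SBP", "DBP")
    baselines: tuple[str, ...] = ("MLR", "PTTc-SVR")
    bhs_mode: str = "strict"
    seed: int = 0
    outdir: str | Path | None = None

    def validate(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie strictly between 0 and 1")
        if not self.targets:
            raise ValueError("at least one target (SBP/DBP) is required")
        if self.source not in ("features", "signals", "records"):
            raise ValueError(f"unknown source {self.source!r}")


def prepare_record(record: SignalRecord) -> SignalRecord:
    """Condition a raw record: wavelet-denoise the ECG and spline-remove the
    PPG baseline (knots at the detected pulse valleys)."""
    ecg = preprocess.denoise_ecg(record.ecg)
    valleys = fiducials.detect_pulse_valleys(record.ppg, record.fs)
    if valleys.size >= 4:
        ppg = preprocess.remove_ppg_baseline(record.ppg, valleys)
    else:
        log.warning("fewer than 4 pulse valleys found; PPG left unchanged")
        ppg = record.ppg
    return SignalRecord(ecg=ecg, ppg=ppg, abp=record.abp, fs=record.fs,
                        meta=dict(record.meta))


def dataset_from_records(records: list[SignalRecord]) -> FeatureDataset:
    """Condition each record, assemble beats, and concatenate feature tables."""
    import pandas as pd

    parts = []
    for i, rec in enumerate(records):
        conditioned = prepare_record(rec)
        beats = fiducials.annotate_beats(conditioned)
        part = extract_features(beats, conditioned.ppg, conditioned.fs,
                                provenance=f"record:{i}")
        parts.append(part)
    features = pd.concat([p.features for p in parts], ignore_index=True)
    labels = pd.concat([p.labels for p in parts], ignore_index=True)
    provenance = [tag for p in parts for tag in p.provenance]
    return FeatureDataset(features=features, labels=labels, provenance=provenance)


def _build_dataset(cfg: RunConfig) -> FeatureDataset:
    if cfg.source == "features":
        return simulate_feature_dataset(
            cfg.n_beats, effect=cfg.effect, noise_sigma=cfg.noise_sigma, seed=cfg.seed
        )
    if cfg.source == "signals":
        sim = cfg.sim or SimConfig(duration_s=120.0, seed=cfg.seed)
        record, _ = simulate_subject(sim)
        return dataset_from_records([record])
    records = [read_record(p) for p in cfg.record_paths]
    for i, rec in enumerate(records):
        if rec.abp is None:
            raise ValueError(
                f"record {cfg.record_paths[i]} has no ABP channel; training "
                "requires reference BP"
            )
    return dataset_from_records(records)


def _mlr_pruned(Xtr, ytr, names):
    """OLS that drops exactly collinear columns (e.g. complements like S1/S2)
    until the design is full rank; returns (model, used column names)."""
    used = list(names)
    while True:
        idx = [names.index(u) for u in used]
        try:
            return fit_mlr(Xtr[:, idx], ytr, feature_names=used), used
        except ValueError as err:
            msg = str(err)
            dropped = None
            for u in reversed(used):
                if u in msg:
                    dropped = u
                    break
            if dropped is None or len(used) == 1:
                raise
            log.info("MLR baseline: dropping collinear feature %s", dropped)
            used.remove(dropped)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full experiment; returns (and optionally writes) the run
    report. Refuses datasets with fewer than 50 usable beats."""
    cfg.validate()
    dataset = _build_dataset(cfg)
    n = len(dataset)
    if n < MIN_BEATS:
        raise ValueError(
            f"only {n} usable beats; at least {MIN_BEATS} are required for a "
            "meaningful train/test split"
        )

    # deterministic sub-seeds (one stream per stage and target)
    states = np.random.SeedSequence(cfg.seed).generate_state(4 * len(cfg.targets) + 1)
    sub = [int(s & 0x7FFFFFFF) for s in states]

    split_rng = np.random.default_rng(sub[0])
    order = split_rng.permutation(n)
    n_train = int(round(cfg.train_frac * n))
    train_idx, test_idx = np.sort(order[:n_train]), np.sort(order[n_train:])

    norm, scaler = minmax_normalize(dataset, mode=cfg.norm_mode, train_idx=train_idx)
    X = norm.X
    Xtr, Xte = X[train_idx], X[test_idx]

    report: dict = {
        "n_beats": n,
        "n_train": int(n_train),
        "n_test": int(n - n_train),
        "seed": cfg.seed,
        "norm_mode": cfg.norm_mode,
        "miv_threshold_pct": cfg.miv_threshold_pct,
        "targets": {},
    }

    for t_i, target in enumerate(cfg.targets):
        y = dataset.y(target)
        ytr, yte = y[train_idx], y[test_idx]
        s_all, s_miv, s_ptt, _ = sub[1 + 4 * t_i : 1 + 4 * (t_i + 1)]

        # (3) GA-SVR on all 14 features
        ga1 = ga_optimize(Xtr, ytr, dataclasses.replace(cfg.ga, seed=s_all))
        model1 = fit_svr(Xtr, ytr, ga1.best_params)

        # (4)-(5) MIV table and feature retention
        mivs = compute_miv(model1, Xtr)
        table = contribution_table(mivs, FEATURE_NAMES)
        selected = select_features(table, cfg.miv_threshold_pct)
        sel_idx = [FEATURE_NAMES.index(f) for f in selected]

        # (6) GA-MIV-SVR on the reduced feature set
        ga2 = ga_optimize(Xtr[:, sel_idx], ytr, dataclasses.replace(cfg.ga, seed=s_miv))
        model2 = fit_svr(Xtr[:, sel_idx], ytr, ga2.best_params)
        yhat = predict_svr(model2, Xte[:, sel_idx])
        evals = {"GA-MIV-SVR": evaluate(yte, yhat, bhs_mode=cfg.bhs_mode)}

        # (7) baselines on the same data
        if "MLR" in cfg.baselines:
            mlr, used = _mlr_pruned(Xtr[:, sel_idx], ytr, selected)
            used_idx = [FEATURE_NAMES.index(f) for f in used]
            evals["MLR"] = evaluate(yte, mlr.predict(Xte[:, used_idx]),
                                    bhs_mode=cfg.bhs_mode)
        if "PTTc-SVR" in cfg.baselines:
            j = FEATURE_NAMES.index("PTTc")
            ga_p = ga_optimize(Xtr[:, [j]], ytr, dataclasses.replace(cfg.ga, seed=s_ptt))
            model_p = fit_svr(Xtr[:, [j]], ytr, ga_p.best_params)
            evals["PTTc-SVR"] = evaluate(yte, predict_svr(model_p, Xte[:, [j]]),
                                         bhs_mode=cfg.bhs_mode)

        report["targets"][target] = {
            "ga_all_features": ga1.to_dict(),
            "miv_table": table.to_dict(orient="records"),
            "selected_features": selected,
            "ga_reduced": ga2.to_dict(),
            "reports": {k: v.to_dict() for k, v in evals.items()},
            "model": model2.to_dict(),
        }

    if cfg.outdir is not None:
        _write_artifacts(cfg, dataset, report)
    return report


def _write_artifacts(cfg: RunConfig, dataset: FeatureDataset, report: dict) -> None:
    import pandas as pd

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.to_csv(outdir / "features.csv")
    for target, block in report["targets"].items():
        pd.DataFrame(block["miv_table"]).to_csv(
            outdir / f"miv_{target}.csv", index=False
        )
        (outdir / f"report_{target}.json").write_text(
            json.dumps(
                {k: v for k, v in block.items() if k != "miv_table"},
                indent=1, sort_keys=True,
            )
        )
    summary = {k: v for k, v in report.items() if k != "targets"}
    (outdir / "run.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
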