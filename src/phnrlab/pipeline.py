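"""End-to-end orchestration: simulate -> extract -> stats -> roc -> tsc.

A single YAML config drives the run; the resolved configuration and a JSON
log (package version, seed, row counts, QC exclusions) are written next to
the outputs.  One global seed fans out to fixed per-stage offsets so each
stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostic import (auc_trapezoid, choose_orientation, confusion_from_threshold,
                         roc_curve, select_one_eye_per_subject, youden_optimal)
from .features import FEATURE_COLUMNS, ExtractionConfig, extract_features_table
from .simulate import CohortSpec, simulate_cohort
from .stats import compare_on_vs_control, fits_to_frame
from .tsc import ClassifierConfig, run_benchmark
from .waveform import read_waveform_table, write_waveform_table

__all__ = ["PipelineConfig", "parse_config", "run_pipeline", "roc_table"]

STAGES = ("simulate", "extract", "stats", "roc", "tsc")
# fixed per-stage seed offsets (stage seed = global seed + offset)
SEED_OFFSETS = {"simulate": 0, "tsc_split": 101, "tsc_model": 211}


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = STAGES
    output_dir: str = "pipeline_out"
    seed: int = 0
    waveforms_path: str | None = None  # input when not simulating
    cohort: CohortSpec = field(default_factory=CohortSpec)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    adjust_age: bool = True
    severity_filter_db: float | None = None  # e.g. -5.0 restricts ON eyes
    classifiers: tuple[str, ...] = ("nn_dtw", "svm_linear", "svm_rbf",
                                    "rf", "gb", "tsf", "lstm")
    split_fractions: tuple[float, float, float] = (0.44, 0.27, 0.29)
    split_tolerance: float = 0.05
    lstm_epochs: int = 100

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {where} keys: {sorted(unknown)}")
    if cls is CohortSpec and isinstance(data.get("waveform"), dict):
        from .simulate import WaveformParams
        data = {**data, "waveform": _build(WaveformParams, data["waveform"],
                                           f"{where}.waveform")}
    return cls(**data)


def parse_config(path: str | Path | None = None, overrides: dict | None = None
                 ) -> PipelineConfig:
    """Load a pipeline config from YAML; unknown keys are rejected by name.

    ``overrides`` (same schema) take precedence over the file contents.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update(loaded)
    data.update(overrides or {})
    nested = {
        "cohort": (CohortSpec, data.pop("cohort", {})),
        "extraction": (ExtractionConfig, data.pop("extraction", {})),
    }
    names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    for attr, (cls, sub) in nested.items():
        if isinstance(sub, cls):
            setattr(cfg, attr, sub)
        else:
            setattr(cfg, attr, _build(cls, dict(sub), attr))
    for name in ("stages", "classifiers", "split_fractions"):
        setattr(cfg, name, tuple(getattr(cfg, name)))
    return cfg


def roc_table(features: pd.DataFrame, feature_columns=None,
              severity_filter_db: float | None = None) -> pd.DataFrame:
    """Per-feature ROC/Youden summary on one eye per subject.

    Recordings are averaged per eye before eye selection.  When
    ``severity_filter_db`` is given, ON eyes are restricted to those with
    HVF mean deviation below the threshold (severe disease subset).
    """
    cols = feature_columns or FEATURE_COLUMNS
    df = features[features["label"].isin(["ON_POS", "ON_NEG"])]
    if "qc_pass" in df.columns:
        df = df[df["qc_pass"].astype(bool)]
    if severity_filter_db is not None:
        keep_on = (df["label"] == "ON_NEG") | (df["hvf_md_db"] < severity_filter_db)
        df = df[keep_on]
    per_eye = (df.groupby(["subject_id", "eye", "label"], as_index=False)[list(cols)]
               .mean())
    rows = [row for _, row in per_eye.iterrows()]
    kept = select_one_eye_per_subject(rows)
    eyes = pd.DataFrame([dict(r) for r in kept])
    out = []
    for feat in cols:
        sub = eyes.dropna(subset=[feat])
        scores, labels = sub[feat].to_numpy(), sub["label"].to_numpy()
        orientation = choose_orientation(scores, labels)
        curve = roc_curve(scores, labels, orientation)
        youden = youden_optimal(curve)
        cm = confusion_from_threshold(scores, labels, youden.cutoff, orientation)
        out.append({
            "feature": feat, "auc": auc_trapezoid(curve),
            "youden_j": youden.j_statistic, "cutoff": youden.cutoff,
            "sensitivity": youden.sensitivity, "specificity": youden.specificity,
            "f1_paper": cm.f1_paper, "f1_std": cm.f1_std,
            "orientation": orientation,
            "n_positive": curve.n_positive, "n_negative": curve.n_negative,
        })
    return pd.DataFrame(out)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the artifact directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    records = None
    features = None
    if "simulate" in config.stages:
        spec = dataclasses.replace(config.cohort,
                                   seed=config.seed + SEED_OFFSETS["simulate"])
        records, truth = simulate_cohort(spec)
        write_waveform_table(records, out / "waveforms.csv")
        truth.to_csv(out / "truth.csv", index=False)
        log["stages"]["simulate"] = {"n_records": len(records),
                                     "n_subjects": spec.n_subjects}
    elif any(s in config.stages for s in ("extract", "tsc")):
        if not config.waveforms_path:
            raise ValueError("waveforms_path required when the simulate stage is off")
        records = read_waveform_table(config.waveforms_path)

    if "extract" in config.stages:
        if records is None:
            raise ValueError("extract stage needs waveforms")
        features = extract_features_table(records, config.extraction)
        features.to_csv(out / "features.csv", index=False)
        excluded = features.loc[~features["qc_pass"],
                                ["subject_id", "eye", "visit_index",
                                 "recording_index", "qc_reasons"]]
        log["stages"]["extract"] = {
            "n_rows": len(features),
            "n_qc_excluded": int(len(excluded)),
            "qc_excluded": excluded.to_dict("records"),
        }

    if "stats" in config.stages:
        if features is None:
            raise ValueError("stats stage needs extracted features")
        usable = features[features["qc_pass"].astype(bool)]
        tables = [fits_to_frame(compare_on_vs_control(usable, adjust_age=False),
                                model="on_vs_control")]
        if config.adjust_age:
            tables.append(fits_to_frame(
                compare_on_vs_control(usable, adjust_age=True),
                model="on_vs_control_age_adjusted"))
        stats_df = pd.concat(tables, ignore_index=True)
        stats_df.to_csv(out / "stats.csv", index=False)
        log["stages"]["stats"] = {"n_models": int(stats_df["model"].nunique()),
                                  "n_rows": len(stats_df)}

    if "roc" in config.stages:
        if features is None:
            raise ValueError("roc stage needs extracted features")
        roc_df = roc_table(features, severity_filter_db=config.severity_filter_db)
        roc_df.to_csv(out / "roc.csv", index=False)
        log["stages"]["roc"] = {"n_features": len(roc_df)}

    if "tsc" in config.stages:
        if records is None:
            raise ValueError("tsc stage needs waveforms")
        labeled = [r for r in records if r.label in ("ON_POS", "ON_NEG")]
        model_seed = config.seed + SEED_OFFSETS["tsc_model"]
        configs = []
        for kind in config.classifiers:
            cfg = ClassifierConfig(kind=kind, seed=model_seed)
            if kind == "lstm":
                cfg = dataclasses.replace(cfg, lstm={**cfg.lstm,
                                                     "n_epochs": config.lstm_epochs})
            configs.append(cfg)
        report = run_benchmark(labeled, configs,
                               split_seed=config.seed + SEED_OFFSETS["tsc_split"],
                               fractions=config.split_fractions,
                               tolerance=config.split_tolerance)
        rows = []
        for kind, cm in report.metrics.items():
            rows.append({
                "classifier": kind,
                "precision_paper": cm.precision_paper,
                "recall_paper": cm.recall_paper,
                "accuracy": cm.accuracy, "f1_paper": cm.f1_paper,
                "precision_std": cm.precision_std, "f1_std": cm.f1_std,
                "n_train": report.split_sizes["train"],
                "n_val": report.split_sizes["validation"],
                "n_test": report.split_sizes["test"],
            })
        pd.DataFrame(rows).to_csv(out / "tsc_report.csv", index=False)
        log["stages"]["tsc"] = {"split_sizes": report.split_sizes,
                                "classifiers": list(report.metrics)}

    (out / "config_resolved.yaml").write_text(
        yaml.safe_dump(_plain(config.to_dict()), sort_keys=False))
    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    return out


def _plain(obj):
    """Recursively convert tuples/NumPy scalars for clean YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
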