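"""End-to-end orchestration: records -> features -> selection -> reports.

``run_pipeline`` reproduces the full experiment layout: a per-segment
feature table, an importance ranking, an incremental cross-validated
MSE profile, a feature-count comparison, and per-interval reports for
the optimal-set decision tree (oDT) against the full-set tree (fDT)
and against naive Bayes and SVM. All stages are pure functions of
(inputs, config, seeds); rerunning with the same seeds reproduces the
reports byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .classification import (ClassifierSpec, IntervalDataset,
                             build_interval_datasets, run_cv, train)
from .evaluation import (aggregate_report, measure_execution_time,
                         sensitivity, specificity)
from .feature_extraction import FeatureConfig, extract_feature_vector
from .feature_selection import (CVConfig, cv_mse_profile,
                                estimate_importance, select_optimal_set)
from .record_io import (FEATURE_NAMES, ECGRecord, FeatureTable,
                        curate_records, replace_outliers, segment_record,
                        truncate_record, write_feature_table)

_INTERVAL_LABELS = {r: f"<= {5 * r}" for r in range(1, 6)}


@dataclass(frozen=True)
class PipelineConfig:
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5)
    folds_select: int = 10
    folds_classify: int = 5
    max_minutes: float = 35.0
    outlier_window_s: float = 1.0
    outlier_n_mad: float = 3.0
    features: FeatureConfig = field(default_factory=FeatureConfig)
    criterion: str = "gini"
    min_split: int = 10
    sd_mode: str = "sample"
    ext_repetitions: int = 25
    optimal_set: tuple[str, ...] | None = None  # None -> choose automatically


@dataclass
class PipelineResult:
    feature_table: FeatureTable
    importance: pd.DataFrame
    mse_profile: pd.DataFrame
    k_comparison: pd.DataFrame
    optimal_set: list[str]
    interval_dt: pd.DataFrame
    interval_classifiers: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        write_feature_table(self.feature_table,
                            out_dir / "feature_table.csv")
        paths["feature_table"] = out_dir / "feature_table.csv"
        for name, frame in (
            ("importance", self.importance),
            ("mse_profile", self.mse_profile),
            ("k_comparison", self.k_comparison),
            ("interval_dt", self.interval_dt),
            ("interval_classifiers", self.interval_classifiers),
        ):
            path = out_dir / f"{name}.csv"
            frame.to_csv(path, float_format="%.6g")
            paths[name] = path
        (out_dir / "optimal_set.txt").write_text(
            ",".join(self.optimal_set) + "\n")
        paths["optimal_set"] = out_dir / "optimal_set.txt"
        return paths


def preprocess_records(records: Iterable[ECGRecord],
                       cfg: PipelineConfig = PipelineConfig()
                       ) -> list[ECGRecord]:
    """Curate, truncate and de-outlier raw records."""
    out = []
    for rec in curate_records(records):
        rec = truncate_record(rec, cfg.max_minutes)
        rec = replace_outliers(rec, cfg.outlier_window_s, cfg.outlier_n_mad)
        out.append(rec)
    return out


def extract_features(records: Iterable[ECGRecord],
                     cfg: PipelineConfig = PipelineConfig()) -> FeatureTable:
    """Segment preprocessed records and extract per-segment features."""
    rows = []
    for rec in records:
        for seg in segment_record(rec):
            vec = extract_feature_vector(seg, cfg.features)
            if vec is None:
                continue
            row = vec.to_dict()
            row.update(
                label=seg.label,
                minutes_before_onset=(
                    seg.minutes_before_onset
                    if seg.minutes_before_onset is not None else np.nan),
                record_id=seg.record_id,
                segment_index=seg.index_in_record,
                n_beats=vec.n_beats,
            )
            rows.append(row)
    if not rows:
        raise ValueError("no usable segments in the supplied records")
    return FeatureTable(pd.DataFrame(rows))


def _evaluate_intervals(datasets: dict[int, IntervalDataset],
                        specs: dict[str, tuple[ClassifierSpec, list[str]]],
                        cfg: PipelineConfig) -> pd.DataFrame:
    """Per-interval SE/SP (averaged over seeds) and exT per classifier."""
    cv = CVConfig(k_folds=cfg.folds_classify, seeds=cfg.seeds)
    records = []
    for r, ds in sorted(datasets.items()):
        row: dict[str, float | str] = {"interval": _INTERVAL_LABELS[r]}
        for name, (spec, subset) in specs.items():
            counts = run_cv(ds, spec, subset, cv)
            row[f"{name}_SE"] = float(np.mean([sensitivity(c)
                                               for c in counts]))
            row[f"{name}_SP"] = float(np.mean([specificity(c)
                                               for c in counts]))
            X = ds.table.frame.loc[:, subset].to_numpy(float)
            model = train(spec, X, ds.table.y, subset)
            row[f"{name}_exT"] = measure_execution_time(
                model, X, cfg.ext_repetitions)
        records.append(row)
    frame = pd.DataFrame(records).set_index("interval")
    return aggregate_report(frame, cfg.sd_mode)


def run_pipeline(records: Iterable[ECGRecord] | None = None,
                 feature_table: FeatureTable | None = None,
                 cfg: PipelineConfig = PipelineConfig(),
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage from raw records or a pre-extracted feature table.

    Exactly one of ``records`` / ``feature_table`` may trigger the
    upstream stages: when only a table is given, preprocessing and
    extraction are skipped.
    """
    if feature_table is None:
        if records is None:
            raise ValueError("need records or a feature table")
        prepped = preprocess_records(records, cfg)
        feature_table = extract_features(prepped, cfg)

    imp = estimate_importance(feature_table, cfg.criterion, cfg.min_split)
    cv_sel = CVConfig(k_folds=cfg.folds_select, seeds=cfg.seeds)
    profile = cv_mse_profile(feature_table, imp.ranking, cv_sel,
                             cfg.criterion, cfg.min_split)

    datasets = build_interval_datasets(feature_table)
    if not datasets:
        raise ValueError("no populated pre-onset intervals")

    # feature-count comparison over the one-SD candidate sizes
    mean, sd = profile.mean, profile.sd
    k_min = int(mean.idxmin())
    threshold = mean.loc[k_min] + sd.loc[k_min]
    candidate_ks = [int(k) for k in mean.index if mean.loc[k] <= threshold]
    cv_cls = CVConfig(k_folds=cfg.folds_classify, seeds=cfg.seeds)
    dt_spec = ClassifierSpec("dt", {"criterion": cfg.criterion,
                                    "min_split": cfg.min_split})
    perf_rows = {}
    for k in candidate_ks:
        subset = imp.ranking[:k]
        se_list, sp_list, ext_list = [], [], []
        for r, ds in sorted(datasets.items()):
            counts = run_cv(ds, dt_spec, subset, cv_cls)
            se_list.append(np.mean([sensitivity(c) for c in counts]))
            sp_list.append(np.mean([specificity(c) for c in counts]))
            X = ds.table.frame.loc[:, subset].to_numpy(float)
            model = train(dt_spec, X, ds.table.y, subset)
            ext_list.append(measure_execution_time(model, X,
                                                   cfg.ext_repetitions))
        perf_rows[k] = {"SE": float(np.mean(se_list)),
                        "SP": float(np.mean(sp_list)),
                        "exT": float(np.mean(ext_list))}
    perf_by_k = pd.DataFrame(perf_rows).T
    perf_by_k.index.name = "k"

    if cfg.optimal_set is not None:
        optimal = list(cfg.optimal_set)
        unknown = set(optimal) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features in optimal set: {unknown}")
    else:
        optimal = select_optimal_set(profile, imp.ranking, perf_by_k)

    interval_dt = _evaluate_intervals(
        datasets,
        {"oDT": (dt_spec, optimal), "fDT": (dt_spec, list(FEATURE_NAMES))},
        cfg,
    )
    interval_cls = _evaluate_intervals(
        datasets,
        {
            "oDT": (dt_spec, optimal),
            "NB": (ClassifierSpec("nb"), optimal),
            "SVM": (ClassifierSpec("svm"), optimal),
        },
        cfg,
    )

    result = PipelineResult(
        feature_table=feature_table,
        importance=imp.to_frame().set_index("No."),
        mse_profile=profile.frame,
        k_comparison=perf_by_k,
        optimal_set=optimal,
        interval_dt=interval_dt,
        interval_classifiers=interval_cls,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
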