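"""Interval-stratified classification: DT vs naive Bayes vs SVM.

Pre-arrhythmic feature rows are binned into five 5-minute intervals
before onset — interval r covers ((r-1)*5, r*5] minutes — and each
interval is paired with an equal number of normal rows matched by
minute position within their record. Classifiers are evaluated with
repeated stratified 5-fold cross-validation (feature subset fixed
before splitting), pooling test-fold confusion counts per seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cart import fit_cart
from .errors import SchemaError
from .evaluation import ConfusionCounts
from .feature_selection import CVConfig, stratified_folds
from .record_io import FEATURE_NAMES, FeatureTable

N_INTERVALS = 5
INTERVAL_MINUTES = 5.0


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind plus kind-specific parameters.

    dt: criterion, min_split; nb: var_smoothing; svm: kernel, C,
    standardize.
    """

    kind: str  # {"dt", "nb", "svm"}
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("dt", "nb", "svm"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass
class IntervalDataset:
    """Rows of one 5-minute interval: positives plus matched negatives."""

    interval_index: int  # r in 1..5
    table: FeatureTable

    @property
    def n_positive(self) -> int:
        return int((self.table.y == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.table.y == 0).sum())


def interval_of(minutes_before_onset: float) -> int | None:
    """Interval index r with (r-1)*5 < m <= r*5, or None outside 0-25."""
    m = minutes_before_onset
    if not 0 < m <= N_INTERVALS * INTERVAL_MINUTES:
        return None
    return max(1, math.ceil(m / INTERVAL_MINUTES))


def build_interval_datasets(table: FeatureTable) -> dict[int, IntervalDataset]:
    """Split a feature table into the five pre-onset interval datasets.

    Positives are assigned by their minutes-before-onset tag; rows
    outside (0, 25] minutes are discarded. Each positive is matched
    with a normal row at the same minute index within its record
    (``segment_index``) when available, drawn without replacement.
    """
    frame = table.frame
    if "minutes_before_onset" not in frame.columns:
        raise SchemaError("table lacks minutes_before_onset for positives")
    pos = frame[frame["label"] == 1]
    neg = frame[frame["label"] == 0]
    has_seg = "segment_index" in frame.columns

    neg_used = np.zeros(len(neg), dtype=bool)
    neg_by_seg: dict[int, list[int]] = {}
    if has_seg:
        for pos_i, seg in enumerate(neg["segment_index"].to_numpy()):
            neg_by_seg.setdefault(int(seg), []).append(pos_i)

    def draw_negative(seg: int | None) -> int | None:
        if seg is not None:
            for i in neg_by_seg.get(seg, []):
                if not neg_used[i]:
                    neg_used[i] = True
                    return i
        free = np.flatnonzero(~neg_used)
        if len(free) == 0:
            return None
        neg_used[free[0]] = True
        return int(free[0])

    datasets: dict[int, IntervalDataset] = {}
    for r in range(1, N_INTERVALS + 1):
        rows = []
        for _, row in pos.iterrows():
            if interval_of(float(row["minutes_before_onset"])) != r:
                continue
            rows.append(row)
            seg = int(row["segment_index"]) if has_seg else None
            j = draw_negative(seg)
            if j is None:
                warnings.warn("negatives exhausted while matching",
                              stacklevel=2)
            else:
                rows.append(neg.iloc[j])
        if not rows:
            warnings.warn(f"interval {r} is empty; skipped in reports",
                          stacklevel=2)
            continue
        sub = pd.DataFrame(rows).reset_index(drop=True)
        datasets[r] = IntervalDataset(r, FeatureTable(sub))
    return datasets


def train(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray,
          feature_subset: list[str] | None = None):
    """Fit a classifier of the given kind; deterministic.

    ``X`` must already be restricted to the feature subset; the subset
    list is stored on the model for schema checks at prediction time.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    p = spec.params
    if spec.kind == "dt":
        model = fit_cart(X, y, criterion=p.get("criterion", "gini"),
                         min_split=p.get("min_split", 10))
    elif spec.kind == "nb":
        model = GaussianNB(var_smoothing=p.get("var_smoothing", 1e-9))
        model.fit(X, y)
    else:
        svc = SVC(kernel=p.get("kernel", "linear"), C=p.get("C", 1.0))
        if p.get("standardize", False):
            model = make_pipeline(StandardScaler(), svc)
        else:
            model = svc
        if len(np.unique(y)) < 2:
            raise ValueError("SVM requires both classes in training data")
        model.fit(X, y)
    model.feature_subset_ = list(feature_subset) if feature_subset else None
    return model


def predict(model, X, feature_names: list[str] | None = None) -> np.ndarray:
    """Predict 0/1 labels; checks the feature schema when names are given."""
    subset = getattr(model, "feature_subset_", None)
    if subset is not None and feature_names is not None:
        missing = [f for f in subset if f not in feature_names]
        if missing:
            raise SchemaError(f"rows missing model features: {missing}")
    return np.asarray(model.predict(np.asarray(X, float)), dtype=int)


def run_cv(dataset: IntervalDataset, spec: ClassifierSpec,
           feature_subset: list[str] | None = None,
           cv: CVConfig = CVConfig(k_folds=5)) -> list[ConfusionCounts]:
    """Repeated stratified CV; pooled confusion counts per seed.

    The feature subset is fixed before splitting (selection outside the
    CV loop). When an interval holds fewer positives than folds, the
    fold count is reduced to the positive count.
    """
    subset = list(feature_subset) if feature_subset else list(FEATURE_NAMES)
    frame = dataset.table.frame
    X = frame.loc[:, subset].to_numpy(float)
    y = dataset.table.y
    k = cv.k_folds
    n_min = min((y == 1).sum(), (y == 0).sum())
    if n_min < k:
        warnings.warn(
            f"interval {dataset.interval_index}: only {n_min} rows in the "
            f"rarer class; folds reduced from {k}", stacklevel=2,
        )
        k = max(2, int(n_min))
    results = []
    for seed in cv.seeds:
        folds = stratified_folds(y, k, seed)
        pred = np.empty(len(y), dtype=int)
        for f in range(k):
            tr = folds != f
            model = train(spec, X[tr], y[tr], subset)
            pred[~tr] = predict(model, X[~tr])
        results.append(ConfusionCounts.from_labels(y, pred))
    return results
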