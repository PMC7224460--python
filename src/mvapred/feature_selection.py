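"""Importance-driven feature ranking and incremental CV error profiling.

The 12 features are ranked by decision-tree predictor importance
computed on the full table, then evaluated incrementally: for each
k = 1..12 the top-k features are cross-validated (stratified k-fold,
repeated over a list of seeds) and the misclassification MSE recorded.
The optimal subset size is the smallest k whose mean MSE lies within
one standard deviation of the global minimum; when a per-k performance
table is supplied, candidates with equal sensitivity prefer the smaller
k (shorter prediction latency at an accepted specificity cost).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cart import CART, fit_cart
from .record_io import FEATURE_NAMES, FeatureTable


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified k-fold settings.

    ``variant="OUT"`` ranks features once on the full table before any
    fold splitting; ``"IN"`` re-ranks inside each training fold.
    """

    k_folds: int = 10
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5)
    variant: str = "OUT"
    stratified: bool = True


@dataclass
class ImportanceResult:
    """Per-feature importance values and the descending ranking."""

    importances: dict[str, float]
    ranking: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "No.": np.arange(1, len(self.ranking) + 1),
            "feature": self.ranking,
            "Imp": [self.importances[f] for f in self.ranking],
        })


@dataclass
class MSEProfile:
    """Cross-validated MSE per feature count: per-seed values, mean, SD."""

    frame: pd.DataFrame  # index: k; columns: seed_<s>..., mean, sd

    @property
    def mean(self) -> pd.Series:
        return self.frame["mean"]

    @property
    def sd(self) -> pd.Series:
        return self.frame["sd"]


def estimate_importance(table: FeatureTable, criterion: str = "gini",
                        min_split: int = 10) -> ImportanceResult:
    """Rank all 12 features by tree predictor importance.

    Importance of a feature is the sum of risk reductions of the branch
    nodes splitting on it, divided by the number of branch nodes;
    features never split on get exactly 0. Ties in importance are broken
    by canonical feature order.
    """
    tree = fit_cart(table.X, table.y, criterion=criterion,
                    min_split=min_split)
    imp = tree.predictor_importance()
    order = sorted(range(len(FEATURE_NAMES)), key=lambda i: (-imp[i], i))
    return ImportanceResult(
        importances={FEATURE_NAMES[i]: float(imp[i])
                     for i in range(len(FEATURE_NAMES))},
        ranking=[FEATURE_NAMES[i] for i in order],
    )


def stratified_folds(y: np.ndarray, k: int, seed: int,
                     max_redraws: int = 100) -> np.ndarray:
    """Fold assignment: seeded shuffle then round-robin per class.

    Redraws with an incremented sub-seed (logged) in the unlikely event
    a training split lacks both classes.
    """
    y = np.asarray(y, int)
    for attempt in range(max_redraws):
        rng = np.random.default_rng(seed + attempt)
        folds = np.empty(len(y), dtype=int)
        slot = 0
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            folds[idx] = (np.arange(len(idx)) + slot) % k
            slot += len(idx)
        ok = all(
            len(np.unique(y[folds != f])) == len(np.unique(y))
            for f in range(k)
        )
        if ok:
            if attempt:
                warnings.warn(
                    f"fold partition redrawn {attempt} time(s)", stacklevel=2,
                )
            return folds
    raise ValueError("could not produce folds with both classes in training")


def _cv_mse_once(X: np.ndarray, y: np.ndarray, folds: np.ndarray,
                 k_folds: int, tree_params: dict) -> float:
    pred = np.empty(len(y), dtype=int)
    for f in range(k_folds):
        train = folds != f
        tree = fit_cart(X[train], y[train], **tree_params)
        pred[~train] = tree.predict(X[~train])
    return float(np.mean((pred - y) ** 2))


def cv_mse_profile(table: FeatureTable, ranking: list[str],
                   cv: CVConfig = CVConfig(),
                   criterion: str = "gini",
                   min_split: int = 10) -> MSEProfile:
    """Incremental top-k CV error profile over the ranked features.

    For each seed, one fold partition is drawn and reused for every
    k = 1..n_features, so per-seed columns are comparable across k.
    With ``variant="IN"``, the ranking argument is ignored and the
    features are re-ranked within each training fold.
    """
    y = table.y
    frame = table.frame
    tree_params = dict(criterion=criterion, min_split=min_split)
    n_feat = len(ranking)
    rows = {}
    for seed in cv.seeds:
        folds = stratified_folds(y, cv.k_folds, seed)
        col = np.empty(n_feat)
        if cv.variant == "OUT":
            for k in range(1, n_feat + 1):
                X = frame.loc[:, ranking[:k]].to_numpy(float)
                col[k - 1] = _cv_mse_once(X, y, folds, cv.k_folds, tree_params)
        elif cv.variant == "IN":
            col[:] = 0.0
            pred = np.empty((n_feat, len(y)), dtype=int)
            for f in range(cv.k_folds):
                train = folds != f
                sub = FeatureTable(frame.loc[train].reset_index(drop=True))
                rank_f = estimate_importance(
                    sub, criterion=criterion, min_split=min_split).ranking
                for k in range(1, n_feat + 1):
                    X = frame.loc[:, rank_f[:k]].to_numpy(float)
                    tree = fit_cart(X[train], y[train], **tree_params)
                    pred[k - 1, ~train] = tree.predict(X[~train])
            for k in range(1, n_feat + 1):
                col[k - 1] = float(np.mean((pred[k - 1] - y) ** 2))
        else:
            raise ValueError(f"unknown CV variant {cv.variant!r}")
        rows[f"seed_{seed}"] = col
    out = pd.DataFrame(rows, index=pd.RangeIndex(1, n_feat + 1, name="k"))
    out["mean"] = out.mean(axis=1)
    # sample SD across seeds, matching the convention of reported SD rows
    out["sd"] = out.loc[:, [f"seed_{s}" for s in cv.seeds]].std(axis=1, ddof=1)
    return MSEProfile(out)


def select_optimal_set(profile: MSEProfile, ranking: list[str],
                       perf_by_k: pd.DataFrame | None = None) -> list[str]:
    """Choose the optimal feature subset from the MSE profile.

    Candidate sizes are all k whose mean MSE is within one SD (the SD at
    the minimising k) of the global minimum mean MSE; the smallest
    candidate wins. When ``perf_by_k`` (indexed by k, with an ``SE``
    column) is given, only candidates whose SE equals the best candidate
    SE are kept before taking the smallest — preferring fewer features
    (lower execution time) at equal sensitivity.
    """
    mean = profile.mean
    k_min = int(mean.idxmin())
    threshold = mean.loc[k_min] + profile.sd.loc[k_min]
    candidates = [int(k) for k in mean.index if mean.loc[k] <= threshold]
    if perf_by_k is not None:
        known = [k for k in candidates if k in perf_by_k.index]
        if known:
            best_se = max(perf_by_k.loc[k, "SE"] for k in known)
            candidates = [k for k in known
                          if perf_by_k.loc[k, "SE"] >= best_se - 1e-9]
    k_star = min(candidates)
    return ranking[:k_star]
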