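"""Random-forest prediction of three-class 1-year disease activity.

Feature matrices combine per-visit biomarker vectors with signed
later-minus-baseline deltas; models are evaluated with stratified 10-fold
cross-validation, an inner grid search over the number of trees (150-800,
step 50), and majority voting over trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .synthetic import FEATURE_NAMES

VARIANTS = ("two_metric", "four_metric", "six_metric")
HORIZONS = ("baseline", "month1", "month3")

_VARIANT_FEATURES = {
    "two_metric": ("ez_length_rate", "elm_length_rate"),
    "four_metric": tuple(f for f in FEATURE_NAMES
                         if not f.endswith("length_rate")),
    "six_metric": tuple(FEATURE_NAMES),
}
_HORIZON_BLOCKS = {
    "baseline": ("baseline",),
    "month1": ("baseline", "month1", "delta_m1"),
    "month3": ("baseline", "month1", "month3", "delta_m1", "delta_m3"),
}
_DELTA_SOURCE = {"delta_m1": "month1", "delta_m3": "month3"}


@dataclass(frozen=True)
class FeatureMatrixSpec:
    variant: str = "six_metric"
    horizon: str = "month3"

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.horizon not in HORIZONS:
            raise ValueError(f"horizon must be one of {HORIZONS}")


@dataclass
class ForestConfig:
    n_trees_grid: tuple[int, ...] = tuple(range(150, 801, 50))
    cv_folds: int = 10
    seed: int = 0
    class_weight: str | None = None
    inner_val_fraction: float = 0.25

    def validate(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if any(t < 150 or t > 800 for t in self.n_trees_grid):
            raise ValueError("n_trees grid must lie in [150, 800]")


@dataclass
class PredMetricsReport:
    auc_macro: float
    auc_per_class: dict[int, float]
    accuracy: float
    sensitivity_macro: float
    specificity_macro: float
    importances: pd.Series            # normalized to sum 1, descending
    selected_n_trees: list[int]
    oof_proba: np.ndarray
    oof_pred: np.ndarray
    labels: np.ndarray
    metadata: dict = field(default_factory=dict)


def build_feature_matrix(table: pd.DataFrame, labels: pd.Series,
                         spec: FeatureMatrixSpec
                         ) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Wide per-eye matrix: one block of columns per visit plus delta blocks.

    Missing intensity cells are imputed as 0 with an indicator column per
    affected visit-block feature; deltas use the imputed values.
    """
    spec.validate()
    feats = list(_VARIANT_FEATURES[spec.variant])
    blocks = _HORIZON_BLOCKS[spec.horizon]
    visits_needed = [b for b in blocks if not b.startswith("delta")]

    wide = {}
    for visit in visits_needed:
        sub = table[table["visit"] == visit].set_index("eye_id")[feats]
        missing_eyes = labels.index.difference(sub.index)
        if len(missing_eyes):
            raise ValueError(
                f"missing visit {visit!r} for eyes: {sorted(missing_eyes)}")
        wide[visit] = sub.loc[labels.index]

    cols: dict[str, np.ndarray] = {}
    indicators: dict[str, np.ndarray] = {}
    imputed = {}
    for visit in visits_needed:
        block = wide[visit]
        filled = block.fillna(0.0)
        imputed[visit] = filled
        for f in feats:
            cols[f"{visit}:{f}"] = filled[f].to_numpy(dtype=float)
            if block[f].isna().any():
                indicators[f"{visit}:{f}:missing"] = \
                    block[f].isna().to_numpy(dtype=float)
    for blk in blocks:
        if blk.startswith("delta"):
            src = _DELTA_SOURCE[blk]
            for f in feats:
                cols[f"{blk}:{f}"] = (imputed[src][f] -
                                      imputed["baseline"][f]).to_numpy(float)
    # deterministic order: visit blocks then features, indicators last
    ordered = [f"{b}:{f}" for b in blocks for f in feats]
    x = pd.DataFrame({c: cols[c] for c in ordered}, index=labels.index)
    for name, vals in indicators.items():
        x[name] = vals
    y = labels.to_numpy(dtype=int)
    if not set(np.unique(y)) <= {0, 1, 2}:
        raise ValueError("labels must be in {0, 1, 2}")
    return x, y, list(x.columns)


def _majority_vote_proba(forest: RandomForestClassifier,
                         x: np.ndarray) -> np.ndarray:
    """Per-class vote share over trees (argmax = majority-vote prediction)."""
    classes = forest.classes_
    votes = np.zeros((x.shape[0], classes.size))
    for tree in forest.estimators_:
        pred = tree.predict(x)
        for k, c in enumerate(classes):
            votes[:, k] += pred == c
    return votes / len(forest.estimators_)


def _ovr_metrics(y: np.ndarray, pred: np.ndarray, proba: np.ndarray,
                 classes: np.ndarray) -> dict:
    per_auc = {}
    for k, c in enumerate(classes):
        per_auc[int(c)] = float(roc_auc_score(y == c, proba[:, k]))
    sens, spec = [], []
    for c in classes:
        tp = np.sum((pred == c) & (y == c))
        fn = np.sum((pred != c) & (y == c))
        tn = np.sum((pred != c) & (y != c))
        fp = np.sum((pred == c) & (y != c))
        sens.append(tp / (tp + fn) if tp + fn else np.nan)
        spec.append(tn / (tn + fp) if tn + fp else np.nan)
    return {
        "auc_macro": float(np.mean(list(per_auc.values()))),
        "auc_per_class": per_auc,
        "accuracy": float(np.mean(pred == y)),
        "sensitivity_macro": float(np.nanmean(sens)),
        "specificity_macro": float(np.nanmean(spec)),
    }


def fit_predict_cv(x: pd.DataFrame | np.ndarray, y: np.ndarray,
                   config: ForestConfig | None = None,
                   column_names: list[str] | None = None
                   ) -> PredMetricsReport:
    """Stratified CV with nested grid search over the number of trees."""
    config = config or ForestConfig()
    config.validate()
    if isinstance(x, pd.DataFrame):
        column_names = list(x.columns)
        x = x.to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    if y.size < config.cv_folds:
        raise ValueError(f"n={y.size} smaller than cv_folds={config.cv_folds}")

    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed)
    oof_proba = np.zeros((y.size, classes.size))
    oof_pred = np.zeros(y.size, dtype=int)
    importances = np.zeros(x.shape[1])
    selected = []
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        xtr, ytr = x[tr], y[tr]
        try:
            itr, ival = train_test_split(
                np.arange(tr.size), test_size=config.inner_val_fraction,
                stratify=ytr, random_state=config.seed + fold)
        except ValueError:   # a class too small to stratify the inner split
            itr, ival = train_test_split(
                np.arange(tr.size), test_size=config.inner_val_fraction,
                random_state=config.seed + fold)
        best_auc, best_n = -np.inf, config.n_trees_grid[0]
        for n_trees in config.n_trees_grid:
            rf = RandomForestClassifier(
                n_estimators=n_trees, random_state=config.seed,
                class_weight=config.class_weight, n_jobs=1)
            rf.fit(xtr[itr], ytr[itr])
            proba = _majority_vote_proba(rf, xtr[ival])
            yv = ytr[ival]
            aucs = [roc_auc_score(yv == c, proba[:, k])
                    for k, c in enumerate(rf.classes_)
                    if 0 < np.sum(yv == c) < yv.size]
            # degenerate inner split: fall back to vote accuracy
            auc = float(np.mean(aucs)) if aucs else float(
                np.mean(rf.classes_[proba.argmax(axis=1)] == yv))
            if auc > best_auc:
                best_auc, best_n = auc, n_trees
        rf = RandomForestClassifier(
            n_estimators=best_n, random_state=config.seed,
            class_weight=config.class_weight, n_jobs=1)
        rf.fit(xtr, ytr)
        proba = _majority_vote_proba(rf, x[te])
        oof_proba[te] = proba
        oof_pred[te] = rf.classes_[proba.argmax(axis=1)]
        importances += rf.feature_importances_
        selected.append(best_n)

    importances /= importances.sum() if importances.sum() > 0 else 1.0
    names = column_names or [f"f{i}" for i in range(x.shape[1])]
    imp = pd.Series(importances, index=names).sort_values(ascending=False)
    stats = _ovr_metrics(y, oof_pred, oof_proba, classes)
    return PredMetricsReport(
        importances=imp, selected_n_trees=selected,
        oof_proba=oof_proba, oof_pred=oof_pred, labels=y,
        metadata={"cv_folds": config.cv_folds, "seed": config.seed,
                  "grid": list(config.n_trees_grid),
                  "grid_search": "nested, inner stratified split",
                  "vote": "majority over trees"},
        **stats)


def rank_feature_importance(report: PredMetricsReport,
                            top_k: int | None = None) -> pd.Series:
    """Normalized impurity importances averaged over folds, descending."""
    if report.importances.empty:
        raise ValueError("report carries no fitted importances")
    imp = report.importances / report.importances.sum()
    return imp.head(top_k) if top_k else imp


def compare_variants(table: pd.DataFrame, labels: pd.Series,
                     config: ForestConfig | None = None
                     ) -> dict[tuple[str, str], PredMetricsReport]:
    """All 9 variant x horizon reports with identical folds and seed."""
    config = config or ForestConfig()
    out = {}
    for variant in VARIANTS:
        for horizon in HORIZONS:
            x, y, names = build_feature_matrix(
                table, labels, FeatureMatrixSpec(variant, horizon))
            out[(variant, horizon)] = fit_predict_cv(x, y, config, names)
    return out


def variant_table(reports: dict[tuple[str, str], PredMetricsReport]
                  ) -> pd.DataFrame:
    """Table-shaped summary: metric rows, variant x horizon columns."""
    cols = {}
    for (variant, horizon), rep in reports.items():
        cols[f"{variant}/{horizon}"] = {
            "AUC": rep.auc_macro, "Accuracy": rep.accuracy,
            "Sensitivity": rep.sensitivity_macro,
            "Specificity": rep.specificity_macro}
    return pd.DataFrame(cols)
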