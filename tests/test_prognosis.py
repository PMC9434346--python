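import numpy as np
import pandas as pd
import pytest

from retquant.prognosis import (FeatureMatrixSpec, ForestConfig,
                                build_feature_matrix, compare_variants,
                                fit_predict_cv, rank_feature_importance,
                                variant_table)
from retquant.synthetic import FEATURE_NAMES


def _toy_table(n_eyes=30, seed=0, signal="ez"):
    """Small feature table whose label depends on the month-3 EZ rate."""
    rng = np.random.default_rng(seed)
    rows, labels = [], {}
    for i in range(n_eyes):
        eye = f"e{i:03d}"
        label = int(rng.integers(0, 3))
        labels[eye] = label
        for visit in ("baseline", "month1", "month3", "month12"):
            row = {"eye_id": eye, "visit": visit}
            for f in FEATURE_NAMES:
                row[f] = float(rng.random())
            if signal == "ez" and visit == "month3":
                row["ez_length_rate"] = {0: 0.75, 1: 0.35, 2: 1.0}[label] \
                    + rng.normal(0, 0.02)
            rows.append(row)
    return pd.DataFrame(rows), pd.Series(labels, name="label")


class TestFeatureMatrix:
    def test_six_metric_month3_60_columns(self):
        table, labels = _toy_table(12)
        x, y, names = build_feature_matrix(
            table, labels, FeatureMatrixSpec("six_metric", "month3"))
        assert x.shape[1] == 60 and len(names) == 60

    def test_two_metric_baseline(self):
        table, labels = _toy_table(12)
        x, _y, _n = build_feature_matrix(
            table, labels, FeatureMatrixSpec("two_metric", "baseline"))
        assert x.shape[1] == 2

    def test_four_metric_has_ten_base_features(self):
        table, labels = _toy_table(12)
        x, _y, _n = build_feature_matrix(
            table, labels, FeatureMatrixSpec("four_metric", "baseline"))
        assert x.shape[1] == 10

    def test_zero_deltas_for_identical_visits(self):
        table, labels = _toy_table(6)
        base = table[table.visit == "baseline"].copy()
        m1 = base.copy()
        m1["visit"] = "month1"
        dup = pd.concat([base, m1], ignore_index=True)
        x, _y, names = build_feature_matrix(
            dup, labels, FeatureMatrixSpec("six_metric", "month1"))
        delta_cols = [c for c in names if c.startswith("delta_m1")]
        assert len(delta_cols) == 12
        assert np.allclose(x[delta_cols].to_numpy(), 0.0)

    def test_missing_visit_lists_eyes(self):
        table, labels = _toy_table(5)
        table = table[~((table.eye_id == "e001") & (table.visit == "month1"))]
        with pytest.raises(ValueError, match="e001"):
            build_feature_matrix(table, labels,
                                 FeatureMatrixSpec("six_metric", "month1"))

    def test_nan_intensity_imputed_with_indicator(self):
        table, labels = _toy_table(8)
        table.loc[table.index[0], "ped_mean_intensity"] = np.nan
        x, _y, names = build_feature_matrix(
            table, labels, FeatureMatrixSpec("six_metric", "baseline"))
        missing = [c for c in names if c.endswith(":missing")]
        assert len(missing) == 1
        assert not x.isna().any().any()

    def test_bad_variant(self):
        with pytest.raises(ValueError, match="variant"):
            FeatureMatrixSpec("five_metric", "month3").validate()


def _fast_config(**kw):
    kw.setdefault("n_trees_grid", (150, 200))
    kw.setdefault("cv_folds", 5)
    kw.setdefault("seed", 0)
    return ForestConfig(**kw)


class TestFitPredictCv:
    def test_signal_recovery(self):
        table, labels = _toy_table(60, seed=1)
        x, y, names = build_feature_matrix(
            table, labels, FeatureMatrixSpec("six_metric", "month3"))
        # one signal column among 60: feature subsampling caps accuracy,
        # so the floor here is softer than on the fully planted cohort
        rep = fit_predict_cv(x, y, _fast_config())
        assert rep.accuracy >= 0.75
        assert rep.auc_macro >= 0.9

    def test_permutation_null(self):
        table, labels = _toy_table(60, seed=2)
        x, y, _n = build_feature_matrix(
            table, labels, FeatureMatrixSpec("six_metric", "month3"))
        aucs = []
        rng = np.random.default_rng(0)
        for rep_i in range(3):
            yp = rng.permutation(y)
            if np.unique(yp).size < 2:
                continue
            rep = fit_predict_cv(x, yp, _fast_config(seed=rep_i))
            aucs.append(rep.auc_macro)
        assert 0.35 <= float(np.mean(aucs)) <= 0.65

    def test_single_class_error(self):
        x = np.random.default_rng(0).random((20, 4))
        with pytest.raises(ValueError, match="single class"):
            fit_predict_cv(x, np.zeros(20, int), _fast_config())

    def test_n_smaller_than_folds_error(self):
        x = np.random.default_rng(0).random((4, 3))
        with pytest.raises(ValueError, match="cv_folds"):
            fit_predict_cv(x, np.array([0, 1, 2, 0]),
                           _fast_config(cv_folds=10))

    def test_reproducible_under_seed(self):
        table, labels = _toy_table(40, seed=3)
        x, y, _n = build_feature_matrix(
            table, labels, FeatureMatrixSpec("two_metric", "month3"))
        a = fit_predict_cv(x, y, _fast_config())
        b = fit_predict_cv(x, y, _fast_config())
        assert a.auc_macro == b.auc_macro
        assert np.array_equal(a.oof_pred, b.oof_pred)

    def test_grid_bounds_validated(self):
        with pytest.raises(ValueError, match="grid"):
            ForestConfig(n_trees_grid=(100,)).validate()


class TestImportance:
    def test_sums_to_one_and_ez_ranks_first(self):
        table, labels = _toy_table(60, seed=4)
        x, y, names = build_feature_matrix(
            table, labels, FeatureMatrixSpec("six_metric", "month3"))
        rep = fit_predict_cv(x, y, _fast_config(), names)
        imp = rank_feature_importance(rep)
        assert imp.sum() == pytest.approx(1.0)
        assert "ez" in imp.index[0] or "elm" in imp.index[0]

    def test_top_k(self):
        table, labels = _toy_table(40, seed=5)
        x, y, names = build_feature_matrix(
            table, labels, FeatureMatrixSpec("six_metric", "baseline"))
        rep = fit_predict_cv(x, y, _fast_config(), names)
        assert len(rank_feature_importance(rep, top_k=5)) == 5


class TestCompareVariants:
    def test_grid_of_nine(self):
        table, labels = _toy_table(24, seed=6)
        reports = compare_variants(
            table, labels, _fast_config(cv_folds=3, n_trees_grid=(150,)))
        assert len(reports) == 9
        tbl = variant_table(reports)
        assert tbl.shape == (4, 9)

    def test_six_beats_four_with_ez_signal(self):
        table, labels = _toy_table(45, seed=7)
        reports = compare_variants(
            table, labels, _fast_config(cv_folds=3, n_trees_grid=(150,)))
        for horizon in ("month3",):
            assert reports[("six_metric", horizon)].auc_macro >= \
                reports[("four_metric", horizon)].auc_macro
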