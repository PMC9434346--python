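import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retquant.metrics import (aggregate_average, bootstrap_ci,
                              class_proportions, confusion_metrics, dice,
                              evaluate_predictions, label_proportions)


class TestDice:
    def test_identical_nonempty(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 3:8] = True
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros(20, bool)
        b = np.zeros(20, bool)
        a[:5] = True
        b[10:] = True
        assert dice(a, b) == 0.0

    def test_nested_square(self):
        # oracle: pred 4 px inside true 8 px -> 2*4/(4+8)
        true = np.zeros((6, 6), bool)
        true[0:2, 0:4] = True          # 8 px
        pred = np.zeros((6, 6), bool)
        pred[0:2, 0:2] = True          # 4 px, fully inside
        assert dice(pred, true) == pytest.approx(2 * 4 / (4 + 8))

    def test_both_empty_is_one(self):
        assert dice(np.zeros(5, bool), np.zeros(5, bool)) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    @given(st.integers(0, 2**20))
    @settings(max_examples=50, deadline=None)
    def test_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(40) < 0.4
        b = rng.random(40) < 0.4
        assert dice(a, b) == dice(b, a)


class TestConfusionMetrics:
    def test_perfect(self):
        v = np.array([1, 0, 1, 1, 0], bool)
        assert confusion_metrics(v, v) == (1.0, 1.0, 1.0)

    def test_stated_counts(self):
        # oracle: TP=8 FN=2 TN=85 FP=5, counted directly
        truth = np.array([1] * 10 + [0] * 90, bool)
        pred = np.array([1] * 8 + [0] * 2 + [0] * 85 + [1] * 5, bool)
        acc, sen, spe = confusion_metrics(pred, truth)
        assert acc == pytest.approx(0.93)
        assert sen == pytest.approx(0.8)
        assert spe == pytest.approx(85 / 90)

    def test_all_negative_truth_sensitivity_nan(self):
        truth = np.zeros(10, bool)
        pred = np.zeros(10, bool)
        _acc, sen, _spe = confusion_metrics(pred, truth)
        assert np.isnan(sen)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_metrics(np.zeros(3, bool), np.zeros(4, bool))

    @given(st.integers(0, 2**20))
    @settings(max_examples=100, deadline=None)
    def test_prevalence_decomposition(self, seed):
        # accuracy = prev*sensitivity + (1-prev)*specificity
        rng = np.random.default_rng(seed)
        truth = rng.random(200) < rng.uniform(0.1, 0.9)
        if not truth.any() or truth.all():
            return
        pred = rng.random(200) < 0.5
        acc, sen, spe = confusion_metrics(pred, truth)
        prev = truth.mean()
        assert acc == pytest.approx(prev * sen + (1 - prev) * spe)


class TestBootstrapCI:
    def test_constant_samples(self):
        lo, hi = bootstrap_ci(np.full(20, 0.7), seed=0)
        assert lo == pytest.approx(0.7) and hi == pytest.approx(0.7)

    def test_contains_mean(self):
        rng = np.random.default_rng(0)
        s = rng.random(50)
        lo, hi = bootstrap_ci(s, n_boot=1000, seed=1)
        assert lo <= s.mean() <= hi

    def test_empty_error(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([]))

    def test_seeded(self):
        s = np.random.default_rng(2).random(30)
        assert bootstrap_ci(s, seed=7) == bootstrap_ci(s, seed=7)

    def test_coverage_monte_carlo(self):
        # oracle: empirical coverage of p=0.9 for Bernoulli means
        rng = np.random.default_rng(0)
        covered = 0
        n_rep = 200
        for rep in range(n_rep):
            s = (rng.random(200) < 0.9).astype(float)
            lo, hi = bootstrap_ci(s, n_boot=2000, seed=rep)
            covered += lo <= 0.9 <= hi
        assert 0.90 <= covered / n_rep <= 0.99


class TestAggregation:
    def test_dice_avg_row(self):
        assert aggregate_average([0.949, 0.892, 0.810, 0.840]) == 0.873

    def test_sensitivity_avg_row(self):
        vals = [0.813, 0.887, 0.798, 0.886, 0.934, 0.918]
        assert aggregate_average(vals) == 0.873

    def test_specificity_avg_row(self):
        vals = [0.998, 0.998, 0.996, 0.996, 0.858, 0.688]
        assert aggregate_average(vals) == 0.922

    def test_identical(self):
        assert aggregate_average([0.5, 0.5, 0.5]) == 0.5

    def test_empty_error(self):
        with pytest.raises(ValueError):
            aggregate_average([])


class TestClassProportions:
    def test_paper_counts(self):
        assert class_proportions([66, 47, 29]) == [46.48, 33.10, 20.42]

    def test_single_class(self):
        assert class_proportions([10, 0, 0]) == [100.00, 0.00, 0.00]

    def test_thirds(self):
        assert class_proportions([1, 1, 1]) == [33.33, 33.33, 33.33]

    def test_empty_error(self):
        with pytest.raises(ValueError):
            class_proportions([])

    def test_label_form(self):
        pct = label_proportions([0, 0, 1, 2])
        assert pct == {0: 50.0, 1: 25.0, 2: 25.0}


class TestReport:
    def test_report_layout(self):
        rng = np.random.default_rng(0)
        per_scan = {}
        for bio in ("IRF", "SRF", "SHRM", "PED", "EZ", "ELM"):
            pairs = []
            for _ in range(4):
                t = rng.random(100) < 0.3
                p = t ^ (rng.random(100) < 0.05)
                pairs.append((p, t))
            per_scan[bio] = pairs
        rep = evaluate_predictions(per_scan, n_boot=200, seed=0)
        assert list(rep.table.columns) == ["IRF", "SRF", "SHRM", "PED",
                                           "EZ", "ELM", "AVG"]
        # dice N/A for the linear layers, as in the report layout
        assert np.isnan(rep.table.loc["dice", "EZ"])
        assert np.isnan(rep.table.loc["dice", "ELM"])
        assert rep.table.loc["accuracy"].dropna().between(0, 1).all()
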