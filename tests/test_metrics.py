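import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from salpvote.errors import DataFormatError
from salpvote.metrics import (
    clopper_pearson,
    compute_metrics,
    confusion_counts,
    f_beta,
    macro_ovr_auc,
)


class TestConfusionCounts:
    def test_perfect_three_class(self):
        y = np.repeat([0, 1, 2], 3)
        counts = confusion_counts(y, y)
        for tp, fp, tn, fn in counts.per_class.values():
            assert fp == 0 and fn == 0 and tp + tn == 9

    def test_hand_counted_example(self):
        counts = confusion_counts(["A", "A", "B"], ["A", "B", "B"])
        tp, fp, tn, fn = counts.per_class["A"]
        assert (tp, fp, tn, fn) == (1, 0, 1, 1)

    def test_counts_sum_to_n_per_class(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 50)
        y_pred = rng.integers(0, 4, 50)
        counts = confusion_counts(y_true, y_pred)
        for quad in counts.per_class.values():
            assert sum(quad) == 50

    def test_unknown_label_rejected(self):
        with pytest.raises(DataFormatError):
            confusion_counts([0, 1], [0, 2], classes=[0, 1])


class TestFBeta:
    def test_reported_precision_recall_pairs(self):
        # published worked examples, rounded to 3 decimals
        assert round(f_beta(0.949, 0.974, beta=1), 3) == 0.961
        assert round(f_beta(0.938, 0.957, beta=2), 3) == 0.953

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.01, 1.0), st.floats(0.1, 10.0))
    def test_identity_when_precision_equals_recall(self, x, beta):
        assert f_beta(x, x, beta) == pytest.approx(x)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_f1_between_min_and_max(self, p, r):
        f1 = f_beta(p, r, 1.0)
        assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12

    def test_zero_convention(self):
        assert f_beta(0.0, 0.0, 2.0) == 0.0


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.repeat([0, 1, 2], 4)
        rep = compute_metrics(y, y)
        assert rep.ACC == 1.0 and rep.MCR == 0.0 and rep.MCC == 1.0
        assert rep.FNR == 0.0 and rep.FPR == 0.0

    def test_identities_exact_on_random_predictions(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        rep = compute_metrics(y_true, y_pred)
        assert rep.ACC + rep.MCR == pytest.approx(1.0, abs=1e-12)
        assert rep.FNR == pytest.approx(1.0 - rep.REC, abs=1e-12)
        assert rep.FPR == pytest.approx(1.0 - rep.SPE, abs=1e-12)

    def test_absent_class_excluded_from_macro(self):
        # class 2 never appears in the truth: macro averages skip it
        rep = compute_metrics([0, 0, 1, 1], [0, 1, 1, 2], classes=[0, 1, 2])
        assert set(rep.per_class) == {0, 1}

    def test_per_class_mcc_matches_sklearn_binarized(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y_true = rng.integers(0, 3, 40)
            y_pred = rng.integers(0, 3, 40)
            rep = compute_metrics(y_true, y_pred)
            for c, m in rep.per_class.items():
                expected = matthews_corrcoef(y_true == c, y_pred == c)
                assert m["MCC"] == pytest.approx(expected, abs=1e-12)

    def test_ci_attached_for_proportion_metrics(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 2, 30)
        y_pred = rng.integers(0, 2, 30)
        rep = compute_metrics(y_true, y_pred)
        lo, hi = rep.ci["ACC"]
        assert lo <= rep.ACC <= hi


class TestClopperPearson:
    def test_boundary_endpoints(self):
        lo0, _ = clopper_pearson(0, 10, 0.95)
        _, hi1 = clopper_pearson(10, 10, 0.95)
        assert lo0 == 0.0 and hi1 == 1.0

    def test_zero_successes_upper_closed_form(self):
        # P(X = 0) = (1 - p)^n = alpha/2  =>  upper = 1 - (alpha/2)^(1/n)
        _, hi = clopper_pearson(0, 10, 0.95)
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-10)

    def test_interval_contains_point_estimate(self):
        for n in (5, 20, 100):
            for k in range(0, n + 1, max(1, n // 5)):
                lo, hi = clopper_pearson(k, n, 0.95)
                assert lo <= k / n <= hi

    def test_width_shrinks_with_n_at_fixed_proportion(self):
        widths = []
        for n in (10, 40, 160, 640):
            lo, hi = clopper_pearson(n // 2, n, 0.95)
            widths.append(hi - lo)
        assert all(b < a for a, b in zip(widths, widths[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(11, 10, 0.95)
        with pytest.raises(ValueError):
            clopper_pearson(1, 10, 1.5)


class TestMacroOvrAuc:
    def test_perfectly_separating_scores(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        assert macro_ovr_auc(y, scores) == 1.0

    def test_constant_scores_half(self):
        y = np.array([0, 1, 0, 1])
        assert macro_ovr_auc(y, np.full((4, 2), 0.5)) == 0.5

    def test_four_sample_pair_enumeration(self):
        # positives ranked 1st and 3rd: 3 of 4 positive-negative pairs won
        y = np.array([1, 0, 1, 0])
        scores = np.column_stack([1 - np.array([0.9, 0.8, 0.4, 0.3]),
                                  [0.9, 0.8, 0.4, 0.3]])
        assert macro_ovr_auc(y, scores, classes=[0, 1]) == pytest.approx(0.75)

    def test_matches_sklearn_on_random_scores(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 3, 60)
        raw = rng.uniform(size=(60, 3))
        scores = raw / raw.sum(axis=1, keepdims=True)
        expected = roc_auc_score(y, scores, multi_class="ovr", average="macro")
        assert macro_ovr_auc(y, scores, classes=[0, 1, 2]) == pytest.approx(expected)

    def test_absent_class_excluded_with_warning(self):
        y = np.array([0, 0, 1, 1])
        scores = np.random.default_rng(5).uniform(size=(4, 3))
        with pytest.warns(UserWarning):
            macro_ovr_auc(y, scores, classes=[0, 1, 2])
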