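import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import actithigh as at
from actithigh.evaluation import ConfusionMatrix
from actithigh.taxonomy import OTHER_CLASS

CLASSES = ("sitting", "walking", "standing")


def _random_streams(seed, n=200, classes=CLASSES):
    rng = np.random.default_rng(seed)
    return rng.choice(classes, n), rng.choice(classes, n)


class TestConfusion:
    def test_perfect_agreement_is_diagonal(self):
        truth = np.array(["sitting", "walking", "walking", "standing"])
        cm = at.confusion(truth, truth, CLASSES)
        assert np.array_equal(cm.counts, np.diag([1, 2, 1]))

    def test_empty_vectors_give_zero_matrix(self):
        cm = at.confusion([], [], CLASSES)
        assert cm.counts.sum() == 0 and cm.counts.shape == (3, 3)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="not in class list"):
            at.confusion(["sitting"], ["flying"], CLASSES)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_brute_force_pair_counting(self, seed):
        truth, pred = _random_streams(seed)
        cm = at.confusion(truth, pred, CLASSES)
        for i, ci in enumerate(CLASSES):
            for j, cj in enumerate(CLASSES):
                brute = sum(1 for t, p in zip(truth, pred) if t == ci and p == cj)
                assert cm.counts[i, j] == brute
        assert cm.total == len(truth)


class TestClassMetrics:
    def test_perfect_diagonal_gives_unit_metrics(self):
        cm = ConfusionMatrix(CLASSES, np.diag([5, 7, 3]))
        for c in CLASSES:
            m = at.class_metrics(cm, c)
            assert m.sensitivity == m.ppv == m.f_measure == 1.0

    def test_absent_class_warns_and_reports_zero(self):
        cm = ConfusionMatrix(CLASSES, np.array([[5, 0, 0], [0, 7, 0], [0, 0, 0]]))
        with pytest.warns(UserWarning, match="standing"):
            m = at.class_metrics(cm, "standing")
        assert m.f_measure == 0.0 and not np.isnan(m.f_measure)

    def test_unknown_class_rejected(self):
        cm = ConfusionMatrix(CLASSES, np.diag([1, 1, 1]))
        with pytest.raises(KeyError):
            at.class_metrics(cm, "cycling")

    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_brute_force_tp_fp_fn(self, seed):
        truth, pred = _random_streams(seed)
        cm = at.confusion(truth, pred, CLASSES)
        for c in CLASSES:
            tp = sum(1 for t, p in zip(truth, pred) if t == c and p == c)
            fn = sum(1 for t, p in zip(truth, pred) if t == c and p != c)
            fp = sum(1 for t, p in zip(truth, pred) if t != c and p == c)
            m = at.class_metrics(cm, c)
            assert m.sensitivity == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)
            assert m.ppv == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)


class TestMacroF:
    def test_symmetric_two_class_matrix(self):
        cm = ConfusionMatrix(("sitting", "walking"), np.array([[8, 2], [2, 8]]))
        f = at.class_metrics(cm, "sitting").f_measure
        assert at.macro_f(cm) == pytest.approx(f)

    def test_unweighted_over_classes(self):
        cm = ConfusionMatrix(CLASSES, np.array([[100, 0, 0], [0, 1, 1], [0, 1, 1]]))
        fs = [at.class_metrics(cm, c).f_measure for c in CLASSES]
        assert at.macro_f(cm) == pytest.approx(np.mean(fs))


class TestMerge:
    scheme = at.five_class_scheme()

    def test_within_group_confusion_vanishes(self):
        truth, pred = at.merge(["sitting"], ["lying"], self.scheme)
        assert list(truth) == ["sedentary"] and list(pred) == ["sedentary"]

    def test_excluded_truth_samples_dropped(self):
        truth, pred = at.merge(["driving", "walking"], ["driving", "walking"], self.scheme)
        assert list(truth) == ["walking"]

    def test_identity_scheme_is_noop(self):
        t0 = ["sitting", "running", "driving"]
        truth, pred = at.merge(t0, t0, at.identity_scheme())
        assert list(truth) == t0 and list(pred) == t0

    def test_retained_sample_predicted_excluded_becomes_other(self):
        truth, pred = at.merge(["walking"], ["driving"], self.scheme)
        assert list(pred) == [OTHER_CLASS]
        cm = at.merged_confusion(["walking", "running"], ["driving", "running"], self.scheme)
        assert OTHER_CLASS in cm.classes
        with pytest.warns(UserWarning, match="walking"):
            assert at.class_metrics(cm, "walking").sensitivity == 0.0

    def test_merging_never_increases_grand_total(self):
        truth, pred = _random_streams(3, classes=at.FINE_CLASSES)
        cm_fine = at.confusion(truth, pred, at.FINE_CLASSES)
        cm_coarse = at.merged_confusion(truth, pred, self.scheme)
        assert cm_coarse.total <= cm_fine.total

    def test_merging_within_group_confusions_raises_macro_f(self):
        # all confusion is sitting<->lying, which the scheme collapses
        truth = ["sitting"] * 10 + ["lying"] * 10 + ["running"] * 10
        pred = ["lying"] * 10 + ["sitting"] * 10 + ["running"] * 10
        fine = at.confusion(truth, pred, ("sitting", "lying", "running"))
        coarse = at.merged_confusion(truth, pred, self.scheme)
        assert at.macro_f(coarse) >= at.macro_f(fine)
        assert at.macro_f(coarse) == pytest.approx(1.0)


class TestDurationError:
    def test_perfect_prediction_zero_error(self):
        truth = ["walking"] * 100 + ["sitting"] * 50
        for c in ("walking", "sitting"):
            assert at.duration_error(truth, truth, c).error == 0.0

    def test_overprediction_by_half(self):
        truth = ["walking"] * 200 + ["sitting"] * 100
        pred = ["walking"] * 300
        de = at.duration_error(truth, pred, "walking", dt_s=0.5)
        assert de.duration_gt == pytest.approx(100.0)
        assert de.duration_alg == pytest.approx(150.0)
        assert de.error == pytest.approx(0.5)

    def test_error_can_exceed_one(self):
        truth = ["walking"] * 10 + ["sitting"] * 90
        pred = ["walking"] * 100
        assert at.duration_error(truth, pred, "walking").error == pytest.approx(9.0)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError):
            at.duration_error(["sitting"], ["sitting"], "walking")

    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_brute_force_recount(self, seed):
        truth, pred = _random_streams(seed)
        for c in CLASSES:
            if not (truth == c).any():
                continue
            de = at.duration_error(truth, pred, c, dt_s=0.5)
            gt = 0.5 * sum(1 for t in truth if t == c)
            alg = 0.5 * sum(1 for p in pred if p == c)
            assert de.error == pytest.approx(abs(alg - gt) / gt)


@pytest.fixture(scope="module")
def small_dataset():
    rng = np.random.default_rng(0)
    means = {"sitting": 0.0, "walking": 4.0, "running": 8.0}
    X = np.vstack([rng.normal(m, 1.0, (40, 24)) for m in means.values()])
    y = np.array(sum(([c] * 40 for c in means), []))
    return X, y


class TestStratifiedKFold:
    def test_pooled_matrix_conserves_class_counts(self, small_dataset):
        X, y = small_dataset
        cm = at.stratified_kfold(X, y, k=5, seed=0, n_trees=20)
        for c in cm.classes:
            assert cm.counts[cm.index(c), :].sum() == (y == c).sum()
        assert cm.total == len(y)

    def test_fold_stratification_contract(self, small_dataset):
        from sklearn.model_selection import StratifiedKFold

        X, y = small_dataset
        sizes, per_class = [], []
        for _, te in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y):
            sizes.append(len(te))
            per_class.append([np.sum(y[te] == c) for c in np.unique(y)])
        assert max(sizes) - min(sizes) <= 1
        per_class = np.array(per_class)
        assert (per_class.max(0) - per_class.min(0) <= 1).all()

    def test_thin_class_rejected_by_name(self, small_dataset):
        X, y = small_dataset
        y = y.copy()
        y[:3] = "cycling"  # only 3 members
        with pytest.raises(ValueError, match="cycling"):
            at.stratified_kfold(X[: len(y)], y, k=5)

    def test_separable_data_scores_high(self, small_dataset):
        X, y = small_dataset
        cm = at.stratified_kfold(X, y, k=5, seed=0, n_trees=20)
        assert at.macro_f(cm) >= 0.95
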