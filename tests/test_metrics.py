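"""Confusion metrics and ROC analysis with carcinoma as the positive class."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import adrenomir as am


def brute_force_auc(scores, truth, positive="ACC"):
    """Mann-Whitney oracle: P(score_pos > score_neg) + 1/2 P(equal)."""
    pos = [s for k, s in scores.items() if truth[k] == positive]
    neg = [s for k, s in scores.items() if truth[k] != positive]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_best_model_style_counts(self):
        # 20/22 sensitivity and 20/21 specificity
        m = am.ConfusionMetrics(tp=20, fn=2, tn=20, fp=1)
        assert 100 * m.sensitivity == pytest.approx(90.91, abs=0.005)
        assert 100 * m.specificity == pytest.approx(95.24, abs=0.005)

    def test_all_correct_gives_all_hundred(self):
        m = am.ConfusionMetrics(tp=21, fp=0, tn=22, fn=0)
        assert m.sensitivity == m.specificity == m.ppv == m.npv == 1.0

    def test_all_inverted_gives_zero_sensitivity_and_specificity(self):
        m = am.ConfusionMetrics(tp=0, fp=22, tn=0, fn=21)
        assert m.sensitivity == 0.0
        assert m.specificity == 0.0

    def test_undefined_denominator_flagged_not_zero(self):
        m = am.ConfusionMetrics(tp=0, fp=0, tn=5, fn=0)
        assert m.ppv is None
        assert m.sensitivity is None
        assert m.specificity == 1.0

    def test_confusion_from_calls_enumerated_grids(self):
        """Hand-count oracle over every call/truth assignment of 4 samples."""
        samples = ["a", "b", "c", "d"]
        for truth_bits in itertools.product([0, 1], repeat=4):
            if len(set(truth_bits)) < 2:
                continue  # need both classes in the truth
            truth = {s: ("ACC" if b else "ACA")
                     for s, b in zip(samples, truth_bits)}
            for call_bits in itertools.product([0, 1], repeat=4):
                calls = {s: ("ACC" if b else "ACA")
                         for s, b in zip(samples, call_bits)}
                m = am.confusion_from_calls(calls, truth)
                tp = sum(c and t for c, t in zip(call_bits, truth_bits))
                fp = sum(c and not t for c, t in zip(call_bits, truth_bits))
                tn = sum((not c) and (not t) for c, t in zip(call_bits, truth_bits))
                fn = sum((not c) and t for c, t in zip(call_bits, truth_bits))
                assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)
                assert m.n_scored == 4

    def test_indeterminate_counted_separately(self):
        truth = {"a": "ACC", "b": "ACA", "c": "ACC"}
        calls = {"a": "ACC", "b": "ACA", "c": "INDETERMINATE"}
        m = am.confusion_from_calls(calls, truth)
        assert m.n_scored == 2
        assert m.n_indeterminate == 1

    def test_missing_truth_rejected(self):
        with pytest.raises(ValueError, match="x"):
            am.confusion_from_calls({"x": "ACC"}, {})

    def test_swapping_positive_class_swaps_metric_pairs(self):
        m = am.ConfusionMetrics(tp=18, fp=3, tn=19, fn=4)
        s = m.swapped()
        assert s.sensitivity == m.specificity
        assert s.specificity == m.sensitivity
        assert s.ppv == m.npv
        assert s.npv == m.ppv


class TestROC:
    def test_perfectly_separated_scores_give_auc_one(self):
        scores = {"a": 0.9, "b": 0.8, "c": 0.2, "d": 0.1}
        truth = {"a": "ACC", "b": "ACC", "c": "ACA", "d": "ACA"}
        assert am.roc_from_scores(scores, truth).auc == pytest.approx(1.0)

    def test_partially_ordered_scores_match_pair_enumeration(self):
        # pairs: (0.9 vs 0.85) win, (0.9 vs 0.1) win, (0.8 vs 0.85) loss,
        # (0.8 vs 0.1) win -> 3 wins of 4 pairs = 0.75
        scores = {"p1": 0.9, "p2": 0.8, "n1": 0.85, "n2": 0.1}
        truth = {"p1": "ACC", "p2": "ACC", "n1": "ACA", "n2": "ACA"}
        roc = am.roc_from_scores(scores, truth)
        assert roc.auc == pytest.approx(0.75)
        assert roc.auc == pytest.approx(brute_force_auc(scores, truth))

    def test_all_scores_equal_give_auc_half(self):
        scores = {"a": 0.5, "b": 0.5, "c": 0.5}
        truth = {"a": "ACC", "b": "ACA", "c": "ACA"}
        assert am.roc_from_scores(scores, truth).auc == pytest.approx(0.5)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            am.roc_from_scores({"a": 0.5, "b": 0.2},
                               {"a": "ACC", "b": "ACC"})

    def test_curve_is_monotone_from_zero_to_one(self):
        rng = np.random.default_rng(0)
        scores = {f"s{i}": float(rng.random()) for i in range(20)}
        truth = {f"s{i}": ("ACC" if i % 2 else "ACA") for i in range(20)}
        roc = am.roc_from_scores(scores, truth)
        assert roc.tpr[0] == roc.fpr[0] == 0.0
        assert roc.tpr[-1] == roc.fpr[-1] == 1.0
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)

    @given(data=st.data())
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_trapezoid_equals_mann_whitney_on_random_instances(self, data):
        """Brute-force pairwise oracle on random 10-sample instances; ties
        in scores are drawn deliberately via a coarse grid."""
        labels = data.draw(
            st.lists(st.sampled_from(["ACA", "ACC"]), min_size=10, max_size=10)
            .filter(lambda ls: len(set(ls)) == 2))
        values = data.draw(
            st.lists(st.integers(min_value=0, max_value=5),
                     min_size=10, max_size=10))
        scores = {f"s{i}": v / 5.0 for i, v in enumerate(values)}
        truth = {f"s{i}": g for i, g in enumerate(labels)}
        roc = am.roc_from_scores(scores, truth)
        assert roc.auc == pytest.approx(brute_force_auc(scores, truth),
                                        abs=1e-12)

    def test_agrees_with_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = {f"s{i}": float(rng.random()) for i in range(30)}
        truth = {f"s{i}": ("ACC" if rng.random() < 0.5 else "ACA")
                 for i in range(30)}
        if len(set(truth.values())) < 2:
            truth["s0"] = "ACC"
            truth["s1"] = "ACA"
        ours = am.roc_from_scores(scores, truth).auc
        ref = roc_auc_score([truth[k] == "ACC" for k in scores],
                            [scores[k] for k in scores])
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_binary_call_scores_reduce_to_mean_of_sens_and_spec(self):
        truth = {f"s{i}": ("ACC" if i < 10 else "ACA") for i in range(20)}
        calls = {f"s{i}": ("ACC" if (i < 8 or i >= 17) else "ACA")
                 for i in range(20)}
        m = am.confusion_from_calls(calls, truth)
        scores = {k: (1.0 if v == "ACC" else 0.0) for k, v in calls.items()}
        roc = am.roc_from_scores(scores, truth)
        assert roc.auc == pytest.approx((m.sensitivity + m.specificity) / 2)


def test_roc_plot_writes_an_image(tmp_path):
    from adrenomir.metrics import plot_roc

    roc = am.roc_from_scores({"a": 0.9, "b": 0.2, "c": 0.7},
                             {"a": "ACC", "b": "ACA", "c": "ACA"})
    path = tmp_path / "roc.png"
    plot_roc({"panel": roc}, path)
    assert path.stat().st_size > 0


class TestEvaluateModels:
    def _fake_votes(self, calls, fractions):
        return [
            am.VoteResult(sample_id=s, votes={"ACC": int(f * 100),
                                              "ACA": 100 - int(f * 100)},
                          vote_fraction_acc=f, final_call=c, n_iterations=100)
            for (s, c), f in zip(calls.items(), fractions)
        ]

    def test_one_row_per_model_with_rounded_percentages(self):
        truth = {"a": "ACC", "b": "ACA"}
        votes = self._fake_votes({"a": "ACC", "b": "ACA"}, [0.9, 0.1])
        df = am.evaluate_models({"m1": votes, "m2": votes}, truth)
        assert list(df.index) == ["m1", "m2"]
        assert df.loc["m1", "sensitivity_pct"] == 100.0
        assert df.loc["m1", "auc_pct"] == 100.0

    def test_indeterminate_call_excluded_from_cells(self):
        truth = {"a": "ACC", "b": "ACA", "c": "ACC"}
        votes = self._fake_votes(
            {"a": "ACC", "b": "ACA", "c": "INDETERMINATE"}, [0.9, 0.1, 0.5])
        df = am.evaluate_models({"m": votes}, truth)
        assert df.loc["m", "indeterminate"] == 1
        assert df.loc["m", "sensitivity_pct"] == 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            am.evaluate_models({}, {})
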