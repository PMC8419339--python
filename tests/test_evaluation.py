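import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from leukodx import (
    ValidationError,
    compare_scores_anova,
    evaluate_predictions,
    scatter_export,
)
from oracles import confusion_metrics

CLASSES = ("AML", "B-ALL", "MPAL")


class TestEvaluatePredictions:
    def test_perfect_three_class_prediction(self):
        y = ["AML", "AML", "B-ALL", "B-ALL", "MPAL", "MPAL"]
        report = evaluate_predictions(y, y)
        assert report.accuracy == 1.0
        assert all(v == 1.0 for v in report.sensitivity.values())
        assert all(v == 1.0 for v in report.specificity.values())

    def test_eleven_of_twelve_rounds_to_92_percent(self):
        y_true = ["B-ALL"] * 5 + ["AML"] * 3 + ["MPAL"] * 4
        y_pred = list(y_true)
        y_pred[0] = "MPAL"
        report = evaluate_predictions(y_true, y_pred)
        assert report.accuracy == pytest.approx(11 / 12)
        assert round(100 * report.accuracy) == 92

    def test_unclassified_counts_against_accuracy_and_sensitivity(self):
        report = evaluate_predictions(
            ["AML", "AML", "B-ALL"], ["AML", "Unclassified", "B-ALL"]
        )
        assert report.accuracy == pytest.approx(2 / 3)
        assert report.sensitivity["AML"] == pytest.approx(0.5)
        assert report.specificity["AML"] == 1.0
        assert report.confusion.loc["AML", "Unclassified"] == 1

    def test_contrived_confusion_against_hand_counts(self):
        y_true = ["AML", "AML", "B-ALL", "B-ALL", "MPAL", "MPAL", "MPAL"]
        y_pred = ["AML", "B-ALL", "B-ALL", "MPAL", "MPAL", "AML", "MPAL"]
        report = evaluate_predictions(y_true, y_pred)
        # AML: TP 1, FN 1, FP 1, TN 4; MPAL: TP 2, FN 1, FP 1, TN 3
        assert report.sensitivity["AML"] == pytest.approx(0.5)
        assert report.specificity["AML"] == pytest.approx(4 / 5)
        assert report.sensitivity["MPAL"] == pytest.approx(2 / 3)
        assert report.specificity["MPAL"] == pytest.approx(3 / 4)
        assert report.confusion.to_numpy().sum() == 7

    def test_random_labelings_match_oracle(self, rng):
        labels = np.array(CLASSES + ("Unclassified",), dtype=object)
        for _ in range(100):
            n = int(rng.integers(2, 20))
            y_true = rng.choice(labels[:3], n)
            y_pred = rng.choice(labels, n)
            report = evaluate_predictions(y_true, y_pred)
            acc, sens, spec = confusion_metrics(list(y_true), list(y_pred), CLASSES)
            assert report.accuracy == pytest.approx(acc, rel=1e-12)
            for c in CLASSES:
                for got, want in ((report.sensitivity[c], sens[c]), (report.specificity[c], spec[c])):
                    assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            evaluate_predictions(["AML"], ["AML", "AML"])


def _scores(rows, labels):
    frame = pd.DataFrame(rows, columns=["aml_score", "ball_score"])
    frame.index = [f"s{i}" for i in range(len(frame))]
    return frame, pd.Series(labels, index=frame.index)


class TestCompareScoresAnova:
    def test_identical_scores_give_null_result(self):
        scores, labels = _scores(
            [[50, 50]] * 6, ["AML", "AML", "B-ALL", "B-ALL", "MPAL", "MPAL"]
        )
        report = compare_scores_anova(scores, labels)
        assert (report.anova["F"] == 0).all()
        assert (report.anova["p_value"] == 1).all()
        assert (report.pairwise["p_bonferroni"] == 1).all()

    def test_two_groups_reduce_to_pooled_t_test(self, rng):
        values = rng.normal(50, 5, 10)
        scores, labels = _scores(
            [[v, 100 - v] for v in values], ["AML"] * 5 + ["B-ALL"] * 5
        )
        report = compare_scores_anova(scores, labels)
        t, p = stats.ttest_ind(values[:5], values[5:], equal_var=True)
        assert report.anova.loc["aml_score", "F"] == pytest.approx(t**2, rel=1e-10)
        assert report.anova.loc["aml_score", "p_value"] == pytest.approx(p, rel=1e-10)
        # single pair -> no multiplicity correction
        row = report.pairwise[report.pairwise["score"] == "aml_score"].iloc[0]
        assert row["p_bonferroni"] == pytest.approx(p, rel=1e-10)

    def test_matches_scipy_f_oneway(self, rng):
        scores, labels = _scores(
            rng.normal(50, 10, size=(12, 2)),
            ["AML"] * 4 + ["B-ALL"] * 4 + ["MPAL"] * 4,
        )
        report = compare_scores_anova(scores, labels)
        for col in scores.columns:
            groups = [scores.loc[labels == c, col] for c in CLASSES]
            f, p = stats.f_oneway(*groups)
            assert report.anova.loc[col, "F"] == pytest.approx(f, rel=1e-10)
            assert report.anova.loc[col, "p_value"] == pytest.approx(p, rel=1e-10)

    def test_synthetic_scores_show_lineage_pattern(self, normalized_cohort):
        from leukodx import ScoreClassifier

        matrix, labels, _ = normalized_cohort
        clf = ScoreClassifier().fit(matrix.T, labels)
        scores = clf.score_pairs(matrix.T)
        report = compare_scores_anova(scores, labels)
        pw = report.pairwise.set_index(["score", "group_a", "group_b"])
        assert pw.loc[("aml_score", "AML", "B-ALL"), "p_bonferroni"] < 0.001
        # the AML-vs-B-ALL contrast is the extreme pair for both scores; the
        # two MPAL contrasts are always less significant than it
        assert (
            pw.loc[("aml_score", "AML", "MPAL"), "p_bonferroni"]
            > pw.loc[("aml_score", "AML", "B-ALL"), "p_bonferroni"]
        )
        assert (
            pw.loc[("ball_score", "AML", "MPAL"), "p_bonferroni"]
            > pw.loc[("ball_score", "AML", "B-ALL"), "p_bonferroni"]
        )

    def test_small_category_rejected(self):
        scores, labels = _scores([[1, 2], [3, 4], [5, 6]], ["AML", "AML", "B-ALL"])
        with pytest.raises(ValidationError, match="B-ALL"):
            compare_scores_anova(scores, labels)

    @settings(derandomize=True, max_examples=100)
    @given(p=st.floats(0, 1), q=st.floats(0, 1))
    def test_bonferroni_is_monotone_and_capped(self, p, q):
        adj_p, adj_q = min(1.0, 3 * p), min(1.0, 3 * q)
        assert (p <= q) == (adj_p <= adj_q) or adj_p == adj_q
        assert 0.0 <= adj_p <= 1.0


def test_scatter_export_columns(normalized_cohort):
    from leukodx import ScoreClassifier

    matrix, labels, _ = normalized_cohort
    clf = ScoreClassifier().fit(matrix.T, labels)
    table = scatter_export(clf.score_pairs(matrix.T), labels)
    assert list(table.columns) == ["aml_score", "ball_score", "true_label"]
    assert (table["true_label"] == labels).all()
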