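"""Diagnostic-performance metrics and score group comparisons.

Accuracy is the fraction of all samples whose predicted label equals the true
one — an ``Unclassified`` prediction is always wrong, and it stays in the
denominator.  Sensitivity and specificity are computed one-vs-rest per disease
class.  Score differences across the three categories are tested with one-way
ANOVA followed by Bonferroni post hoc pairwise comparisons (pooled within-group
variance t-tests, raw p multiplied by the number of comparisons, capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

REPORT_CLASSES = ("AML", "B-ALL", "MPAL")
UNCLASSIFIED = "Unclassified"


@dataclass
class EvaluationReport:
    """Confusion matrix plus derived diagnostic metrics."""

    confusion: pd.DataFrame  # true (rows) x predicted (columns)
    accuracy: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]

    def summary(self) -> pd.DataFrame:
        """One row per disease class with sensitivity and specificity (percent)."""
        return pd.DataFrame(
            {
                "sensitivity_pct": {
                    c: round(100.0 * v, 1) for c, v in self.sensitivity.items()
                },
                "specificity_pct": {
                    c: round(100.0 * v, 1) for c, v in self.specificity.items()
                },
            }
        )


def evaluate_predictions(true_labels, predicted_labels) -> EvaluationReport:
    """Confusion matrix, accuracy and per-class sensitivity/specificity.

    Both inputs are aligned sequences of labels; predictions may include
    ``Unclassified``, which counts against accuracy and against the
    sensitivity of the sample's true class.
    """
    y_true = np.asarray(pd.Series(true_labels).to_numpy(), dtype=object)
    y_pred = np.asarray(pd.Series(predicted_labels).to_numpy(), dtype=object)
    if len(y_true) != len(y_pred):
        raise ValidationError(
            f"label lists differ in length: {len(y_true)} vs {len(y_pred)}"
        )
    if len(y_true) == 0:
        raise ValidationError("no samples to evaluate")
    classes = list(REPORT_CLASSES) + [UNCLASSIFIED]
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    confusion.index.name = "true"
    confusion.columns.name = "predicted"
    for t, p in zip(y_true, y_pred):
        confusion.loc[t, p] += 1
    accuracy = float((y_true == y_pred).mean())
    sensitivity, specificity = {}, {}
    for c in REPORT_CLASSES:
        tp = int(((y_true == c) & (y_pred == c)).sum())
        fn = int(((y_true == c) & (y_pred != c)).sum())
        fp = int(((y_true != c) & (y_pred == c)).sum())
        tn = int(((y_true != c) & (y_pred != c)).sum())
        sensitivity[c] = tp / (tp + fn) if tp + fn else float("nan")
        specificity[c] = tn / (tn + fp) if tn + fp else float("nan")
    return EvaluationReport(
        confusion=confusion,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
    )


@dataclass
class ScoreComparisonReport:
    """One-way ANOVA per score plus Bonferroni-adjusted pairwise comparisons."""

    anova: pd.DataFrame  # index score, columns F, p_value
    pairwise: pd.DataFrame  # score, group_a, group_b, mean_diff, p_raw, p_bonferroni


def _one_way_anova(groups: list[np.ndarray]) -> tuple[float, float, float, int]:
    """Return (F, p, pooled within-group variance, residual df).

    Degenerate cases are resolved explicitly: no spread at all gives F = 0 and
    p = 1; separated constant groups give p = 0.
    """
    n_total = sum(len(g) for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    msw = ssw / df_w
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0, 0.0, df_w
        return float("inf"), 0.0, 0.0, df_w
    f = (ssb / df_b) / msw
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p, float(msw), df_w


def compare_scores_anova(
    scores: pd.DataFrame, labels: pd.Series
) -> ScoreComparisonReport:
    """Compare each score column across diagnostic categories.

    ``scores`` is samples x score columns (typically ``aml_score`` and
    ``ball_score``); ``labels`` assigns each sample a category.  Pairwise
    post hoc tests use the ANOVA's pooled within-group variance and Bonferroni
    correction by the number of pairs tested (3 for three categories).
    """
    labels = labels.reindex(scores.index)
    if labels.isna().any():
        raise ValidationError("every scored sample needs a label")
    categories = [c for c in ("AML", "B-ALL", "MPAL") if c in set(labels)]
    if len(categories) < 2:
        raise ValidationError("need >= 2 categories to compare")
    for c in categories:
        if (labels == c).sum() < 2:
            raise ValidationError(f"category {c!r} has < 2 samples")
    anova_rows, pair_rows = {}, []
    pairs = list(combinations(categories, 2))
    for col in scores.columns:
        groups = [scores.loc[labels == c, col].to_numpy(float) for c in categories]
        f, p, msw, df_w = _one_way_anova(groups)
        anova_rows[col] = {"F": f, "p_value": p}
        for (a, ga), (b, gb) in combinations(zip(categories, groups), 2):
            diff = ga.mean() - gb.mean()
            if msw == 0.0:
                p_raw = 1.0 if diff == 0.0 else 0.0
            else:
                se = np.sqrt(msw * (1.0 / len(ga) + 1.0 / len(gb)))
                t = diff / se
                p_raw = float(2.0 * stats.t.sf(abs(t), df_w))
            pair_rows.append(
                {
                    "score": col,
                    "group_a": a,
                    "group_b": b,
                    "mean_diff": float(diff),
                    "p_raw": p_raw,
                    "p_bonferroni": min(1.0, len(pairs) * p_raw),
                }
            )
    return ScoreComparisonReport(
        anova=pd.DataFrame(anova_rows).T.rename_axis("score"),
        pairwise=pd.DataFrame(pair_rows),
    )


def scatter_export(scores: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Scatter-ready table: sample_id, aml_score, ball_score, true_label."""
    out = scores.copy()
    out["true_label"] = labels.reindex(scores.index)
    return out.rename_axis("sample_id")
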