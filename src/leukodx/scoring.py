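"""Positivity-threshold calibration, AML/B-ALL scores and the 30/30 decision rule.

Each signature gene gets a positivity threshold; a sample's AML score is
100 x the fraction of AML-specific genes whose FPKM strictly exceeds their
threshold, and likewise for the B-ALL score.  The four-way call is:

* AML    — AML score >= cutoff and B-ALL score < cutoff,
* B-ALL  — AML score < cutoff and B-ALL score >= cutoff,
* MPAL   — both scores >= cutoff,
* Unclassified — both scores below the cutoff (counted as incorrect in every
  accuracy computation).

The default cutoff is 30.  The per-gene threshold is the geometric mean of the
AML and B-ALL training-group means (the midpoint in log space), scaled by one
global multiplier k chosen by grid search to maximize balanced training
accuracy of the cutoff rule, ties broken toward k = 1.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .io import ValidationError, align_labels, validate_expression_matrix
from .selection import SignatureModel, differential_test, select_signature

DEFAULT_CUTOFF = 30.0
#: grid of global threshold multipliers searched during calibration
DEFAULT_K_GRID = tuple(np.round(np.arange(0.5, 2.0 + 1e-9, 0.1), 1))
UNCLASSIFIED = "Unclassified"
#: floor applied to a group mean before the geometric mean, so thresholds stay > 0
_MEAN_FLOOR = 1e-3


class ScorePair(NamedTuple):
    aml_score: float
    ball_score: float


def classify(scores: ScorePair | tuple[float, float], cutoff: float = DEFAULT_CUTOFF) -> str:
    """Four-way call from an (AML score, B-ALL score) pair."""
    aml, ball = scores
    if aml >= cutoff and ball < cutoff:
        return "AML"
    if aml < cutoff and ball >= cutoff:
        return "B-ALL"
    if aml >= cutoff and ball >= cutoff:
        return "MPAL"
    return UNCLASSIFIED


def _require_genes(matrix_index: pd.Index, model: SignatureModel) -> None:
    missing = [g for g in model.genes if g not in matrix_index]
    if missing:
        raise ValidationError(f"signature gene(s) missing from matrix: {missing}")


def compute_scores(
    sample: pd.Series | pd.DataFrame, model: SignatureModel
) -> ScorePair | pd.DataFrame:
    """AML and B-ALL scores for one sample (Series) or every sample (DataFrame).

    A gene counts as positively expressed only when its value is strictly
    greater than its threshold; a value exactly at the threshold does not count.
    """
    if not model.thresholds:
        raise ValidationError("signature model has no calibrated thresholds")
    if isinstance(sample, pd.Series):
        frame = sample.to_frame(name=getattr(sample, "name", "sample"))
        out = compute_scores(frame, model)
        return ScorePair(float(out.iloc[0, 0]), float(out.iloc[0, 1]))
    _require_genes(sample.index, model)
    scores = {}
    for name, genes in (("aml_score", model.aml_genes), ("ball_score", model.ball_genes)):
        if not genes:  # empty signature side: nothing can be positive
            scores[name] = np.zeros(sample.shape[1])
            continue
        thr = np.array([model.thresholds[g] for g in genes])
        values = sample.loc[list(genes)].to_numpy(float)
        positive = values > thr[:, None]
        scores[name] = 100.0 * positive.mean(axis=0)
    out = pd.DataFrame(scores, index=sample.columns.copy())
    out.index.name = "sample_id"
    return out


def _balanced_accuracy(calls: pd.Series, labels: pd.Series) -> float:
    accs = []
    for cat in labels.unique():
        mask = labels == cat
        accs.append(float((calls[mask] == cat).mean()))
    return float(np.mean(accs))


def calibrate_thresholds(
    matrix: pd.DataFrame,
    labels: pd.Series,
    model: SignatureModel,
    cutoff: float = DEFAULT_CUTOFF,
    k_grid: tuple[float, ...] = DEFAULT_K_GRID,
) -> SignatureModel:
    """Set per-gene positivity thresholds from AML and B-ALL training samples.

    Per gene the base threshold is sqrt(mean_AML x mean_B-ALL) of the raw FPKM
    training means (group means floored at a tiny positive value so the
    threshold stays positive).  One global multiplier k from ``k_grid`` scales
    every threshold; the k maximizing balanced training accuracy of the cutoff
    rule over the AML and B-ALL samples is kept, preferring k closest to 1 on
    ties.  Also stores the training-cohort median of the reference gene when
    present, for later reference-gene normalization of external data.
    """
    if not model.aml_genes and not model.ball_genes:
        raise ValidationError("signature model has no genes to calibrate")
    validate_expression_matrix(matrix)
    labels = align_labels(matrix, labels)
    _require_genes(matrix.index, model)
    train_cols = labels.index[labels.isin(["AML", "B-ALL"])]
    train_labels = labels[train_cols]
    for cat in ("AML", "B-ALL"):
        if (train_labels == cat).sum() < 1:
            raise ValidationError(f"no {cat} training samples for calibration")
    sub = matrix.loc[model.genes, train_cols]
    mean_aml = sub[train_labels.index[train_labels == "AML"]].mean(axis=1)
    mean_ball = sub[train_labels.index[train_labels == "B-ALL"]].mean(axis=1)
    base = np.sqrt(
        np.maximum(mean_aml.to_numpy(), _MEAN_FLOOR)
        * np.maximum(mean_ball.to_numpy(), _MEAN_FLOOR)
    )
    base_thresholds = dict(zip(model.genes, base))

    best: tuple[float, float, float] | None = None  # (accuracy, -|k-1|, -k)
    best_k = 1.0
    for k in k_grid:
        candidate = SignatureModel(
            aml_genes=model.aml_genes,
            ball_genes=model.ball_genes,
            thresholds={g: k * t for g, t in base_thresholds.items()},
            reference_gene=model.reference_gene,
        )
        scores = compute_scores(matrix[train_cols], candidate)
        calls = scores.apply(
            lambda row: classify(ScorePair(row["aml_score"], row["ball_score"]), cutoff),
            axis=1,
        )
        key = (_balanced_accuracy(calls, train_labels), -abs(k - 1.0), -k)
        if best is None or key > best:
            best, best_k = key, float(k)

    reference_level = model.reference_level
    if model.reference_gene in matrix.index:
        reference_level = float(matrix.loc[model.reference_gene, train_cols].median())
    return SignatureModel(
        aml_genes=list(model.aml_genes),
        ball_genes=list(model.ball_genes),
        thresholds={g: best_k * t for g, t in base_thresholds.items()},
        reference_gene=model.reference_gene,
        reference_level=reference_level,
    )


class ScoreClassifier(ClassifierMixin, BaseEstimator):
    """Signature-score classifier for acute leukemia lineage.

    ``fit(X, y)`` takes a samples x genes FPKM frame and labels; it selects
    AML- and B-ALL-specific signature genes from the AML and B-ALL samples
    (unless a pre-built ``signature`` with gene lists is supplied) and
    calibrates their positivity thresholds.  ``predict`` returns one of
    ``AML``, ``B-ALL``, ``MPAL`` or ``Unclassified`` per sample, and
    ``score_pairs`` exposes the underlying (AML score, B-ALL score) pairs.

    Parameters
    ----------
    fold_min, q_max, fpkm_min:
        Signature-selection filters: minimum fold change, maximum BH-adjusted
        q-value, and minimum FPKM mean in the overexpressing group.
    cutoff:
        Score cutoff of the decision rule (percent, default 30).
    k_grid:
        Candidate global threshold multipliers for calibration.
    signature:
        Optional :class:`SignatureModel` whose gene lists are used as-is;
        thresholds are still calibrated on the fitted data.
    """

    def __init__(
        self,
        fold_min: float = 2.0,
        q_max: float = 0.05,
        fpkm_min: float = 100.0,
        cutoff: float = DEFAULT_CUTOFF,
        k_grid: tuple[float, ...] = DEFAULT_K_GRID,
        signature: SignatureModel | None = None,
    ):
        self.fold_min = fold_min
        self.q_max = q_max
        self.fpkm_min = fpkm_min
        self.cutoff = cutoff
        self.k_grid = k_grid
        self.signature = signature

    def fit(self, X: pd.DataFrame, y) -> "ScoreClassifier":
        X = _as_samples_frame(X)
        y = pd.Series(np.asarray(y, dtype=object), index=X.index, name="label")
        matrix = X.T
        if self.signature is not None:
            model = self.signature
        else:
            results = differential_test(matrix, y, "AML", "B-ALL")
            model = select_signature(
                results, fold_min=self.fold_min, q_max=self.q_max, fpkm_min=self.fpkm_min
            )
        self.signature_ = calibrate_thresholds(
            matrix, y, model, cutoff=self.cutoff, k_grid=tuple(self.k_grid)
        )
        self.k_ = _infer_multiplier(model, self.signature_, matrix, y)
        self.classes_ = np.array(["AML", "B-ALL", "MPAL", UNCLASSIFIED], dtype=object)
        return self

    def score_pairs(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "signature_")
        X = _as_samples_frame(X)
        return compute_scores(X.T, self.signature_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        pairs = self.score_pairs(X)
        calls = [
            classify(ScorePair(a, b), self.cutoff)
            for a, b in zip(pairs["aml_score"], pairs["ball_score"])
        ]
        return np.asarray(calls, dtype=object)


def _as_samples_frame(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a samples x genes pandas DataFrame")
    return X


def _infer_multiplier(
    model: SignatureModel, fitted: SignatureModel, matrix: pd.DataFrame, labels: pd.Series
) -> float:
    """Recover the chosen global multiplier from fitted vs base thresholds."""
    train = labels.index[labels.isin(["AML", "B-ALL"])]
    gene = fitted.genes[0]
    sub = matrix.loc[[gene], train]
    mean_a = float(sub[train[labels[train] == "AML"]].mean(axis=1).iloc[0])
    mean_b = float(sub[train[labels[train] == "B-ALL"]].mean(axis=1).iloc[0])
    base = float(np.sqrt(max(mean_a, _MEAN_FLOOR) * max(mean_b, _MEAN_FLOOR)))
    return round(fitted.thresholds[gene] / base, 6)
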