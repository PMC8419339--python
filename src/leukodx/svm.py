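"""Soft-margin SVM with hyperbolic-tangent (sigmoid) kernel for the three lineages.

Features are the signature genes.  Each feature is Z-transformed (centred and
scaled to unit population standard deviation) using parameters estimated from
the training samples only; zero-variance features are dropped and recorded.
Multiclass decisions use the one-vs-one strategy with majority vote; a voting
tie is broken by the fixed class order AML < B-ALL < MPAL, making predictions
deterministic for fixed training data.

Leave-one-out cross-validation refits the standardization and the SVM on every
training fold, so the held-out sample never leaks into the stored (mean, sd).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .evaluation import EvaluationReport, evaluate_predictions
from .io import ValidationError, align_labels, validate_expression_matrix

CLASS_ORDER = ("AML", "B-ALL", "MPAL")


def z_transform(
    matrix: pd.DataFrame,
    genes: Sequence[str],
    params: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize the given genes of a genes x samples matrix.

    With ``params`` absent, per-gene mean and population standard deviation
    are computed from the supplied samples; genes with zero variance are
    dropped with a warning.  With ``params`` given (a frame indexed by gene
    with columns ``mean`` and ``sd``), the stored parameters are applied
    unchanged — the transform of new data need not have zero mean.

    Returns ``(standardized genes x samples frame, params frame)``.
    """
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise ValidationError(f"feature gene(s) missing from matrix: {missing}")
    sub = matrix.loc[list(genes)]
    if params is None:
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=0)
        keep = sd > 0
        if not keep.all():
            dropped = list(sub.index[~keep])
            warnings.warn(
                f"dropping zero-variance feature(s): {dropped}", stacklevel=2
            )
            sub, mean, sd = sub.loc[keep], mean[keep], sd[keep]
        params = pd.DataFrame({"mean": mean, "sd": sd})
        params.index.name = "gene"
    else:
        sub = matrix.loc[params.index]
    standardized = sub.sub(params["mean"], axis=0).div(params["sd"], axis=0)
    return standardized, params


class TanhSVMClassifier(ClassifierMixin, BaseEstimator):
    """One-vs-one soft-margin SVM with tanh kernel and built-in Z-transformation.

    ``fit(X, y)`` expects a samples x genes frame (optionally restricted to
    ``feature_genes``).  Standardization parameters are estimated from the
    fitted samples and stored, so a pipeline refitting per fold cannot leak
    held-out data.

    Parameters
    ----------
    C : float
        Soft-margin penalty (default 1).
    gamma : float or "auto"
        Kernel scale; "auto" means 1 / n_features.
    coef0 : float
        Kernel offset of tanh(gamma <x, x'> + coef0).
    feature_genes : sequence of str, optional
        Columns of X to use as features; default all columns.

    Attributes
    ----------
    feature_names_ : list of retained (non-constant) feature genes
    dropped_features_ : list of zero-variance genes removed before training
    standardization_ : DataFrame of per-gene (mean, sd) from the training data
    classes_ : sorted class labels (AML < B-ALL < MPAL)
    """

    def __init__(
        self,
        C: float = 1.0,
        gamma: float | str = "auto",
        coef0: float = 0.0,
        feature_genes: Sequence[str] | None = None,
    ):
        self.C = C
        self.gamma = gamma
        self.coef0 = coef0
        self.feature_genes = feature_genes

    def fit(self, X: pd.DataFrame, y) -> "TanhSVMClassifier":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float))
            X.columns = [str(c) for c in X.columns]
        y = pd.Series(np.asarray(y, dtype=object), index=X.index)
        genes = list(self.feature_genes) if self.feature_genes is not None else list(X.columns)
        present = sorted(set(y))
        if len(present) < 2:
            raise ValidationError(f"need >= 2 classes in training data, got {present}")
        self.classes_ = np.array(sorted(present), dtype=object)

        features, params = z_transform(X.T, genes)
        self.standardization_ = params
        self.feature_names_ = list(params.index)
        self.dropped_features_ = [g for g in genes if g not in set(self.feature_names_)]
        if not self.feature_names_:
            raise ValidationError("all features have zero variance")

        train = features.T.to_numpy(float)
        self._pair_machines_: dict[tuple[str, str], SVC] = {}
        for a, b in combinations(self.classes_, 2):
            mask = y.isin([a, b]).to_numpy()
            svc = SVC(
                kernel="sigmoid", C=self.C, gamma=self.gamma, coef0=self.coef0
            )
            svc.fit(train[mask], y.to_numpy(object)[mask])
            self._pair_machines_[(a, b)] = svc
        return self

    def _transform(self, X: pd.DataFrame) -> np.ndarray:
        features, _ = z_transform(X.T, self.feature_names_, self.standardization_)
        return features.T.to_numpy(float)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "_pair_machines_")
        values = self._transform(X)
        votes = pd.DataFrame(
            0, index=range(len(values)), columns=list(self.classes_)
        )
        for (a, b), svc in self._pair_machines_.items():
            pred = svc.predict(values)
            for cls in (a, b):
                votes.loc[:, cls] += (pred == cls).astype(int)
        # idxmax takes the first column on ties; columns follow sorted class order
        return votes.idxmax(axis=1).to_numpy(object)


def train_svm(
    features: pd.DataFrame,
    labels: pd.Series,
    C: float = 1.0,
    gamma: float | str = "auto",
    coef0: float = 0.0,
    feature_genes: Sequence[str] | None = None,
    required_classes: Sequence[str] | None = None,
) -> TanhSVMClassifier:
    """Fit a :class:`TanhSVMClassifier` on a samples x genes feature frame.

    ``required_classes`` (e.g. the full AML/B-ALL/MPAL trio) makes the absence
    of any of those classes from the training labels an error.
    """
    if required_classes is not None:
        absent = [c for c in required_classes if c not in set(labels)]
        if absent:
            raise ValidationError(f"class(es) absent from training data: {absent}")
    return TanhSVMClassifier(
        C=C, gamma=gamma, coef0=coef0, feature_genes=feature_genes
    ).fit(features, labels)


@dataclass
class CrossValReport:
    """Leave-one-out result: per-sample predictions plus summary metrics."""

    predictions: pd.DataFrame  # columns: true, predicted; index: sample_id
    accuracy: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]

    @property
    def evaluation(self) -> EvaluationReport:
        return evaluate_predictions(
            self.predictions["true"], self.predictions["predicted"]
        )


def leave_one_out_cv(
    matrix: pd.DataFrame,
    labels: pd.Series,
    feature_genes: Sequence[str] | None = None,
    C: float = 1.0,
    gamma: float | str = "auto",
    coef0: float = 0.0,
) -> CrossValReport:
    """Leave-one-out cross-validation of the tanh-kernel SVM.

    ``matrix`` is genes x samples.  Every fold refits the Z-transformation
    and all pairwise machines on the remaining samples and predicts the
    held-out one.  Requires >= 2 samples of every class so that no fold loses
    a class entirely.
    """
    validate_expression_matrix(matrix)
    labels = align_labels(matrix, labels)
    counts = labels.value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise ValidationError(
            f"leave-one-out needs >= 2 samples per class; too few: {dict(thin)}"
        )
    X = matrix.T
    rows = []
    for sample in X.index:
        train_idx = X.index != sample
        clf = TanhSVMClassifier(C=C, gamma=gamma, coef0=coef0, feature_genes=feature_genes)
        clf.fit(X.loc[train_idx], labels[train_idx])
        pred = clf.predict(X.loc[[sample]])[0]
        rows.append({"sample_id": sample, "true": labels[sample], "predicted": pred})
    predictions = pd.DataFrame(rows).set_index("sample_id")
    report = evaluate_predictions(predictions["true"], predictions["predicted"])
    return CrossValReport(
        predictions=predictions,
        accuracy=report.accuracy,
        sensitivity=report.sensitivity,
        specificity=report.specificity,
    )
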