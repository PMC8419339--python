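"""Reference-gene normalization for cross-platform transfer of the models.

Expression data from another platform or cohort is put on the training scale
by a per-sample multiplicative rescaling that anchors a housekeeping-style
reference gene (ABL1, the standard internal control in leukemia molecular
diagnostics) to a fixed target level.  After normalization every sample has
exactly the target expression of the reference gene, so any per-sample global
scale factor — library size, platform units — cancels out of the downstream
scores and SVM predictions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ValidationError, validate_expression_matrix

DEFAULT_REFERENCE_GENE = "ABL1"


def abl1_normalize(
    matrix: pd.DataFrame,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    target_level: float | None = None,
) -> pd.DataFrame:
    """Rescale every sample so the reference gene equals ``target_level``.

    ``matrix`` is genes x samples.  Each column is multiplied by
    ``target_level / reference value`` of that sample.  When ``target_level``
    is None the median reference value of the given matrix is used; to anchor
    external data to a training cohort, pass the stored
    ``SignatureModel.reference_level``.
    """
    validate_expression_matrix(matrix)
    if reference_gene not in matrix.index:
        raise ValidationError(f"reference gene {reference_gene!r} not in matrix")
    ref = matrix.loc[reference_gene]
    zero = ref.index[ref <= 0]
    if len(zero):
        raise ValidationError(
            f"reference gene {reference_gene!r} is 0 in sample(s): {list(zero)}"
        )
    if target_level is None:
        target_level = float(ref.median())
    if not target_level > 0:
        raise ValidationError(f"target_level must be > 0, got {target_level}")
    factors = target_level / ref.to_numpy(float)
    out = matrix.mul(factors, axis=1)
    # anchor exactly: the reference row is the target by construction
    out.loc[reference_gene] = target_level
    return out


class ReferenceGeneNormalizer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer form of reference-gene normalization.

    Works on samples x genes frames.  ``fit`` stores the target level (the
    median reference value of the fitted cohort unless ``target_level`` is
    given); ``transform`` rescales each sample so its reference-gene value
    equals the stored target.  Idempotent: transforming already-normalized
    data changes nothing.
    """

    def __init__(
        self,
        reference_gene: str = DEFAULT_REFERENCE_GENE,
        target_level: float | None = None,
    ):
        self.reference_gene = reference_gene
        self.target_level = target_level

    def fit(self, X: pd.DataFrame, y=None) -> "ReferenceGeneNormalizer":
        if self.reference_gene not in X.columns:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} not in columns"
            )
        if self.target_level is not None:
            self.target_level_ = float(self.target_level)
        else:
            ref = X[self.reference_gene].to_numpy(float)
            if (ref <= 0).any():
                bad = list(X.index[np.asarray(ref) <= 0])
                raise ValidationError(
                    f"reference gene {self.reference_gene!r} is 0 in sample(s): {bad}"
                )
            self.target_level_ = float(np.median(ref))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "target_level_")
        return abl1_normalize(X.T, self.reference_gene, self.target_level_).T
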