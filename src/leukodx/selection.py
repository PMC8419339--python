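"""Selection of lineage-specific signature genes from a labeled FPKM matrix.

A gene is AML-specific when it is overexpressed in AML relative to B-ALL by
more than ``fold_min`` (default 2), significant at BH-adjusted q < ``q_max``
(default 0.05), and highly expressed (AML group mean >= ``fpkm_min``, default
100 FPKM); B-ALL-specific genes are defined symmetrically.  MPAL samples take
no part in selection — the contrast is strictly AML versus B-ALL.

The per-gene test is a Welch two-sample t-test on log2(FPKM + 1) with
Benjamini-Hochberg FDR across all tested genes; fold change is the ratio of
raw group means with a 0.1 pseudocount in numerator and denominator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError, align_labels, validate_expression_matrix

#: pseudocount added to both group means before taking their ratio
FOLD_PSEUDOCOUNT = 0.1


@dataclass
class SignatureModel:
    """Lineage signature: two disjoint gene lists plus per-gene positivity thresholds.

    ``thresholds`` is empty until calibration; ``reference_level`` stores the
    training-cohort median of the reference gene so external data can be
    rescaled onto the training scale before scoring.
    """

    aml_genes: list[str]
    ball_genes: list[str]
    thresholds: dict[str, float] = field(default_factory=dict)
    reference_gene: str = "ABL1"
    reference_level: float | None = None

    def __post_init__(self) -> None:
        overlap = set(self.aml_genes) & set(self.ball_genes)
        if overlap:
            raise ValidationError(
                f"gene(s) in both signature lists: {sorted(overlap)}"
            )
        for gene, thr in self.thresholds.items():
            if not thr > 0:
                raise ValidationError(f"threshold for {gene!r} must be > 0, got {thr}")

    @property
    def genes(self) -> list[str]:
        """All signature genes, AML list first (fixed feature order for the SVM)."""
        return list(self.aml_genes) + list(self.ball_genes)

    def to_json(self) -> str:
        return json.dumps(
            {
                "aml_genes": list(self.aml_genes),
                "ball_genes": list(self.ball_genes),
                "thresholds": dict(self.thresholds),
                "reference_gene": self.reference_gene,
                "reference_level": self.reference_level,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        raw = json.loads(text)
        return cls(
            aml_genes=list(raw["aml_genes"]),
            ball_genes=list(raw["ball_genes"]),
            thresholds={k: float(v) for k, v in raw.get("thresholds", {}).items()},
            reference_gene=raw.get("reference_gene", "ABL1"),
            reference_level=raw.get("reference_level"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "SignatureModel":
        return cls.from_json(Path(path).read_text())


def differential_test(
    matrix: pd.DataFrame,
    labels: pd.Series,
    group_a: str = "AML",
    group_b: str = "B-ALL",
) -> pd.DataFrame:
    """Per-gene Welch t-test of group_a vs group_b on log2(FPKM + 1).

    Returns a DataFrame indexed by gene with columns ``mean_a``, ``mean_b``
    (raw FPKM group means), ``fold_change`` (pseudocounted ratio mean_a/mean_b),
    ``p_value`` and BH-adjusted ``q_value``.

    Genes with zero variance in both groups get p = 1 when the group means are
    equal (no evidence of change) and p = 0 when they differ (infinite t).
    """
    validate_expression_matrix(matrix)
    labels = align_labels(matrix, labels)
    a_cols = labels.index[labels == group_a]
    b_cols = labels.index[labels == group_b]
    for name, cols in ((group_a, a_cols), (group_b, b_cols)):
        if len(cols) < 2:
            raise ValidationError(
                f"group {name!r} has {len(cols)} sample(s); need >= 2 for a variance"
            )
    a_raw = matrix[a_cols].to_numpy(float)
    b_raw = matrix[b_cols].to_numpy(float)
    a_log = np.log2(a_raw + 1.0)
    b_log = np.log2(b_raw + 1.0)

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant genes trip scipy's precision-loss warning; the 0/0
        # case is resolved explicitly below
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        _, p = stats.ttest_ind(a_log, b_log, axis=1, equal_var=False)
    # Welch is 0/0 when both groups are constant; resolve by comparing means.
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(a_log.mean(axis=1), b_log.mean(axis=1))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)

    _, q, _, _ = multipletests(p, method="fdr_bh")
    mean_a = a_raw.mean(axis=1)
    mean_b = b_raw.mean(axis=1)
    fold = (mean_a + FOLD_PSEUDOCOUNT) / (mean_b + FOLD_PSEUDOCOUNT)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fold,
            "p_value": p,
            "q_value": q,
        },
        index=matrix.index.copy(),
    )


def select_signature(
    results: pd.DataFrame,
    fold_min: float = 2.0,
    q_max: float = 0.05,
    fpkm_min: float = 100.0,
) -> SignatureModel:
    """Apply the three selection filters to a differential_test(AML, B-ALL) result.

    AML-specific: fold_change > fold_min, q < q_max and AML mean >= fpkm_min;
    B-ALL-specific genes mirror this (fold_change < 1/fold_min, B-ALL mean
    >= fpkm_min).  Thresholds are left unset.
    """
    if len(results) == 0:
        raise ValidationError("empty differential-test result")
    sig = results["q_value"] < q_max
    aml = sig & (results["fold_change"] > fold_min) & (results["mean_a"] >= fpkm_min)
    ball = sig & (results["fold_change"] < 1.0 / fold_min) & (
        results["mean_b"] >= fpkm_min
    )
    aml_genes = list(results.index[aml])
    ball_genes = list(results.index[ball])
    for side, genes in (("AML", aml_genes), ("B-ALL", ball_genes)):
        if not genes:
            warnings.warn(f"no {side}-specific genes passed the filters", stacklevel=2)
    return SignatureModel(aml_genes=aml_genes, ball_genes=ball_genes)
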