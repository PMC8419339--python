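"""Reading, writing and validation of expression matrices, label tables and variant tables.

The canonical in-memory containers are pandas objects:

* an *expression matrix* is a :class:`pandas.DataFrame` of non-negative FPKM
  values with genes in rows and samples in columns (index name ``gene``);
* a *label table* is a :class:`pandas.Series` mapping sample id to one of the
  three diagnostic categories ``B-ALL``, ``AML``, ``MPAL``;
* a *variant table* is a list of :class:`VariantRecord`.

All readers validate on load and raise :class:`ValidationError` with a message
naming the offending gene, sample, row or cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

DIAGNOSTIC_CATEGORIES = ("AML", "B-ALL", "MPAL")

#: Strings accepted as a missing RNA VAF cell (plus an empty cell / NaN).
_MISSING_TOKENS = {"", "-", "–", "—", "na", "nan", "none"}

_TRUE_TOKENS = {"true", "yes", "y", "1", "detected"}
_FALSE_TOKENS = {"false", "no", "n", "0", "not detected", "not_detected"}


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates its contract."""


@dataclass(frozen=True)
class VariantRecord:
    """One variant with paired DNA-panel and RNA-seq measurements.

    ``dna_vaf`` and ``rna_vaf`` are percentages in [0, 100]; ``rna_vaf`` is
    ``None`` when RNA-seq reported no allele fraction for the variant (such
    records are excluded from the DNA/RNA correlation).  ``fpkm`` is the
    expression level of the host gene in the same sample and
    ``detected_in_rna`` records whether RNA-seq called the variant at all.
    """

    case_id: str
    gene: str
    dna_vaf: float
    rna_vaf: float | None
    fpkm: float
    detected_in_rna: bool

    def __post_init__(self) -> None:
        _check_vaf(self.dna_vaf, "dna_vaf", self)
        if self.rna_vaf is not None:
            _check_vaf(self.rna_vaf, "rna_vaf", self)
        if not math.isfinite(self.fpkm) or self.fpkm < 0:
            raise ValidationError(
                f"fpkm must be finite and >= 0, got {self.fpkm!r} "
                f"for {self.case_id}/{self.gene}"
            )


def _check_vaf(value: float, field: str, rec: "VariantRecord") -> None:
    if not math.isfinite(value) or not 0.0 <= value <= 100.0:
        raise ValidationError(
            f"{field} must lie in [0, 100], got {value!r} for "
            f"{rec.case_id}/{rec.gene}"
        )


def validate_expression_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples FPKM matrix and return it unchanged.

    Checks: unique gene and sample identifiers, at least one gene and one
    sample, and every value finite, numeric and non-negative.
    """
    if matrix.shape[0] < 1 or matrix.shape[1] < 1:
        raise ValidationError("expression matrix needs at least 1 gene and 1 sample")
    for axis, what in ((matrix.index, "gene"), (matrix.columns, "sample")):
        dup = axis[axis.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate {what} identifier(s): {sorted(set(dup))}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        coerced = matrix.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & matrix.notna()
        if bad.to_numpy().any():
            gene, sample = _first_true(bad)
            raise ValidationError(
                f"non-numeric value at gene {gene!r}, sample {sample!r}"
            )
        matrix = coerced
        values = matrix.to_numpy()
    finite = np.isfinite(values)
    if not finite.all():
        gene, sample = _first_true(pd.DataFrame(~finite, matrix.index, matrix.columns))
        raise ValidationError(f"non-finite value at gene {gene!r}, sample {sample!r}")
    if (values < 0).any():
        gene, sample = _first_true(matrix < 0)
        raise ValidationError(
            f"negative FPKM at gene {gene!r}, sample {sample!r}: "
            f"{matrix.loc[gene, sample]}"
        )
    return matrix


def _first_true(mask: pd.DataFrame) -> tuple[str, str]:
    arr = mask.to_numpy()
    i, j = np.argwhere(arr)[0]
    return str(mask.index[i]), str(mask.columns[j])


def read_expression_matrix(path: str | Path, fmt: str = "tsv") -> pd.DataFrame:
    """Read a TSV expression matrix (first column gene symbol, header = sample ids)."""
    if fmt != "tsv":
        raise ValueError(f"unsupported format: {fmt!r}")
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "gene"
    matrix.columns = matrix.columns.astype(str)
    return validate_expression_matrix(matrix)


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    validate_expression_matrix(matrix)
    out = matrix.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def validate_labels(labels: pd.Series) -> pd.Series:
    labels = labels.astype(str)
    bad = sorted(set(labels) - set(DIAGNOSTIC_CATEGORIES))
    if bad:
        raise ValidationError(
            f"unknown label(s) {bad}; allowed: {list(DIAGNOSTIC_CATEGORIES)}"
        )
    dup = labels.index[labels.index.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample identifier(s): {sorted(set(dup))}")
    return labels


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV ``sample_id<TAB>label`` into a Series."""
    table = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if table.shape[1] != 2:
        raise ValidationError(
            f"label table must have exactly 2 columns, found {table.shape[1]}"
        )
    labels = pd.Series(
        table.iloc[:, 1].to_numpy(), index=table.iloc[:, 0].astype(str), name="label"
    )
    labels.index.name = "sample_id"
    return validate_labels(labels)


def write_labels(labels: pd.Series, path: str | Path) -> None:
    validate_labels(labels)
    out = labels.rename("label").rename_axis("sample_id")
    out.to_csv(path, sep="\t")


def _parse_optional_float(cell: object) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text.lower() in _MISSING_TOKENS:
        return None
    return float(text)


def _parse_bool(cell: object, where: str) -> bool:
    text = str(cell).strip().lower()
    if text in _TRUE_TOKENS:
        return True
    if text in _FALSE_TOKENS:
        return False
    raise ValidationError(f"cannot interpret detected flag {cell!r} in {where}")


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant CSV/TSV with columns case, gene, dna_vaf, rna_vaf, fpkm, detected.

    A missing RNA VAF may be encoded as an empty cell or a dash; such records
    carry ``rna_vaf=None`` and are skipped by the VAF correlation.
    """
    table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = ["case", "gene", "dna_vaf", "rna_vaf", "fpkm", "detected"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"variant table missing column(s): {missing}")
    records = []
    for row in table.itertuples(index=False):
        rna = _parse_optional_float(getattr(row, "rna_vaf"))
        records.append(
            VariantRecord(
                case_id=str(row.case),
                gene=str(row.gene),
                dna_vaf=float(row.dna_vaf),
                rna_vaf=rna,
                fpkm=float(row.fpkm),
                detected_in_rna=_parse_bool(row.detected, f"{row.case}/{row.gene}"),
            )
        )
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [
        {
            "case": r.case_id,
            "gene": r.gene,
            "dna_vaf": r.dna_vaf,
            "rna_vaf": "" if r.rna_vaf is None else r.rna_vaf,
            "fpkm": r.fpkm,
            "detected": str(r.detected_in_rna).lower(),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def table2_variants() -> list[VariantRecord]:
    """The packaged 14-variant DNA-panel vs RNA-seq comparison table.

    Eleven records carry both a DNA and an RNA allele fraction; two NOTCH3
    variants in genes expressed below 1 FPKM were not detected by RNA-seq at
    all, and one further NOTCH3 variant was detected without a reported
    allele fraction.
    """
    with resources.as_file(
        resources.files("leukodx.data").joinpath("table2_variants.csv")
    ) as path:
        return read_variant_table(path)


def align_labels(matrix: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Return labels reindexed to the matrix sample order, requiring full coverage."""
    missing = [s for s in matrix.columns if s not in labels.index]
    if missing:
        raise ValidationError(f"sample(s) without a label: {missing}")
    return labels.reindex(matrix.columns)
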