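"""Concordance of variant allele fractions between DNA panel sequencing and RNA-seq.

RNA-seq can only call a variant when the host gene is actually transcribed:
records with FPKM below a detectability floor (1.0 by default) are expected to
be missed.  For the variants RNA-seq does quantify, the DNA and RNA allele
fractions are compared by Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

from scipy import stats

from .io import ValidationError, VariantRecord


@dataclass
class DetectabilityReport:
    """Partition of variants by an expression floor, with observed concordance."""

    expected_detectable: list[VariantRecord]
    expected_missed: list[VariantRecord]
    fpkm_min: float
    #: fraction of records whose observed RNA detection status matches the
    #: expression-based expectation (low FPKM <=> not detected)
    concordance: float


class VafCorrelation(NamedTuple):
    r: float
    p_value: float
    n: int


def detectability_filter(
    records: Iterable[VariantRecord], fpkm_min: float = 1.0
) -> DetectabilityReport:
    """Split records into expected-detectable (FPKM >= floor) and expected-missed."""
    records = list(records)
    missed = [r for r in records if r.fpkm < fpkm_min]
    detectable = [r for r in records if r.fpkm >= fpkm_min]
    agree = sum(
        1 for r in records if (r.fpkm < fpkm_min) == (not r.detected_in_rna)
    )
    return DetectabilityReport(
        expected_detectable=detectable,
        expected_missed=missed,
        fpkm_min=fpkm_min,
        concordance=agree / len(records) if records else float("nan"),
    )


def vaf_correlation(
    records: Iterable[VariantRecord], fpkm_min: float | None = None
) -> VafCorrelation:
    """Pearson correlation between DNA and RNA allele fractions.

    All records carrying both VAFs enter the correlation; ``fpkm_min``
    optionally excludes variants in genes expressed below that level.  The
    p-value is the usual two-sided t-test with n - 2 degrees of freedom.
    """
    pairs = [
        (r.dna_vaf, r.rna_vaf)
        for r in records
        if r.rna_vaf is not None and (fpkm_min is None or r.fpkm >= fpkm_min)
    ]
    if len(pairs) < 3:
        raise ValidationError(
            f"need >= 3 records with both VAFs, got {len(pairs)}"
        )
    dna, rna = zip(*pairs)
    result = stats.pearsonr(dna, rna)
    return VafCorrelation(
        r=float(result.statistic), p_value=float(result.pvalue), n=len(pairs)
    )
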