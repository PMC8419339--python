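"""Synthetic FPKM matrices and variant tables with known ground truth.

The generator emulates the statistical structure the diagnosis pipeline
assumes, so every stage is testable without sequencing data:

* a planted set of AML-specific genes log-normally distributed around a high
  level (default 200 FPKM) in AML samples and a low level (default 20 FPKM)
  in B-ALL samples, and a mirrored B-ALL-specific set — i.e. >2-fold
  separation at >=100 FPKM, the regime the signature filters target;
* MPAL samples that partially activate both lineage programs: each MPAL
  sample draws a mixing fraction lambda and expresses a random
  lambda-fraction of each signature set at its own-lineage level;
* background genes at a per-gene level common to all groups;
* an ABL1 reference gene emitted at a fixed level, after which the whole
  sample column is multiplied by a per-sample scale factor — the distortion
  reference-gene normalization exists to undo.

All randomness flows through one :class:`numpy.random.Generator`, so a given
seed reproduces the matrix bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    DIAGNOSTIC_CATEGORIES,
    ValidationError,
    VariantRecord,
    validate_expression_matrix,
)

_SHORT = {"AML": "AML", "B-ALL": "BALL", "MPAL": "MPAL"}


@dataclass
class SyntheticConfig:
    """Study conditions for the expression generator.

    ``n_per_group`` is either one count for all three categories or a mapping
    per category.  Signature sizes default to the 251 AML- and 117
    B-ALL-specific genes of the reference signature; expression levels are in
    FPKM and noise is log-normal with ``sigma_log2`` standard deviation on the
    log2 scale.
    """

    n_per_group: int | Mapping[str, int] = 20
    n_aml_sig: int = 251
    n_ball_sig: int = 117
    n_background: int = 2000
    base_high: float = 200.0
    base_low: float = 20.0
    sigma_log2: float = 0.5
    mpal_mix_range: tuple[float, float] = (0.3, 0.7)
    sample_scale_range: tuple[float, float] = (0.5, 2.0)
    abl1_level: float = 100.0
    seed: int = 0

    def counts(self) -> dict[str, int]:
        if isinstance(self.n_per_group, Mapping):
            return {c: int(self.n_per_group.get(c, 0)) for c in DIAGNOSTIC_CATEGORIES}
        return {c: int(self.n_per_group) for c in DIAGNOSTIC_CATEGORIES}

    def validate(self) -> None:
        if min(self.n_aml_sig, self.n_ball_sig, self.n_background) < 0:
            raise ValidationError("gene counts must be >= 0")
        if any(n < 0 for n in self.counts().values()):
            raise ValidationError("sample counts must be >= 0")
        if not (self.base_high > 0 and self.base_low > 0 and self.abl1_level > 0):
            raise ValidationError("expression levels must be > 0")
        if self.sigma_log2 < 0:
            raise ValidationError("sigma_log2 must be >= 0")
        lo, hi = self.mpal_mix_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError(f"mpal_mix_range must lie inside (0, 1), got {self.mpal_mix_range}")
        slo, shi = self.sample_scale_range
        if not (0.0 < slo <= shi):
            raise ValidationError(f"invalid sample_scale_range {self.sample_scale_range}")


@dataclass
class GroundTruth:
    """What the generator planted: gene sets, labels, mixing fractions, scales."""

    aml_genes: list[str]
    ball_genes: list[str]
    background_genes: list[str]
    labels: pd.Series
    mpal_lambda: dict[str, float] = field(default_factory=dict)
    scale_factors: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "aml_genes": self.aml_genes,
                "ball_genes": self.ball_genes,
                "background_genes": self.background_genes,
                "labels": {k: v for k, v in self.labels.items()},
                "mpal_lambda": self.mpal_lambda,
                "scale_factors": self.scale_factors,
            },
            indent=2,
        )


def generate_expression(
    config: SyntheticConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Generate a labeled genes x samples FPKM matrix with planted signatures."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.counts()

    aml_genes = [f"AMLSIG{i:04d}" for i in range(config.n_aml_sig)]
    ball_genes = [f"BALLSIG{i:04d}" for i in range(config.n_ball_sig)]
    bg_genes = [f"BG{i:04d}" for i in range(config.n_background)]
    gene_ids = aml_genes + ball_genes + bg_genes + ["ABL1"]

    samples = []
    for cat in DIAGNOSTIC_CATEGORIES:
        samples += [f"{_SHORT[cat]}{i + 1:02d}" for i in range(counts[cat])]
    labels = pd.Series(
        sum(([cat] * counts[cat] for cat in DIAGNOSTIC_CATEGORIES), []),
        index=samples,
        name="label",
    )
    labels.index.name = "sample_id"
    if len(samples) == 0:
        raise ValidationError("configuration yields zero samples")

    log_high, log_low = np.log2(config.base_high), np.log2(config.base_low)
    # per-gene background level shared by all groups (log2-uniform, 1..512 FPKM)
    bg_log = rng.uniform(0.0, 9.0, size=config.n_background)

    n_genes = len(gene_ids) - 1  # ABL1 handled separately, noise-free
    means = np.empty((n_genes, len(samples)))
    mpal_lambda: dict[str, float] = {}
    a_sl = slice(0, config.n_aml_sig)
    b_sl = slice(config.n_aml_sig, config.n_aml_sig + config.n_ball_sig)
    for j, sample in enumerate(samples):
        cat = labels.iloc[j]
        col = np.empty(n_genes)
        col[a_sl] = log_high if cat == "AML" else log_low
        col[b_sl] = log_high if cat == "B-ALL" else log_low
        if cat == "MPAL":
            lam = float(rng.uniform(*config.mpal_mix_range))
            mpal_lambda[sample] = lam
            for sl, n_sig in ((a_sl, config.n_aml_sig), (b_sl, config.n_ball_sig)):
                n_hi = int(round(lam * n_sig))
                hi_idx = rng.choice(n_sig, size=n_hi, replace=False)
                block = np.full(n_sig, log_low)
                block[hi_idx] = log_high
                col[sl] = block
        col[config.n_aml_sig + config.n_ball_sig :] = bg_log
        means[:, j] = col

    noise = rng.normal(0.0, config.sigma_log2, size=means.shape)
    values = np.power(2.0, means + noise)
    values = np.vstack([values, np.full((1, len(samples)), config.abl1_level)])

    scales = rng.uniform(*config.sample_scale_range, size=len(samples))
    values = values * scales[None, :]

    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"), columns=samples)
    validate_expression_matrix(matrix)
    truth = GroundTruth(
        aml_genes=aml_genes,
        ball_genes=ball_genes,
        background_genes=bg_genes,
        labels=labels,
        mpal_lambda=mpal_lambda,
        scale_factors=dict(zip(samples, scales.astype(float))),
    )
    return matrix, labels, truth


def cohort12_config(seed: int = 0) -> SyntheticConfig:
    """A high-separation 12-sample cohort: 5 B-ALL, 3 AML, 4 MPAL.

    Mirrors the composition of a small clinical discovery cohort; the reduced
    log-noise and narrowed MPAL mixing range put the three categories in a
    strongly separated regime for cross-validation at discovery-cohort scale.
    """
    return SyntheticConfig(
        n_per_group={"B-ALL": 5, "AML": 3, "MPAL": 4},
        sigma_log2=0.25,
        mpal_mix_range=(0.4, 0.6),
        seed=seed,
    )


def generate_variant_table(
    n: int = 14,
    rho: float = 0.787,
    frac_low_expression: float = 2.0 / 14.0,
    seed: int = 0,
) -> list[VariantRecord]:
    """Variant records with a target DNA/RNA VAF correlation.

    DNA VAFs are uniform on [5, 70] percent; RNA VAFs are built from a
    bivariate-normal construction with correlation ``rho`` (matched mean and
    spread), clipped to [0, 100].  A ``frac_low_expression`` fraction of
    records sits below 1 FPKM, has no RNA VAF and is flagged undetected —
    mimicking variants RNA-seq cannot see for lack of transcript.
    Defaults mirror the 14-variant DNA-vs-RNA comparison of the reference
    cohort (n = 14, r ~ 0.787, 2/14 below 1 FPKM).
    """
    if n < 3:
        raise ValidationError(f"need n >= 3, got {n}")
    if not -1.0 <= rho <= 1.0:
        raise ValidationError(f"rho must lie in [-1, 1], got {rho}")
    if not 0.0 <= frac_low_expression < 1.0:
        raise ValidationError(
            f"frac_low_expression must lie in [0, 1), got {frac_low_expression}"
        )
    rng = np.random.default_rng(seed)
    dna = rng.uniform(5.0, 70.0, size=n)
    n_low = int(round(frac_low_expression * n))
    low_idx = set(rng.choice(n, size=n_low, replace=False).tolist())
    z = (dna - dna.mean()) / dna.std(ddof=0)
    noise = rng.normal(0.0, 1.0, size=n)
    mix = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
    rna = np.clip(dna.mean() + dna.std(ddof=0) * mix, 0.0, 100.0)
    fpkm_low = rng.uniform(0.05, 0.95, size=n)
    fpkm_high = rng.uniform(5.0, 300.0, size=n)
    records = []
    for i in range(n):
        low = i in low_idx
        records.append(
            VariantRecord(
                case_id=f"CASE{i + 1:02d}",
                gene=f"GENE{i + 1:02d}",
                dna_vaf=float(dna[i]),
                rna_vaf=None if low else float(rna[i]),
                fpkm=float(fpkm_low[i] if low else fpkm_high[i]),
                detected_in_rna=not low,
            )
        )
    return records
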