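"""End-to-end orchestration: simulate/load -> normalize -> select -> calibrate ->
score -> SVM cross-validation -> evaluation, with every artifact written to disk.

The configuration is a plain mapping (usually parsed from YAML).  Top-level
keys:

``simulation``
    Synthetic-generator settings (:class:`~leukodx.simulate.SyntheticConfig`
    fields); mutually exclusive with ``matrix``/``labels`` paths.
``normalize``
    ``{"reference_gene": "ABL1", "target_level": null}`` — rescale every
    sample by the reference gene before any model step; ``null`` anchors to
    the cohort median.
``selection`` / ``scoring`` / ``svm``
    Filter, cutoff and kernel settings passed through to the respective
    modules.

Every run writes ``run_config.json`` recording the seeds, thresholds and
parameters actually used.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import evaluation as ev
from .io import (
    ValidationError,
    align_labels,
    read_expression_matrix,
    read_labels,
    write_expression_matrix,
    write_labels,
)
from .normalize import abl1_normalize
from .scoring import DEFAULT_CUTOFF, ScorePair, calibrate_thresholds, classify, compute_scores
from .selection import differential_test, select_signature
from .simulate import SyntheticConfig, generate_expression
from .svm import leave_one_out_cv

log = logging.getLogger("leukodx")


def _get(config: Mapping[str, Any], key: str) -> dict:
    value = config.get(key) or {}
    if not isinstance(value, Mapping):
        raise ValidationError(f"config section {key!r} must be a mapping")
    return dict(value)


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Path]:
    """Execute the full differential-diagnosis pipeline; returns artifact paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    sim = _get(config, "simulation")
    if sim:
        sim_config = SyntheticConfig(**sim)
        log.info("simulating expression data (seed=%s)", sim_config.seed)
        matrix, labels, truth = generate_expression(sim_config)
        artifacts["matrix"] = outdir / "matrix.tsv"
        artifacts["labels"] = outdir / "labels.tsv"
        artifacts["ground_truth"] = outdir / "ground_truth.json"
        write_expression_matrix(matrix, artifacts["matrix"])
        write_labels(labels, artifacts["labels"])
        artifacts["ground_truth"].write_text(truth.to_json())
    else:
        if "matrix" not in config:
            raise ValidationError("config needs either a 'simulation' block or a 'matrix' path")
        if "labels" not in config:
            raise ValidationError("config needs a 'labels' table path")
        matrix = read_expression_matrix(config["matrix"])
        labels = read_labels(config["labels"])
    labels = align_labels(matrix, labels)

    norm = _get(config, "normalize")
    if norm:
        reference = norm.get("reference_gene", "ABL1")
        target = norm.get("target_level")
        log.info("normalizing by reference gene %s (target=%s)", reference, target)
        matrix = abl1_normalize(matrix, reference, target)

    sel = _get(config, "selection")
    log.info("selecting signature genes (filters: %s)", sel or "defaults")
    results = differential_test(matrix, labels, "AML", "B-ALL")
    model = select_signature(
        results,
        fold_min=float(sel.get("fold_min", 2.0)),
        q_max=float(sel.get("q_max", 0.05)),
        fpkm_min=float(sel.get("fpkm_min", 100.0)),
    )
    artifacts["differential"] = outdir / "differential.tsv"
    results.to_csv(artifacts["differential"], sep="\t")

    scoring_cfg = _get(config, "scoring")
    cutoff = float(scoring_cfg.get("cutoff", DEFAULT_CUTOFF))
    model = calibrate_thresholds(matrix, labels, model, cutoff=cutoff)
    log.info(
        "calibrated %d thresholds (reference level=%s)",
        len(model.thresholds),
        model.reference_level,
    )
    artifacts["signature"] = outdir / "signature.json"
    model.save(artifacts["signature"])

    scores = compute_scores(matrix, model)
    calls = [
        classify(ScorePair(a, b), cutoff)
        for a, b in zip(scores["aml_score"], scores["ball_score"])
    ]
    score_table = scores.assign(call=calls)
    artifacts["scores"] = outdir / "scores.tsv"
    score_table.to_csv(artifacts["scores"], sep="\t")
    artifacts["scatter"] = outdir / "scatter.tsv"
    ev.scatter_export(scores, labels).to_csv(artifacts["scatter"], sep="\t")

    svm_cfg = _get(config, "svm")
    log.info("running leave-one-out SVM cross-validation")
    cv = leave_one_out_cv(
        matrix,
        labels,
        feature_genes=model.genes,
        C=float(svm_cfg.get("C", 1.0)),
        gamma=svm_cfg.get("gamma", "auto"),
        coef0=float(svm_cfg.get("coef0", 0.0)),
    )
    artifacts["svm_crossval"] = outdir / "svm_crossval.tsv"
    cv.predictions.to_csv(artifacts["svm_crossval"], sep="\t")

    score_report = ev.evaluate_predictions(labels, pd.Series(calls, index=scores.index))
    anova = ev.compare_scores_anova(scores, labels)
    artifacts["confusion"] = outdir / "confusion.tsv"
    score_report.confusion.to_csv(artifacts["confusion"], sep="\t")
    artifacts["anova"] = outdir / "anova_pairwise.tsv"
    anova.pairwise.to_csv(artifacts["anova"], sep="\t", index=False)
    summary = {
        "scoring": {
            "accuracy": score_report.accuracy,
            "sensitivity": score_report.sensitivity,
            "specificity": score_report.specificity,
        },
        "svm_loocv": {
            "accuracy": cv.accuracy,
            "sensitivity": cv.sensitivity,
            "specificity": cv.specificity,
        },
        "anova": {
            score: dict(row) for score, row in anova.anova.iterrows()
        },
        "n_samples": int(len(labels)),
        "n_signature_genes": len(model.genes),
    }
    artifacts["summary"] = outdir / "summary.json"
    artifacts["summary"].write_text(json.dumps(summary, indent=2))

    used = {
        "simulation": sim or None,
        "normalize": norm or None,
        "selection": {
            "fold_min": float(sel.get("fold_min", 2.0)),
            "q_max": float(sel.get("q_max", 0.05)),
            "fpkm_min": float(sel.get("fpkm_min", 100.0)),
        },
        "scoring": {"cutoff": cutoff},
        "svm": {
            "C": float(svm_cfg.get("C", 1.0)),
            "gamma": svm_cfg.get("gamma", "auto"),
            "coef0": float(svm_cfg.get("coef0", 0.0)),
        },
    }
    artifacts["run_config"] = outdir / "run_config.json"
    artifacts["run_config"].write_text(json.dumps(used, indent=2))
    log.info("wrote %d artifacts to %s", len(artifacts), outdir)
    return artifacts
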