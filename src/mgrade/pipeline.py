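"""End-to-end training pipeline: DE -> GGI labeling -> elimination -> final model."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classifier, diffexp, ggi
from .datatypes import CancerConfig, ClinicalTable, ExpressionMatrix, config_for

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "train_pipeline"]


@dataclass
class PipelineResult:
    signature: diffexp.SignatureGeneSets
    labeling: ggi.GGILabeling
    mgrade_labels: pd.Series
    trace: classifier.EliminationTrace
    model: classifier.TrainedGradeModel


def train_pipeline(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    config: CancerConfig | None = None,
    seed: int = 0,
    counts_input: bool = False,
    elimination_grid: list | None = None,
    final_grid: list | None = "default",
) -> PipelineResult:
    """Train a grade classifier from a labeled cohort.

    Steps: differential expression of histological G3/G4 vs G1 samples;
    signature filtering; unscaled GGI + Cox threshold scan to produce mGrade
    training labels; SHAP-guided recursive elimination of the signature down
    to the stop size; selection of the best-CV-loss geneset; final model fit
    with a CV-tuned hyperparameter grid.
    """
    if config is None:
        config = config_for("custom")
    grade = clin.grade.reindex(expr.sample_ids)
    de_groups = pd.Series(
        np.where(grade.isin(["G3", "G4"]), "high", np.where(grade == "G1", "low", None)),
        index=grade.index,
        dtype=object,
    ).dropna()
    de = diffexp.de_test(expr, de_groups, counts_input=counts_input)
    signature = diffexp.select_signature_genes(de, config, expr.platform)
    logger.info(
        "signature: %d up-in-high, %d up-in-low genes",
        len(signature.up_in_high), len(signature.up_in_low),
    )

    scores = ggi.compute_ggi(expr, signature)
    labeling = ggi.scan_ggi_threshold(scores, clin)
    mgrade_labels = ggi.assign_mgrade_labels(labeling, config)

    trace = classifier.recursive_elimination(
        expr, mgrade_labels, signature.all_genes, config,
        seed=seed, param_grid=elimination_grid, positive=config.high_label,
    )
    best_genes = classifier.select_best_geneset(trace)
    grid = classifier.default_param_grid(config) if final_grid == "default" else final_grid
    model = classifier.train_final(
        expr, mgrade_labels, best_genes, config,
        seed=seed, param_grid=grid, trace=trace, positive=config.high_label,
    )
    return PipelineResult(signature, labeling, mgrade_labels, trace, model)
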