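"""Evaluation pipeline: run all metric groups over a set of tables and
collect the results for reporting.

Metric groups and what they mean
--------------------------------
1. depth — identified/quantifiable feature counts, overlap, missingness
2. normalization — abundance distributions, pairwise AUROC similarity
3. batch — silhouette width and principal-component regression on batches
4. signal — complex-pair correlation, network function prediction, class
   prediction, clustering concordance
5. reproducibility — QC-replicate CV distribution
6. concordance — paired-omics gene-wise / sample-wise correlation

Supervised metrics (class prediction, clustering concordance) run on the
study samples only; QC replicates are excluded there because they carry no
class of interest, but participate in all technical metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import batch as batch_mod
from . import depth as depth_mod
from . import normalization as norm_mod
from . import repro as repro_mod
from . import signal as signal_mod
from .datatypes import (
    EvaluationConfig,
    GeneSetCollection,
    OmicsDataTable,
    SampleAnnotation,
    ValidationError,
)
from .io import align_tables

logger = logging.getLogger(__name__)

GROUPS = ("depth", "normalization", "batch", "signal", "reproducibility", "concordance")


@dataclass
class TableEvaluation:
    """All per-table results; a group left at None was skipped."""

    table_name: str
    depth: depth_mod.DepthSummary | None = None
    distribution: norm_mod.DistributionSimilarity | None = None
    abundance_summary: pd.DataFrame | None = None
    batch: batch_mod.BatchAssessment | None = None
    complex_corr: signal_mod.ComplexCorrelationResult | None = None
    function_pred: signal_mod.FunctionPredictionResult | None = None
    class_pred: signal_mod.ClassPredictionResult | None = None
    clustering: signal_mod.ClusteringResult | None = None
    cv: repro_mod.CvResult | None = None
    concordance: repro_mod.ConcordanceResult | None = None
    skipped: dict[str, str] = field(default_factory=dict)


@dataclass
class RadarScores:
    table_name: str
    scores: dict[str, float | None]  # group -> score in [0,1], None = absent
    mapping_record: dict[str, str]


@dataclass
class EvaluationReport:
    tables: dict[str, TableEvaluation]
    overlap: pd.DataFrame | None
    radar: dict[str, RadarScores]
    annotation: SampleAnnotation
    config: EvaluationConfig


def _rescale_auroc(a: float) -> float:
    """Map an AUROC in [0.5, 1] onto [0, 1], clamping below 0.5."""
    return float(np.clip((a - 0.5) / 0.5, 0.0, 1.0))


def normalize_scores(evaluations: dict[str, TableEvaluation]) -> dict[str, RadarScores]:
    """Map raw metrics onto comparable [0, 1] radar scores per table.

    The mapping is fixed and recorded alongside each score so comparisons
    are auditable:

    - depth: n_quantifiable / max(n_quantifiable over tables)
    - normalization: distribution similarity score (already in [0, 1])
    - batch: mean of 1 − clamp(ASW, 0, 1) and 1 − PCR R² (higher = cleaner)
    - signal: mean of the available AUROCs (complex separation, median
      function prediction, class prediction), each rescaled [0.5, 1] → [0, 1]
    - reproducibility: fraction of QC CVs below the threshold
    - concordance: clamp(median gene-wise r, 0, 1)

    Skipped groups stay ``None`` (absent), never zero.
    """
    if not evaluations:
        raise ValidationError("no evaluated tables")
    max_quant = max(
        (ev.depth.n_quantifiable for ev in evaluations.values() if ev.depth),
        default=0,
    )
    mapping = {
        "depth": "n_quantifiable / max over tables",
        "normalization": "mean over sample pairs of 1 - 2|AUROC - 0.5|",
        "batch": "mean of 1 - clamp(ASW, 0, 1) and 1 - PCR R^2",
        "signal": "mean of available AUROCs rescaled from [0.5, 1] to [0, 1]",
        "reproducibility": "fraction of QC CVs below threshold",
        "concordance": "clamp(median gene-wise Spearman r, 0, 1)",
    }
    out: dict[str, RadarScores] = {}
    for name, ev in evaluations.items():
        scores: dict[str, float | None] = {g: None for g in GROUPS}
        if ev.depth and max_quant > 0:
            scores["depth"] = ev.depth.n_quantifiable / max_quant
        if ev.distribution:
            scores["normalization"] = float(ev.distribution.similarity_score)
        if ev.batch:
            asw_q = 1.0 - float(np.clip(ev.batch.asw_batch, 0.0, 1.0))
            pcr_q = 1.0 - float(np.clip(ev.batch.pcr_batch_r2, 0.0, 1.0))
            scores["batch"] = (asw_q + pcr_q) / 2.0
        sig_parts = []
        if ev.complex_corr:
            sig_parts.append(_rescale_auroc(ev.complex_corr.separation_auroc))
        if ev.function_pred and ev.function_pred.median_auroc is not None:
            sig_parts.append(_rescale_auroc(ev.function_pred.median_auroc))
        if ev.class_pred:
            sig_parts.append(_rescale_auroc(ev.class_pred.cv_auroc))
        if sig_parts:
            scores["signal"] = float(np.mean(sig_parts))
        if ev.cv:
            scores["reproducibility"] = float(ev.cv.fraction_below_threshold)
        if ev.concordance:
            scores["concordance"] = float(
                np.clip(ev.concordance.median_genewise_r, 0.0, 1.0)
            )
        out[name] = RadarScores(table_name=name, scores=scores, mapping_record=mapping)
    return out


def evaluate_tables(
    tables: list[OmicsDataTable],
    annotation: SampleAnnotation,
    config: EvaluationConfig | None = None,
    complexes: GeneSetCollection | None = None,
    pathways: GeneSetCollection | None = None,
    paired: OmicsDataTable | None = None,
) -> EvaluationReport:
    """Run every applicable metric group on every table.

    Inapplicable groups (no QC samples, no gene sets, no paired table, a
    single batch...) are skipped per table with the reason recorded;
    everything computable is computed.
    """
    config = config or EvaluationConfig()
    aligned, ann = align_tables(tables, annotation)
    study_samples = [s for s in ann.sample_ids if s not in set(ann.qc_samples)]

    evaluations: dict[str, TableEvaluation] = {}
    for table in aligned:
        ev = TableEvaluation(table_name=table.name)

        ev.depth = depth_mod.depth_summary(table, config)
        ev.distribution = norm_mod.pairwise_distribution_auroc(table)
        ev.abundance_summary = norm_mod.abundance_distribution_summary(table)[0]
        ev.batch = batch_mod.assess_batch_effect(table, ann.batches, config)

        study_table = (
            table.subset_samples(study_samples) if len(study_samples) >= 3 else table
        )
        study_ann = ann.subset(study_table.sample_ids)

        if complexes is not None:
            try:
                ev.complex_corr = signal_mod.complex_pair_correlations(
                    table,
                    complexes,
                    n_pairs=config.n_complex_pairs,
                    seed=config.random_seed,
                    min_complete=config.min_complete_pairs,
                )
            except ValidationError as exc:
                ev.skipped["complex_corr"] = str(exc)
        else:
            ev.skipped["complex_corr"] = "no complex gene sets supplied"
        if pathways is not None:
            try:
                network = signal_mod.build_coexpression_network(table, config)
                ev.function_pred = signal_mod.function_prediction_auroc(
                    network, pathways, config, table_name=table.name
                )
            except ValidationError as exc:
                ev.skipped["function_pred"] = str(exc)
        else:
            ev.skipped["function_pred"] = "no pathway gene sets supplied"
        try:
            ev.class_pred = signal_mod.class_prediction_cv_auroc(
                study_table, study_ann, config
            )
        except ValidationError as exc:
            ev.skipped["class_pred"] = str(exc)
        try:
            ev.clustering = signal_mod.clustering_concordance(study_table, study_ann)
        except ValidationError as exc:
            ev.skipped["clustering"] = str(exc)
        try:
            ev.cv = repro_mod.qc_cv(table, ann, config)
        except ValidationError as exc:
            ev.skipped["reproducibility"] = str(exc)
        if paired is not None:
            try:
                ev.concordance = repro_mod.paired_omics_concordance(
                    table, paired, min_complete=config.min_complete_pairs
                )
            except ValidationError as exc:
                ev.skipped["concordance"] = str(exc)
        else:
            ev.skipped["concordance"] = "no paired-omics table supplied"
        evaluations[table.name] = ev

    overlap = (
        depth_mod.feature_overlap_sets(aligned) if len(aligned) >= 2 else None
    )
    radar = normalize_scores(evaluations)
    return EvaluationReport(
        tables=evaluations,
        overlap=overlap,
        radar=radar,
        annotation=ann,
        config=config,
    )
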