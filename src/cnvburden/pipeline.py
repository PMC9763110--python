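"""End-to-end pipeline: consensus -> QC -> burden -> association -> meta.

`run_pipeline` chains the stages on in-memory tables and returns every
intermediate product plus a structured log of record counts, mirroring how
the stages would be chained from the command line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationBundle
from .association import (
    BurdenRegression,
    EnrichmentRegression,
    fit_ordinal,
    rescale_phenotype,
)
from .burden import BurdenEncoder
from .consensus import ConsensusCaller
from .io import CALL_COLUMNS
from .meta import meta_analyze
from .qc import CNVCallFilter, FilterConfig, SampleOutlierFilter, chromosome_cnv_fractions

__all__ = ["PipelineResult", "run_pipeline", "prepare_analysis_table"]

SPAN_TERMS = (
    "span_total_mb",
    "span_del_mb",
    "span_dup_mb",
    "span_ndd_del_mb",
    "span_ndd_dup_mb",
    "span_nonndd_del_mb",
    "span_nonndd_dup_mb",
)


@dataclass
class PipelineResult:
    consensus: pd.DataFrame
    conflicts: pd.DataFrame
    sample_report: pd.DataFrame
    cnv_report: pd.DataFrame
    burden: pd.DataFrame
    data: pd.DataFrame
    cohort_results: pd.DataFrame
    meta: pd.DataFrame
    meta_or: pd.DataFrame | None = None
    log: dict = field(default_factory=dict)


def prepare_analysis_table(
    subjects: pd.DataFrame, qc_metrics: pd.DataFrame, burden: pd.DataFrame
) -> pd.DataFrame:
    """Merge subjects, LRR-SD and burden features; add the 0-1 phenotype."""
    data = subjects.merge(
        qc_metrics[["sample_id", "lrr_sd"]], on="sample_id", how="left"
    ).merge(burden.reset_index(), on="sample_id", how="left")
    burden_cols = burden.columns
    data[burden_cols] = data[burden_cols].fillna(0)
    pheno01 = np.full(len(data), np.nan)
    for (lo, hi), g in data[~data["is_case_control"]].groupby(
        ["assessment_min", "assessment_max"]
    ):
        pheno01[g.index] = rescale_phenotype(
            g["phenotype_raw"].to_numpy(), lo, hi, sample_ids=g["sample_id"].tolist()
        )
    return data.assign(phenotype01=pheno01)


def run_pipeline(
    callsets: pd.DataFrame,
    qc_metrics: pd.DataFrame,
    subjects: pd.DataFrame,
    annotation: AnnotationBundle,
    filter_config: FilterConfig | None = None,
    include_carriers: bool = True,
    include_genes: bool = True,
    include_genesets: bool = True,
    gene_frequency_threshold: float = 1e-4,
    ordinal_terms: tuple[str, ...] = (),
    heterogeneity: bool = False,
) -> PipelineResult:
    """Run the full analysis on one study's inputs.

    Parameters mirror the pipeline stages; the gene family only includes
    genes whose carrier frequency reaches ``gene_frequency_threshold``
    (carriers / analysis subjects). ``ordinal_terms`` selects burden terms
    for which odds-ratio estimates are additionally produced by ordinal
    logistic regression (score cohorts) and meta-analysed on the log-OR
    scale.
    """
    cfg = filter_config or FilterConfig()
    log: dict = {"input_calls": len(callsets), "input_samples": len(subjects)}

    caller = ConsensusCaller(probes=annotation.probes)
    consensus = caller.transform(callsets[CALL_COLUMNS])
    conflicts = caller.report_["conflicts"]
    log.update({k: v for k, v in caller.report_.items() if k != "conflicts"})

    # per-sample CNV load, computed on the consensus set
    load = (
        consensus.assign(kb=(consensus["end"] - consensus["start"]) / 1e3)
        .groupby("sample_id")
        .agg(cnv_count=("kb", "size"), kb_burden=("kb", "sum"))
        .reset_index()
    )
    metrics = qc_metrics.merge(load, on="sample_id", how="left").fillna(
        {"cnv_count": 0, "kb_burden": 0.0}
    )
    fractions = chromosome_cnv_fractions(consensus, annotation.chrom_lengths)

    sampler = SampleOutlierFilter(
        iqr_multiplier=cfg.iqr_multiplier, aneuploidy_fraction=cfg.aneuploidy_fraction
    )
    sampler.fit(metrics, fractions)
    consensus_kept = sampler.transform(consensus)
    subjects_kept = subjects[subjects["sample_id"].isin(sampler.passed_)].reset_index(drop=True)
    log["samples_failed_qc"] = int((~sampler.report_["pass"]).sum())
    log["samples_analyzed"] = len(subjects_kept)

    cnv_filter = CNVCallFilter(
        annotation,
        special_region_overlap=cfg.special_region_overlap,
        segdup_overlap=cfg.segdup_overlap,
        max_frequency=cfg.max_frequency,
        min_length_bp=cfg.min_length_bp,
        min_probes=cfg.min_probes,
    )
    cnv_filter.fit(consensus_kept, n_samples=len(subjects_kept))
    analysis_calls = cnv_filter.transform(consensus_kept)
    log.update(cnv_filter.summary_)

    features = ["spans"]
    if include_carriers:
        features.append("carriers")
    if include_genes or include_genesets:
        features.append("genes")
    if include_genesets:
        features.append("genesets")
    encoder = BurdenEncoder(annotation, features=tuple(features))
    burden = encoder.transform(analysis_calls, subjects=subjects_kept["sample_id"])

    data = prepare_analysis_table(subjects_kept, qc_metrics, burden)

    terms: list[tuple[str, bool]] = [(t, False) for t in SPAN_TERMS]
    if include_carriers:
        carrier_cols = [c for c in burden.columns if c.startswith("carrier__")]
        terms += [(c, False) for c in carrier_cols if burden[c].sum() > 0]
    if include_genes:
        n = len(subjects_kept)
        for c in burden.columns:
            if c.startswith(("gene__", "gene_del__", "gene_dup__")):
                if burden[c].sum() / n >= gene_frequency_threshold:
                    terms.append((c, False))
    if include_genesets:
        terms += [
            (c, True) for c in burden.columns
            if c.startswith(("geneset__", "geneset_del__", "geneset_dup__"))
        ]

    rows = []
    for term, enrichment in terms:
        est = (EnrichmentRegression if enrichment else BurdenRegression)(term=term)
        est.fit(data)
        rows.extend(r.to_dict() for r in est.results_)
    cohort_results = pd.DataFrame(rows)
    log["terms_tested"] = len(terms)

    meta = meta_analyze(cohort_results, heterogeneity=heterogeneity)

    meta_or_df = None
    if ordinal_terms:
        or_rows = []
        score_data = data[~data["is_case_control"]]
        for term in ordinal_terms:
            for r in fit_ordinal(score_data, term):
                or_rows.append(r.to_dict())
        if or_rows:
            or_results = pd.DataFrame(or_rows)
            meta_or_df = meta_analyze(or_results, or_scale=True)

    return PipelineResult(
        consensus=consensus,
        conflicts=conflicts,
        sample_report=sampler.report_,
        cnv_report=cnv_filter.report_,
        burden=burden,
        data=data,
        cohort_results=cohort_results,
        meta=meta,
        meta_or=meta_or_df,
        log=log,
    )
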