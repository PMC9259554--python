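"""End-to-end orchestration: spectra + manifest + config -> peak
matrix -> binary matrix -> rankings -> clustering -> performance
tables.  Thin glue over the stage modules; each artifact of a run is
kept so the CLI and tests can serialise or inspect any stage.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import classify, cluster, features, peaks, preprocess
from .io import PipelineConfig, RawSpectrum, SampleManifest

logger = logging.getLogger("pepstrat")


@dataclass
class PipelineResult:
    config: PipelineConfig
    peak_matrix_raw: peaks.PeakMatrix      # per-replicate, pre-averaging
    peak_matrix: peaks.PeakMatrix          # averaged + occurrence-filtered
    binary: features.BinaryMatrix
    labels: pd.Series                      # sample_id -> group
    ranking_bda: features.FeatureRanking
    ranking_rf: features.FeatureRanking
    clusters: cluster.ClusterResult
    pca: cluster.PcaResult
    split: classify.SplitSpec
    performance_test: pd.DataFrame
    performance_cv: pd.DataFrame


def build_peak_matrix(spectra: list[RawSpectrum], manifest: SampleManifest,
                      config: PipelineConfig) -> tuple[peaks.PeakMatrix,
                                                       peaks.PeakMatrix]:
    """Preprocess every non-excluded spectrum, detect and bin peaks,
    average replicates, filter rare bins.  Returns (per-replicate
    matrix, averaged+filtered matrix)."""
    excluded = set(
        manifest.table.loc[manifest.table["excluded"], "sample_id"] + "::r"
        + manifest.table.loc[manifest.table["excluded"], "replicate"].astype(str))
    peak_lists = []
    for s in spectra:
        if f"{s.sample_id}::r{s.replicate}" in excluded:
            continue
        processed = preprocess.preprocess_spectrum(s, config)
        peak_lists.append(peaks.detect_peaks(processed, config.snr,
                                             config.peak_half_window))
    logger.info("detected peaks in %d spectra (median %d peaks/spectrum)",
                len(peak_lists),
                int(pd.Series([len(p) for p in peak_lists]).median()))
    matrix_raw = peaks.bin_peaks(peak_lists, config.bin_tolerance)
    averaged = peaks.average_replicates(matrix_raw, manifest)
    filtered = peaks.filter_occurrence(averaged, config.min_occurrence_frac)
    logger.info("peak matrix: %d samples x %d bins (of %d before the "
                "occurrence filter)", filtered.n_samples, filtered.n_bins,
                averaged.n_bins)
    return matrix_raw, filtered


def run_pipeline(spectra: list[RawSpectrum], manifest: SampleManifest,
                 config: PipelineConfig) -> PipelineResult:
    """The full analysis on an in-memory dataset."""
    matrix_raw, matrix = build_peak_matrix(spectra, manifest, config)
    labels = manifest.sample_groups().reindex(matrix.values.index)
    binary = features.dichotomize(matrix, labels, mode=config.binarize_mode)

    ranking_bda = features.bda_tscores(binary, labels)
    ranking_rf = features.rf_importance_ranking(binary, labels,
                                                n_trees=config.n_trees,
                                                seed=config.seed)

    top_bins = features.select_top_k(ranking_bda, min(config.top_k,
                                                      matrix.n_bins))
    b_top = binary.subset(top_bins)
    clusters = cluster.hkmeans(b_top, config.n_clusters, labels=labels)
    pca_result = cluster.pca(b_top.values)

    split = classify.split_train_test(manifest, config.train_frac, config.seed)
    k_values = tuple(k for k in (5, 10, 15, 20) if k <= matrix.n_bins)
    perf_test, perf_cv = classify.evaluate_grid(
        binary, labels, split, algorithms=("BDA", "RF"), k_values=k_values,
        cv_folds=config.cv_folds, cv_repeats=config.cv_repeats,
        seed=config.seed, n_trees=config.n_trees,
        positive_classes=config.positive_groups)
    return PipelineResult(config=config, peak_matrix_raw=matrix_raw,
                          peak_matrix=matrix, binary=binary, labels=labels,
                          ranking_bda=ranking_bda, ranking_rf=ranking_rf,
                          clusters=clusters, pca=pca_result, split=split,
                          performance_test=perf_test, performance_cv=perf_cv)
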