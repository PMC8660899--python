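"""End-to-end convenience wrappers chaining the normalization and test steps.

Proteome order of operations: riBAQ -> minimum-detection filter ->
(optional) constitutive filter -> replicate averaging -> quantile
normalization -> log10.  Transcriptome: size-factor normalization +
shifted log2 -> replicate averaging.  The stage-paired permutation test
runs on the resulting "expression values"; the fold-change census runs on
the linear averaged matrix before quantile normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datamodel import ExpressionMatrix
from .de import classify_up_down, fold_change_census, paired_de_test
from .normalize import (
    NormalizationReport,
    average_replicates,
    compute_ribaq,
    filter_constitutive,
    filter_min_detection,
    log_transform,
    normalize_counts,
    quantile_normalize,
)


@dataclass
class ProteomeRun:
    """Artifacts of a full proteome pipeline run."""

    expression: ExpressionMatrix          # log10 expression values
    linear_averaged: ExpressionMatrix     # linear riBAQ after averaging
    report: NormalizationReport
    de: pd.DataFrame | None = None
    census: pd.DataFrame | None = None


def proteome_expression_values(
    matrix: ExpressionMatrix,
    constitutive: bool = True,
    min_samples: int = 2,
    average_before_quantile: bool = True,
) -> ProteomeRun:
    """Raw iBAQ intensities -> log10 expression values.

    ``average_before_quantile`` reflects the adopted reading of the
    pipeline order (averaging first, then quantile normalization); the
    switch allows the alternative order.
    """
    ribaq = compute_ribaq(matrix)
    filtered, report = filter_min_detection(ribaq, min_samples=min_samples)
    if constitutive:
        filtered = filter_constitutive(filtered)
        report.n_constitutive = filtered.n_features
    if average_before_quantile:
        averaged = average_replicates(filtered)
        normalized, reference = quantile_normalize(averaged)
    else:
        qn, reference = quantile_normalize(filtered)
        normalized = average_replicates(qn)
        averaged = average_replicates(filtered)
    report.quantile_reference = reference
    expression = log_transform(normalized, base=10)
    return ProteomeRun(
        expression=expression, linear_averaged=averaged, report=report
    )


def run_proteome_pipeline(
    matrix: ExpressionMatrix,
    pairing: str = "stage",
    alpha_fdr: float = 0.1,
    fc_cut: float = 2.0,
    thresholds=(4, 5, 6, 7, 8),
    constitutive: bool = True,
) -> ProteomeRun:
    """Full proteome analysis: normalization, paired test, census.

    In ``stage_replicate`` pairing mode the permutation test runs on the
    quantile-normalized, *unaveraged* per-replicate expression values
    (replicate pairs within stages), while the census and fold changes
    always use the replicate-averaged linear matrix.
    """
    run = proteome_expression_values(matrix, constitutive=constitutive)
    if pairing == "stage_replicate":
        ribaq = compute_ribaq(matrix)
        filtered, _ = filter_min_detection(ribaq)
        if constitutive:
            filtered = filter_constitutive(filtered)
        qn, _ = quantile_normalize(filtered)
        test_matrix = log_transform(qn, base=10)
    else:
        test_matrix = run.expression
    run.de = paired_de_test(
        test_matrix, pairing=pairing, alpha_fdr=alpha_fdr, fc_cut=fc_cut
    )
    run.census = fold_change_census(run.linear_averaged, thresholds=thresholds)
    return run


def run_transcriptome_pipeline(
    matrix: ExpressionMatrix,
    pairing: str = "stage",
    alpha_fdr: float = 0.1,
) -> tuple[pd.DataFrame, NormalizationReport]:
    """Transcript counts -> expression values -> paired permutation test."""
    normalized, report = normalize_counts(matrix)
    averaged = average_replicates(normalized) if pairing == "stage" else normalized
    de = paired_de_test(averaged, pairing=pairing, alpha_fdr=alpha_fdr)
    return de, report
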