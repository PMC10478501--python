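"""Gene, sample and summary-statistic filters producing the analysis matrix.

The raw abundance matrix (TPM scale) is reduced to the analysis-ready
log2(TPM + 1) matrix in three steps:

1. ``filter_genes`` — drop organellar/rDNA compartments, transposable
   elements, pseudogenes and transcripts shorter than 150 nt, then
   re-estimate TPM over the surviving genes so every sample sums to 10^6.
2. ``filter_samples`` — drop libraries with fewer than 2 M mapped reads and
   PCA outliers (> 4 SD from the centroid on PC1 or PC2 of the
   gene-centred log2 matrix).
3. ``filter_expression_stats`` — keep genes whose trimmed mean of log2
   values exceeds 0.3 and whose coefficient of variation exceeds 0.15.

All thresholds are strict inequalities and configurable.  Outputs are
sorted by gene and sample id, and each filter records what it removed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import trim_mean
from sklearn.decomposition import PCA

from .containers import (AnnotationError, ConfigurationError, ExpressionMatrix,
                         InsufficientDataError)

__all__ = ["filter_genes", "filter_samples", "filter_expression_stats",
           "preprocess", "FilterReport"]

logger = logging.getLogger(__name__)

EXCLUDED_COMPARTMENTS = {"ChrC", "ChrM", "chloroplast", "mitochondria"}
EXCLUDED_BIOTYPES = {"transposable_element", "TE", "pseudogene", "rDNA"}
MIN_EFFECTIVE_LENGTH = 150
TPM_TARGET = 1_000_000.0


class FilterReport:
    """Per-item record of which rule removed which gene/sample."""

    def __init__(self):
        self.rows: list[tuple[str, str, str]] = []

    def add(self, kind: str, item: str, rule: str) -> None:
        self.rows.append((kind, item, rule))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["kind", "item", "rule"])


def filter_genes(raw: ExpressionMatrix, annotation: pd.DataFrame,
                 min_length: int = MIN_EFFECTIVE_LENGTH,
                 report: FilterReport | None = None) -> ExpressionMatrix:
    """Apply compartment/biotype/length filters and re-estimate TPM.

    ``raw`` must be on the linear TPM (or count) scale.  Returns the
    log2(TPM + pseudocount) matrix over the surviving genes, each sample
    re-scaled to sum to 10^6.
    """
    if raw.scale != "linear":
        raise ConfigurationError("filter_genes expects a linear-scale matrix")
    unknown = raw.gene_ids.difference(annotation.index)
    if len(unknown) > 0:
        raise AnnotationError(
            f"{len(unknown)} genes missing from annotation, e.g. "
            f"{list(unknown[:5])}")
    ann = annotation.loc[raw.gene_ids]
    keep = pd.Series(True, index=raw.gene_ids)
    rules = {
        "excluded compartment":
            ann["chromosome"].isin(EXCLUDED_COMPARTMENTS),
        "excluded biotype": ann["biotype"].isin(EXCLUDED_BIOTYPES),
        f"effective length < {min_length}":
            ann["effective_length"] < min_length,
    }
    for rule, mask in rules.items():
        for gid in raw.gene_ids[mask & keep]:
            if report is not None:
                report.add("gene", gid, rule)
        keep &= ~mask
    data = raw.data.loc[keep[keep].index]
    colsum = data.sum(axis=0)
    if (colsum <= 0).any():
        raise ConfigurationError("a sample has zero total abundance after "
                                 "gene filtering")
    tpm = data * (TPM_TARGET / colsum)
    log2 = np.log2(tpm + raw.pseudocount)
    return ExpressionMatrix(log2, scale="log2",
                            pseudocount=raw.pseudocount).sorted()


def filter_samples(expr: ExpressionMatrix, meta: pd.DataFrame,
                   min_reads: int = 2_000_000, pca_sd_k: float = 4.0,
                   report: FilterReport | None = None
                   ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop low-coverage libraries and whole-transcriptome PCA outliers."""
    if expr.scale != "log2":
        raise ConfigurationError("filter_samples expects the log2 matrix")
    meta = meta.loc[expr.sample_ids]
    if meta["mapped_reads"].isna().any():
        raise ConfigurationError("mapped_reads required for every sample")
    low = meta.index[meta["mapped_reads"] < min_reads]
    for sid in low:
        if report is not None:
            report.add("sample", sid, f"mapped reads < {min_reads}")
    keep = expr.sample_ids.difference(low)
    data = expr.data[list(keep)]

    # PCA on gene-centred log2 values, samples as observations
    centred = (data.sub(data.mean(axis=1), axis=0)).T.to_numpy()
    if centred.shape[0] >= 3 and np.any(centred.std(axis=0) > 0):
        n_comp = min(2, centred.shape[0] - 1, centred.shape[1])
        scores = PCA(n_components=n_comp,
                     svd_solver="full").fit_transform(centred)
        sd = scores.std(axis=0, ddof=1)
        outlier = np.zeros(len(keep), dtype=bool)
        for c in range(scores.shape[1]):
            if sd[c] > 0:
                outlier |= np.abs(scores[:, c] - scores[:, c].mean()) \
                    > pca_sd_k * sd[c]
        for sid in data.columns[outlier]:
            if report is not None:
                report.add("sample", sid, f"PCA outlier > {pca_sd_k} SD")
        data = data.loc[:, ~outlier]
    if data.shape[1] < 3:
        raise InsufficientDataError(
            f"only {data.shape[1]} samples survive filtering; downstream "
            "statistics are undefined")
    out = ExpressionMatrix(data, scale="log2",
                           pseudocount=expr.pseudocount).sorted()
    return out, meta.loc[out.sample_ids]


def filter_expression_stats(expr: ExpressionMatrix,
                            mean_min: float = 0.3, cv_min: float = 0.15,
                            trim_frac: float = 0.1,
                            report: FilterReport | None = None
                            ) -> ExpressionMatrix:
    """Keep genes with trimmed mean log2 > mean_min and CV > cv_min.

    Both statistics are computed on the log2 scale across all retained
    samples; ``trim_frac`` is the proportion cut from each tail.
    """
    if expr.scale != "log2":
        raise ConfigurationError("filter_expression_stats expects log2 values")
    if not 0 <= trim_frac < 0.5:
        raise ConfigurationError("trim_frac must be in [0, 0.5)")
    values = expr.data.to_numpy()
    tmean = trim_mean(values, trim_frac, axis=1)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean), np.inf)
    cv = np.where(sd == 0, 0.0, cv)       # constant gene: no variation
    keep = (tmean > mean_min) & (cv > cv_min)
    if report is not None:
        for gid, km, kc in zip(expr.gene_ids, tmean > mean_min, cv > cv_min):
            if not km:
                report.add("gene", gid, f"trimmed mean <= {mean_min}")
            elif not kc:
                report.add("gene", gid, f"CV <= {cv_min}")
    return ExpressionMatrix(expr.data.loc[keep], scale="log2",
                            pseudocount=expr.pseudocount).sorted()


def preprocess(raw: ExpressionMatrix, annotation: pd.DataFrame,
               meta: pd.DataFrame, min_reads: int = 2_000_000,
               pca_sd_k: float = 4.0, mean_min: float = 0.3,
               cv_min: float = 0.15, trim_frac: float = 0.1
               ) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Run all three filters in order; returns (matrix, meta, report)."""
    report = FilterReport()
    log2 = filter_genes(raw, annotation, report=report)
    log2, meta = filter_samples(log2, meta, min_reads=min_reads,
                                pca_sd_k=pca_sd_k, report=report)
    out = filter_expression_stats(log2, mean_min=mean_min, cv_min=cv_min,
                                  trim_frac=trim_frac, report=report)
    logger.info("preprocessing kept %d genes x %d samples", *out.shape)
    return out, meta, report.to_frame()
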