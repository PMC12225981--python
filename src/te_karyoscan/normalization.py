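"""Gene-anchored median-of-ratios normalization and display-level batch removal.

Size factors are estimated from gene counts only (the classical
median-of-ratios construction over genes positive in every sample) and then
applied to genes and TE subfamilies alike, so that a genuine genome-wide
shift in TE expression is not normalised away by the TE rows themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations_io import AnnotationError, CountMatrix, SampleSheet

__all__ = ["SizeFactors", "size_factors_from_genes", "normalize_joint", "remove_batch_effect"]


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample positive multipliers removing sequencing-depth differences."""

    factors: pd.Series  # indexed by sample_id

    def __post_init__(self) -> None:
        if (self.factors <= 0).any() or not np.isfinite(self.factors).all():
            raise AnnotationError("size factors must be positive and finite")

    def __getitem__(self, sample_id: str) -> float:
        return float(self.factors[sample_id])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.factors.index)

    def to_tsv(self, path) -> None:
        self.factors.rename("size_factor").to_csv(path, sep="\t", index_label="sample_id")


def size_factors_from_genes(gene_counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors from gene counts.

    For every gene with positive counts in all samples, each sample's count
    is divided by the gene's geometric mean across samples; the sample's
    factor is the median of those ratios. Computed in log space for
    numerical stability. Genes with any zero are excluded from the
    reference, matching the standard construction.
    """
    if gene_counts.feature_kind != "gene":
        raise AnnotationError(f"expected gene matrix, got {gene_counts.feature_kind}")
    counts = gene_counts.data.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise AnnotationError(
            "no gene has positive counts in every sample; cannot build the "
            "median-of-ratios reference (pseudo-reference fallback is disabled)"
        )
    kept = counts[all_positive]
    log_geomean = np.log(kept).mean(axis=1, keepdims=True)
    ratios = kept / np.exp(log_geomean)
    # median over genes on the ratio scale; even counts use the midpoint
    factors = np.median(ratios, axis=0)
    return SizeFactors(pd.Series(factors, index=gene_counts.data.columns))


def normalize_joint(
    gene_counts: CountMatrix, te_counts: CountMatrix, factors: SizeFactors
) -> CountMatrix:
    """Divide genes and TE subfamilies by gene-derived size factors.

    Returns a stacked ``mixed`` matrix (gene rows first) with per-row kind
    labels so downstream statistics can separate the two feature sets.
    """
    if list(gene_counts.sample_ids) != list(te_counts.sample_ids):
        raise AnnotationError("gene and TE matrices must share the same samples")
    if set(factors.sample_ids) != set(gene_counts.sample_ids):
        raise AnnotationError("size factors do not cover the sample set")
    overlap = set(gene_counts.feature_ids) & set(te_counts.feature_ids)
    if overlap:
        raise AnnotationError(f"feature ids shared between genes and TEs: {sorted(overlap)[:5]}")
    stacked = pd.concat([gene_counts.data, te_counts.data])
    fvec = factors.factors.reindex(stacked.columns)
    normalized = stacked / fvec
    kinds = pd.Series(
        ["gene"] * len(gene_counts.data) + [te_counts.feature_kind] * len(te_counts.data),
        index=stacked.index,
    )
    return CountMatrix(normalized, feature_kind="mixed", normalized=True, row_kinds=kinds)


def remove_batch_effect(
    normalized: CountMatrix,
    sheet: SampleSheet,
    batch_col: str = "batch",
    group_col: str = "karyotype",
) -> CountMatrix:
    """Subtract additive batch offsets on the log2 scale, for display only.

    Per feature, a least-squares fit of ``log2(count + 0.5)`` on biological
    group (treatment coding) plus batch (sum-to-zero coding) is performed
    jointly for all features; the batch component is subtracted and the
    values back-transformed. The biological group is retained as covariate
    so unbalanced batches do not soak up real group differences. Inferential
    models should instead include batch as a covariate — this adjustment is
    only for descriptive statistics and plots.
    """
    if not normalized.normalized:
        raise AnnotationError("remove_batch_effect expects a normalized matrix")
    samples = normalized.sample_ids
    batch = sheet.column(batch_col).reindex(samples)
    if batch.isna().any():
        raise AnnotationError("sample sheet missing batch for some samples")
    levels = sorted(batch.unique())
    if len(levels) < 2:
        return normalized  # single batch: nothing to remove
    group = sheet.column(group_col).reindex(samples)
    # 1:1 confounding check: each batch level maps to exactly one group and
    # vice versa -> the batch offset is unidentifiable.
    cross = pd.crosstab(batch, group)
    if ((cross > 0).sum(axis=1) == 1).all() and ((cross > 0).sum(axis=0) == 1).all():
        raise AnnotationError(
            f"batch ({batch_col}) is perfectly confounded with {group_col}"
        )

    # design: intercept + group dummies (treatment) + batch (sum-to-zero)
    g_dummies = pd.get_dummies(group, drop_first=True, dtype=float)
    b_codes = pd.Categorical(batch, categories=levels).codes
    n_b = len(levels)
    contr_sum = np.vstack([np.eye(n_b - 1), -np.ones((1, n_b - 1))])
    b_design = contr_sum[b_codes]  # samples × (n_b - 1)
    X = np.column_stack(
        [np.ones(len(samples)), g_dummies.to_numpy(), b_design]
    )
    n_batch_cols = n_b - 1
    logy = np.log2(normalized.data.to_numpy(dtype=float) + 0.5)
    beta, *_ = np.linalg.lstsq(X, logy.T, rcond=None)
    batch_part = b_design @ beta[-n_batch_cols:, :]  # samples × features
    adjusted = np.power(2.0, logy - batch_part.T) - 0.5
    adjusted = np.maximum(adjusted, 0.0)
    out = pd.DataFrame(adjusted, index=normalized.data.index, columns=normalized.data.columns)
    return normalized.replace_data(out)
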