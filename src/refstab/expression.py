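"""Relative quantification of qPCR data and normalization factors.

ct values are converted to linear-scale relative quantities with the standard
2^-dct transform: for gene *i* and sample *j*,

    q_ij = E ** (ct_min,i - ct_ij),    E = 2 (100% amplification efficiency),

with the per-gene calibrator ct_min,i the minimum ct over samples, so the most
expressed sample of each gene has q = 1 and q in (0, 1] everywhere. All
downstream stability metrics and fold changes are invariant to the calibrator
choice (it multiplies each gene's q by a constant).

A normalization factor (NF) is the per-sample geometric mean of the relative
quantities of a set of validated reference genes; dividing a target gene's q by
the NF removes shared sample-loading variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CtTable, DataValidationError, GroupDesign


@dataclass
class ExpressionTable:
    """Samples x genes matrix of linear-scale relative quantities (q > 0)."""

    q: pd.DataFrame
    design: GroupDesign

    def __post_init__(self):
        if (self.q.to_numpy() <= 0).any():
            raise DataValidationError("relative quantities must be > 0")

    @property
    def genes(self) -> list[str]:
        return list(self.q.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.q.index)

    def select_genes(self, genes: list[str]) -> "ExpressionTable":
        unknown = [g for g in genes if g not in set(self.genes)]
        if unknown:
            raise DataValidationError(f"unknown gene(s): {unknown}")
        return ExpressionTable(self.q[genes], self.design)


@dataclass(frozen=True)
class NFVector:
    """Per-sample normalization factor: geometric mean of a reference-gene set."""

    gene_set: tuple[str, ...]
    nf: pd.Series

    def __post_init__(self):
        if len(self.gene_set) < 1:
            raise DataValidationError("NF gene set must be non-empty")
        if (self.nf.to_numpy() <= 0).any():
            raise DataValidationError("NF values must be > 0")


@dataclass
class FoldChangeTable:
    """Per-group relative expression of one target, scaled to a baseline group.

    ``normalized`` holds per-sample values rescaled so the baseline-group mean
    is 1; ``group_means`` the per-group arithmetic means of those values;
    ``fold_change`` the group mean over the baseline mean (baseline = 1).
    """

    target: str
    baseline_group: str
    normalized: pd.Series
    group_means: pd.Series
    fold_change: pd.Series


def relative_quantities(ct: CtTable, efficiency: float = 2.0) -> ExpressionTable:
    """Convert ct values to relative quantities q = E**(ct_min - ct) per gene.

    ``efficiency`` is the amplification factor per PCR cycle; the default 2
    corresponds to 100% efficiency (the 2^-dct convention).
    """
    if efficiency <= 1:
        raise DataValidationError("amplification efficiency must exceed 1")
    ct_min = ct.ct.min(axis=0)
    q = np.power(efficiency, ct_min - ct.ct)
    return ExpressionTable(q, ct.design)


def normalization_factor(expr: ExpressionTable, gene_set: list[str]) -> NFVector:
    """Geometric mean of the relative quantities of ``gene_set``, per sample."""
    if len(gene_set) == 0:
        raise DataValidationError("NF gene set must be non-empty")
    unknown = [g for g in gene_set if g not in set(expr.genes)]
    if unknown:
        raise DataValidationError(f"unknown gene(s) in NF set: {unknown}")
    logq = np.log(expr.q[list(gene_set)])
    nf = np.exp(logq.mean(axis=1))
    return NFVector(tuple(gene_set), nf)


def normalize_and_compare(
    expr: ExpressionTable,
    target: str,
    normalizer: NFVector | None,
    baseline_group: str,
) -> FoldChangeTable:
    """Normalize a target gene (optionally by an NF) and compare groups.

    Each sample's value is q_target / NF (or q_target alone when ``normalizer``
    is None, the non-normalized display), then all values are rescaled so the
    mean of the baseline group equals 1. Fold change per group is the group
    mean of the rescaled values.
    """
    if target not in set(expr.genes):
        raise DataValidationError(f"unknown target gene: {target!r}")
    if baseline_group not in set(expr.design.groups):
        raise DataValidationError(f"unknown baseline group: {baseline_group!r}")
    values = expr.q[target].copy()
    if normalizer is not None:
        if set(normalizer.nf.index) != set(values.index):
            raise DataValidationError("normalizer sample set differs from expression table")
        values = values / normalizer.nf.loc[values.index]
    groups = expr.design.groups.loc[values.index]
    baseline_mean = values[groups == baseline_group].mean()
    normalized = values / baseline_mean
    group_means = normalized.groupby(groups).mean()
    group_means = group_means.loc[[g for g in expr.design.group_names if g in group_means.index]]
    fold_change = group_means / group_means[baseline_group]
    return FoldChangeTable(target, baseline_group, normalized, group_means, fold_change)
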