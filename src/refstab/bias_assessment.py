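"""Intergroup bias detection for candidate reference genes, plus the cohort
comparison statistics (chi-square, Welch t).

A reference gene whose expression differs systematically between experimental
groups distorts every fold change computed against it ("systematic bias"); a
higher reference expression in one group underestimates normalized target
expression there. Bias is flagged per gene (or per normalization factor) with
a one-way fixed-effects ANOVA across groups, run on the log2 expression scale
(equivalently on -dct), where the additive Gaussian error model of qPCR holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ContingencyTable, DataValidationError, GroupDesign
from .expression import ExpressionTable, FoldChangeTable, NFVector, normalize_and_compare

DEFAULT_ALPHA = 0.05


@dataclass
class BiasFlag:
    """Verdict for one gene or NF: per-group fold change, intergroup p, flag."""

    label: str
    fold_change: pd.Series
    p_value: float
    flag: str  # "stable" | "biased"


def intergroup_test(values: pd.Series, design: GroupDesign) -> float:
    """One-way fixed-effects ANOVA omnibus p-value across groups.

    ``values`` is a per-sample series (indexed by sample id) of the quantity
    being tested. Degenerate inputs resolve by convention: zero between-group
    variation gives p = 1; zero within-group variation with any between-group
    difference gives p = 0.
    """
    groups = design.groups.loc[values.index]
    levels = [g for g in design.group_names if g in set(groups)]
    if len(levels) < 2:
        raise DataValidationError("intergroup test requires >=2 groups")
    arrays = [values[groups == g].to_numpy(dtype=float) for g in levels]
    for g, a in zip(levels, arrays):
        if len(a) < 2:
            raise DataValidationError(f"group {g!r} has fewer than 2 samples")

    n = np.array([len(a) for a in arrays], dtype=float)
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ssb = float((n * (means - grand) ** 2).sum())
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    scale = max(float(np.concatenate(arrays).var()), 1.0) * n.sum()
    tiny = 1e-12 * max(scale, 1.0)
    if ssb <= tiny:
        return 1.0
    if ssw <= tiny:
        return 0.0
    df_b = len(levels) - 1
    df_w = int(n.sum()) - len(levels)
    f = (ssb / df_b) / (ssw / df_w)
    return float(stats.f.sf(f, df_b, df_w))


def chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    All-zero categories (columns) are dropped before testing; degrees of
    freedom are (r-1)(c-1) on the reduced table.
    """
    reduced = table.drop_empty_categories().counts
    if reduced.shape[1] < 2:
        raise DataValidationError("need >=2 non-empty categories")
    if reduced.shape[0] < 2:
        raise DataValidationError("need >=2 groups")
    stat, p, dof, _ = stats.chi2_contingency(reduced.to_numpy(), correction=False)
    return float(stat), int(dof), float(p)


def welch_t_test(x, y) -> float:
    """Two-tailed Welch t-test p-value for two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DataValidationError("each sample needs >=2 observations")
    res = stats.ttest_ind(x, y, equal_var=False)
    p = float(res.pvalue)
    if np.isnan(p):  # both samples constant and equal
        return 1.0 if x.mean() == y.mean() else 0.0
    return p


def bias_flag(
    expr: ExpressionTable,
    target: str,
    baseline_group: str,
    normalizer: NFVector | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> BiasFlag:
    """Flag one gene (or its NF-normalized version) as stable or biased.

    Fold changes are reported on the linear scale (group mean / baseline
    mean); the ANOVA runs on log2 of the same per-sample values.
    """
    fc: FoldChangeTable = normalize_and_compare(expr, target, normalizer, baseline_group)
    p = intergroup_test(np.log2(fc.normalized), expr.design)
    flag = "stable" if p >= alpha else "biased"
    return BiasFlag(target, fc.fold_change, p, flag)


def bias_table(
    expr: ExpressionTable,
    baseline_group: str,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-gene bias assessment of non-normalized relative expression.

    Returns a frame indexed by gene with one fold-change column per group
    (``fc_<group>``), the intergroup p-value and the stable/biased flag.
    """
    rows = {}
    for gene in expr.genes:
        bf = bias_flag(expr, gene, baseline_group, None, alpha)
        row = {f"fc_{g}": v for g, v in bf.fold_change.items()}
        row["p_value"] = bf.p_value
        row["flag"] = bf.flag
        rows[gene] = row
    return pd.DataFrame.from_dict(rows, orient="index")
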