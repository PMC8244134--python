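"""Systematic screening of RNA-seq count matrices for reference-gene candidates.

Counts are upper-quartile (UQ) normalized: each sample is scaled by the 75th
percentile of its nonzero counts, referenced to the geometric mean of those
percentiles so the output stays on the count scale. Candidates must then clear
three filters on x = log2(UQ + pseudocount):

    (i)   mean_samples(x) > 5           (expressed well above noise)
    (ii)  SD_samples(x)   < 1           (low overall variability)
    (iii) max_samples |x - mean(x)| < 2 (no outlying sample; a deviation of
                                         exactly 2 fails)

Passing genes are ranked by ascending coefficient of variation CV = SD/mean of
the same log2 values. Two datasets can be screened independently and their
intersection re-screened on the combined (column-concatenated) matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CountMatrix, DataValidationError, GroupDesign

MEAN_LOG_MIN = 5.0
SD_LOG_MAX = 1.0
MAX_DEV_MAX = 2.0
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class ScreenThresholds:
    mean_log_min: float = MEAN_LOG_MIN
    sd_log_max: float = SD_LOG_MAX
    max_dev_max: float = MAX_DEV_MAX


@dataclass
class ScreenResult:
    """Per-gene filter statistics and CV ranking.

    ``table`` columns: ``mean_log``, ``sd_log``, ``max_dev`` (all log2 counts),
    ``cv`` (dimensionless, SD/mean of log2 values; NaN when mean_log <= 0),
    ``pass`` (bool) and ``rank`` (1..n_pass by ascending cv among passing
    genes; NaN otherwise).
    """

    table: pd.DataFrame
    thresholds: ScreenThresholds
    pseudocount: float

    @property
    def n_pass(self) -> int:
        return int(self.table["pass"].sum())

    @property
    def passing_genes(self) -> list[str]:
        passing = self.table[self.table["pass"]]
        return list(passing.sort_values("rank").index)


def uq_normalize(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Upper-quartile normalization of a genes x samples count matrix.

    Per sample, the scale factor is its 75th percentile of nonzero counts
    divided by the geometric mean of all samples' 75th percentiles; the
    normalized value is count / scale. Linear-interpolation percentiles.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    mat = mat.astype(float)
    uq = {}
    for s in mat.columns:
        col = mat[s].to_numpy()
        nonzero = col[col > 0]
        if len(nonzero) == 0:
            raise DataValidationError(f"sample {s!r} has no nonzero counts")
        uq[s] = float(np.percentile(nonzero, 75))
    uq_series = pd.Series(uq)
    ref = float(np.exp(np.log(uq_series).mean()))
    scale = uq_series / ref
    return mat.div(scale, axis=1)


def screen_candidates(
    uq: pd.DataFrame,
    thresholds: ScreenThresholds | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    linear_cv: bool = False,
) -> ScreenResult:
    """Apply the three reference-gene filters and rank passing genes by CV.

    ``uq`` is a genes x samples matrix of UQ-normalized values. ``linear_cv``
    switches the ranking statistic to SD/mean of the linear UQ values.
    """
    if thresholds is None:
        thresholds = ScreenThresholds()
    if (uq.to_numpy() < 0).any():
        raise DataValidationError("UQ values must be >= 0")
    x = np.log2(uq + pseudocount)
    mean_log = x.mean(axis=1)
    sd_log = x.std(axis=1, ddof=1)
    max_dev = x.sub(mean_log, axis=0).abs().max(axis=1)
    passing = (
        (mean_log > thresholds.mean_log_min)
        & (sd_log < thresholds.sd_log_max)
        & (max_dev < thresholds.max_dev_max)
    )
    if linear_cv:
        cv = uq.std(axis=1, ddof=1) / uq.mean(axis=1)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = sd_log / mean_log
        cv[mean_log <= 0] = np.nan

    table = pd.DataFrame(
        {"mean_log": mean_log, "sd_log": sd_log, "max_dev": max_dev, "cv": cv, "pass": passing}
    )
    ranked = table[passing].sort_values("cv", kind="mergesort")
    table["rank"] = pd.Series(
        np.arange(1, len(ranked) + 1, dtype=float), index=ranked.index
    ).reindex(table.index)
    return ScreenResult(table, thresholds, pseudocount)


def combine_counts(a: CountMatrix, b: CountMatrix) -> CountMatrix:
    """Column-concatenate two count matrices on their shared gene set."""
    shared = [g for g in a.genes if g in set(b.genes)]
    if not shared:
        raise DataValidationError("count matrices share no genes")
    counts = pd.concat([a.counts.loc[shared], b.counts.loc[shared]], axis=1)
    groups = pd.concat([a.design.groups, b.design.groups])
    return CountMatrix(counts, GroupDesign(groups))


def intersect_screens(
    result_a: ScreenResult,
    result_b: ScreenResult,
    combined: CountMatrix,
) -> ScreenResult:
    """Re-screen the genes passing in both datasets on the combined matrix.

    The combined matrix is UQ-normalized afresh; only genes in the A-and-B
    passing intersection are retained (with pass/CV re-evaluated on the
    combined data). An empty intersection yields a valid empty result with a
    warning.
    """
    inter = [g for g in result_a.passing_genes if g in set(result_b.passing_genes)]
    inter = [g for g in inter if g in set(combined.genes)]
    if not inter:
        warnings.warn("empty intersection of passing genes", stacklevel=2)
        empty = pd.DataFrame(
            columns=["mean_log", "sd_log", "max_dev", "cv", "pass", "rank"]
        ).astype({"pass": bool})
        return ScreenResult(empty, result_a.thresholds, result_a.pseudocount)
    uq = uq_normalize(combined)
    full = screen_candidates(uq, result_a.thresholds, result_a.pseudocount)
    sub = full.table.loc[inter].copy()
    ranked = sub[sub["pass"]].sort_values("cv", kind="mergesort")
    sub["rank"] = pd.Series(
        np.arange(1, len(ranked) + 1, dtype=float), index=ranked.index
    ).reindex(sub.index)
    return ScreenResult(sub, full.thresholds, full.pseudocount)
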