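"""BestKeeper-style descriptive stability analysis of ct values.

BestKeeper judges candidate reference genes by (a) the raw dispersion of their
ct values — the standard deviation (SD, in cycles) — and (b) how tightly each
gene tracks the BestKeeper index, the per-sample geometric mean of all
candidate genes' ct values, measured by the Pearson correlation r and the
coefficient of determination r^2.

A gene whose ct SD exceeds 1 cycle varies more than two-fold in starting
template and is demoted below every gene with SD <= 1 regardless of its
correlation; within each tier, genes are ordered by descending r^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CtTable, DataValidationError

SD_DEMOTION_CYCLES = 1.0  # SD > 1 cycle ~ >2-fold template variation


@dataclass
class BestKeeperResult:
    """Per-gene dispersion and index-correlation statistics with ranks.

    ``table`` columns: ``sd_ct`` (cycles), ``cv_ct`` (%), ``r``, ``r2``,
    ``rank`` (1 = most stable). ``index`` is the per-sample BestKeeper index
    (geometric mean of candidate ct values, in cycles).
    """

    table: pd.DataFrame
    index: pd.Series

    @property
    def ranking(self) -> pd.Series:
        return self.table["rank"]


def bestkeeper_rank(ct: CtTable, genes: list[str] | None = None) -> BestKeeperResult:
    """Rank candidate reference genes by SD and correlation with the index.

    The index is computed over the same candidate set being ranked. Genes with
    ct SD strictly greater than 1 cycle are ranked below all others; each tier
    is ordered by descending r^2, ties broken by ascending SD then gene label.
    A gene with zero ct variance has an undefined correlation and is rejected.
    """
    sub = ct if genes is None else ct.select_genes(list(genes))
    mat = sub.ct
    if mat.shape[0] < 2:
        raise DataValidationError("BestKeeper needs >=2 samples")
    if mat.shape[1] < 2:
        raise DataValidationError("BestKeeper needs >=2 genes")

    sd = mat.std(axis=0, ddof=1)
    constant = sd[sd == 0]
    if len(constant) > 0:
        raise DataValidationError(
            f"undefined correlation: gene {constant.index[0]!r} has constant ct"
        )

    index = np.exp(np.log(mat).mean(axis=1))
    r = mat.apply(lambda col: np.corrcoef(col.to_numpy(), index.to_numpy())[0, 1])
    table = pd.DataFrame(
        {
            "sd_ct": sd,
            "cv_ct": 100.0 * sd / mat.mean(axis=0),
            "r": r,
            "r2": r**2,
        }
    )

    demoted = table["sd_ct"] > SD_DEMOTION_CYCLES
    # label order as final tie-break: pre-sort by label, then stable-sort the keys
    order = (
        table.sort_index()
        .assign(_demoted=demoted.sort_index())
        .sort_values(
            by=["_demoted", "r2", "sd_ct"], ascending=[True, False, True], kind="mergesort"
        )
    )
    table["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    return BestKeeperResult(table, index.rename("bestkeeper_index"))
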