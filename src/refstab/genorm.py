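"""GeNorm-style stability: pairwise log-ratio variation and V analysis.

GeNorm scores a candidate gene j by its average pairwise variation with every
other candidate: for each pair (j, k) the per-sample log2 expression ratio
A_jk = log2(q_j / q_k) is formed and its standard deviation across samples
taken; the gene-stability measure is

    M_j = mean_{k != j} SD_samples(log2(q_j / q_k)).

Genes whose expression tracks the others (co-regulated up to sample loading)
have low M. The least stable gene (highest M) is eliminated and M recomputed
on the reduced set, iterating down to the final, most stable pair — which is
not resolvable further (their mutual ratio defines both M values) and shares
rank 1.

The pairwise-variation (V) analysis asks how many genes a normalization factor
needs: with NF_n the per-sample geometric mean of the n most stable genes,
V_{n,n+1} = SD_samples(log2(NF_n / NF_{n+1})). A small V means the (n+1)-th
gene does not change the factor; conventionally V < 0.15 is taken to indicate
that n genes suffice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DataValidationError
from .expression import ExpressionTable

DEFAULT_V_THRESHOLD = 0.15


@dataclass
class GeNormResult:
    """M values at elimination, elimination order, ranks, and the V series.

    ``m`` is each gene's M at the step it was eliminated (for the final pair,
    at the two-gene stage). ``rank`` uses competition ranking: the final two
    genes share rank 1, the next gene has rank 3. ``v_series`` is indexed by n
    and holds V_{n,n+1}; ``recommended_n`` is the smallest n with V below
    ``threshold``, or None when no V clears it.
    """

    m: pd.Series
    elimination_order: list[str]
    rank: pd.Series
    stable_order: list[str]
    v_series: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    recommended_n: int | None = None
    threshold: float = DEFAULT_V_THRESHOLD

    @property
    def ranking(self) -> pd.Series:
        return self.rank

    @property
    def top_pair(self) -> tuple[str, str]:
        return tuple(self.stable_order[:2])  # type: ignore[return-value]


def m_values(q: pd.DataFrame) -> pd.Series:
    """Gene-stability measure M for every gene of a samples x genes q matrix."""
    if (q.to_numpy() <= 0).any():
        raise DataValidationError("relative quantities must be > 0")
    logq = np.log2(q)
    genes = list(q.columns)
    out = {}
    for j in genes:
        sds = [
            (logq[j] - logq[k]).std(ddof=1)
            for k in genes
            if k != j
        ]
        out[j] = float(np.mean(sds))
    return pd.Series(out, name="M")


def genorm_rank(expr: ExpressionTable, genes: list[str] | None = None) -> GeNormResult:
    """Iterative-elimination GeNorm ranking of candidate reference genes."""
    q = expr.q if genes is None else expr.select_genes(list(genes)).q
    if q.shape[1] < 3:
        raise DataValidationError("ranking undefined: GeNorm needs >=3 genes")
    if q.shape[0] < 2:
        raise DataValidationError("GeNorm needs >=2 samples")

    input_order = list(q.columns)
    remaining = list(input_order)
    eliminated: list[str] = []
    m_at_removal: dict[str, float] = {}
    while len(remaining) > 2:
        m = m_values(q[remaining])
        worst_val = m.max()
        # tie on max M -> remove the later gene in input order
        worst = [g for g in remaining if m[g] == worst_val][-1]
        m_at_removal[worst] = float(m[worst])
        eliminated.append(worst)
        remaining.remove(worst)
    m_final = m_values(q[remaining])
    for g in remaining:
        m_at_removal[g] = float(m_final[g])

    stable_order = list(remaining) + list(reversed(eliminated))
    rank_map = {stable_order[0]: 1, stable_order[1]: 1}
    for pos, g in enumerate(stable_order[2:], start=3):
        rank_map[g] = pos
    m_series = pd.Series({g: m_at_removal[g] for g in input_order}, name="M")
    rank = pd.Series({g: rank_map[g] for g in input_order}, name="rank")
    return GeNormResult(m_series, eliminated, rank, stable_order)


def genorm_v(
    expr: ExpressionTable,
    ranking: GeNormResult,
    threshold: float = DEFAULT_V_THRESHOLD,
) -> GeNormResult:
    """Pairwise-variation analysis; fills ``v_series`` and ``recommended_n``.

    V_{n,n+1} compares the geometric-mean normalization factors over the n and
    n+1 most stable genes for n = 2 .. n_genes - 1.
    """
    order = ranking.stable_order
    if len(order) < 3:
        raise DataValidationError("V analysis needs >=3 genes")
    logq = np.log2(expr.q[order])
    v = {}
    for n in range(2, len(order)):
        nf_n = logq.iloc[:, :n].mean(axis=1)
        nf_n1 = logq.iloc[:, : n + 1].mean(axis=1)
        v[n] = float((nf_n - nf_n1).std(ddof=1))
    v_series = pd.Series(v, name="V").sort_index()
    below = v_series[v_series < threshold]
    recommended_n = int(below.index[0]) if len(below) else None
    return GeNormResult(
        ranking.m,
        ranking.elimination_order,
        ranking.rank,
        order,
        v_series,
        recommended_n,
        threshold,
    )
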