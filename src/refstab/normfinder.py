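"""NormFinder-style model-based stability: variance decomposition on ct values.

NormFinder treats each candidate gene's log-scale expression as the sum of a
gene baseline, a shared per-sample effect, a gene-by-group interaction (the
intergroup bias d_ig) and within-group noise (variance gamma2_ig). Because ct
is proportional to -log2 expression and every statistic used here is symmetric
in sign, the decomposition is run directly on ct.

For gene i, group g, sample j (y = ct):

1. per-sample centering        z_igj = y_igj - mean_i' y_i'gj
2. intergroup deviation        d_ig  = mean_j z_igj - mean_g' mean_j z_ig'j
3. intragroup variance         gamma2_ig = Var_j z_igj            (ddof=1)
4. shrinkage toward zero       d~_ig = d_ig * max(0, 1 - (gamma2_ig/n_g) /
                                                  (sum_g d_ig^2 / (G-1)))
5. stability value             rho_i = (1/G) sum_g (|d~_ig| + sqrt(gamma2_ig/n_g))

Lower rho = more stable. With a single group, rho_i = sqrt(gamma2_i) (pure
intragroup noise). The shrinkage damps intergroup estimates that are small
relative to their own sampling noise, so a gene is not penalized for apparent
bias it cannot statistically support.

A normalization factor is assembled greedily: starting from the lowest-rho
gene, genes are added while the stability of the averaged set

    rho_S = (1/G) sum_g (|mean_{i in S} d~_ig| + sqrt(sum_{i in S} gamma2_ig
                                                      / (|S|^2 n_g)))

keeps decreasing. Opposite-sign intergroup biases cancel in the mean — the
mechanism by which a pair can beat its best member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CtTable, DataValidationError


@dataclass
class NormFinderDecomposition:
    """Per-gene, per-group variance decomposition (genes x groups frames)."""

    d: pd.DataFrame
    d_shrunk: pd.DataFrame
    gamma2: pd.DataFrame
    n_g: pd.Series

    @property
    def groups(self) -> list[str]:
        return list(self.d.columns)


@dataclass
class NormFinderResult:
    """Stability values, ranks, and (after NF selection) the chosen gene set."""

    rho: pd.Series
    rank: pd.Series
    nf_genes: tuple[str, ...] | None = None
    nf_rho: float | None = None


def _decompose(ct: CtTable) -> NormFinderDecomposition:
    y = ct.ct  # samples x genes
    groups = ct.design.groups.loc[y.index]
    group_names = [g for g in ct.design.group_names if g in set(groups)]
    for g in group_names:
        if (groups == g).sum() < 2:
            raise DataValidationError(f"group {g!r} has fewer than 2 samples")

    z = y.sub(y.mean(axis=1), axis=0)  # per-sample centering across genes
    cell_mean = z.groupby(groups, sort=False).mean().T  # genes x groups
    cell_mean = cell_mean[group_names]
    d = cell_mean.sub(cell_mean.mean(axis=1), axis=0)
    gamma2 = z.groupby(groups, sort=False).var(ddof=1).T[group_names]
    n_g = groups.value_counts()[group_names].astype(float)

    G = len(group_names)
    if G >= 2:
        denom = (d**2).sum(axis=1) / (G - 1)  # per-gene spread of d_ig
        with np.errstate(divide="ignore", invalid="ignore"):
            c = 1.0 - gamma2.div(n_g, axis=1).div(denom, axis=0)
        c = c.clip(lower=0.0)
        c[denom == 0] = 0.0
        d_shrunk = d * c
    else:
        d_shrunk = d * 0.0
    return NormFinderDecomposition(d, d_shrunk, gamma2, n_g)


def normfinder_stability(ct: CtTable) -> tuple[NormFinderDecomposition, NormFinderResult]:
    """Compute per-gene stability values rho and ranks (1 = most stable)."""
    if ct.ct.shape[1] < 2:
        raise DataValidationError("NormFinder needs >=2 genes")
    decomp = _decompose(ct)
    G = len(decomp.groups)
    if G == 1:
        rho = np.sqrt(decomp.gamma2.iloc[:, 0])
    else:
        se = np.sqrt(decomp.gamma2.div(decomp.n_g, axis=1))
        rho = (decomp.d_shrunk.abs() + se).mean(axis=1)
    rho = rho.rename("rho")
    order = rho.to_frame().assign(_label=rho.index).sort_values(["rho", "_label"])
    rank = pd.Series(np.arange(1, len(order) + 1), index=order.index, name="rank")
    return decomp, NormFinderResult(rho, rank.loc[rho.index])


def nf_set_stability(decomp: NormFinderDecomposition, gene_set: list[str]) -> float:
    """Stability rho_S of the normalization factor built from ``gene_set``."""
    S = list(gene_set)
    if not S:
        raise DataValidationError("gene set must be non-empty")
    G = len(decomp.groups)
    k = len(S)
    bias = decomp.d_shrunk.loc[S].mean(axis=0).abs()
    noise = np.sqrt(decomp.gamma2.loc[S].sum(axis=0) / (k**2 * decomp.n_g))
    return float((bias + noise).sum() / G)


def normfinder_select_nf(
    decomp: NormFinderDecomposition,
    result: NormFinderResult | None = None,
    max_genes: int | None = None,
) -> NormFinderResult:
    """Greedy NF gene-set selection; stops when adding a gene no longer helps.

    Requires >=2 groups (the selection trades intergroup biases off against
    each other). Returns a result carrying ``nf_genes`` and ``nf_rho``.
    """
    if len(decomp.groups) < 2:
        raise DataValidationError("NF selection requires >=2 groups")
    if result is None:
        G = len(decomp.groups)
        se = np.sqrt(decomp.gamma2.div(decomp.n_g, axis=1))
        rho = (decomp.d_shrunk.abs() + se).mean(axis=1).rename("rho")
        order = rho.to_frame().assign(_label=rho.index).sort_values(["rho", "_label"])
        rank = pd.Series(np.arange(1, len(order) + 1), index=order.index, name="rank").loc[
            rho.index
        ]
        result = NormFinderResult(rho, rank)

    genes = list(result.rho.index)
    current = [result.rank.idxmin()]
    current_rho = nf_set_stability(decomp, current)
    while True:
        if max_genes is not None and len(current) >= max_genes:
            break
        remaining = [g for g in genes if g not in current]
        if not remaining:
            break
        trials = [(nf_set_stability(decomp, current + [g]), g) for g in remaining]
        best_rho, best_gene = min(trials, key=lambda t: (t[0], t[1]))
        if best_rho < current_rho:
            current.append(best_gene)
            current_rho = best_rho
        else:
            break
    return NormFinderResult(result.rho, result.rank, tuple(current), current_rho)
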