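"""End-to-end reference-gene validation: three algorithms, mean-rank consensus,
normalization-factor vetting, the co-regulation guard, and bias flags.

The workflow runs BestKeeper (on ct), NormFinder (on ct) and GeNorm (on
relative quantities) over configurable group subsets ("steps", e.g. the two
neonatal groups first, then neonates plus adults), aggregates the three
per-gene ranks by their arithmetic mean, and vets the NormFinder-proposed
normalization factor: a multi-gene NF is accepted only when its stability
value is strictly lower (better) than that of the best single gene.

GeNorm cannot separate co-regulated genes — two members of one gene family
track each other and share artificially low M values. The family guard checks
GeNorm's top pair against a gene-family map; if both members share a family,
the one with the worse consensus rank is excluded and GeNorm re-run on the
reduced set (the procedure used to displace a second ribosomal gene from the
top pair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bestkeeper import BestKeeperResult, bestkeeper_rank
from .bias_assessment import DEFAULT_ALPHA, bias_table
from .data_model import CtTable, DataValidationError
from .expression import relative_quantities
from .genorm import DEFAULT_V_THRESHOLD, GeNormResult, genorm_rank, genorm_v
from .normfinder import (
    NormFinderDecomposition,
    NormFinderResult,
    nf_set_stability,
    normfinder_select_nf,
    normfinder_stability,
)

GeneFamilyMap = Mapping[str, str]


@dataclass
class NFDecision:
    """Verdict on a candidate multi-gene normalization factor."""

    genes: tuple[str, ...]
    stability: float
    best_single_gene: str
    best_single_stability: float
    verdict: str  # "accept" | "reject"


@dataclass
class ValidationReport:
    """One validation step: per-algorithm results, consensus, NF verdict, flags."""

    step_label: str
    groups: tuple[str, ...]
    bestkeeper: BestKeeperResult
    normfinder: NormFinderResult
    normfinder_decomposition: NormFinderDecomposition
    genorm: GeNormResult
    genorm_final: GeNormResult
    consensus: pd.DataFrame
    nf_decision: NFDecision | None
    v_series: pd.Series
    recommended_n: int | None
    bias_flags: pd.DataFrame
    excluded_genes: dict[str, str] = field(default_factory=dict)

    @property
    def consensus_order(self) -> list[str]:
        return list(self.consensus.index)


def mean_rank(
    rankings: Mapping[str, pd.Series],
    tiebreak: pd.Series | None = None,
) -> pd.DataFrame:
    """Aggregate per-algorithm gene ranks by their arithmetic mean.

    ``rankings`` maps algorithm name to a gene-indexed rank series; all series
    must cover the same genes. Ties on the mean rank are broken by the
    ``tiebreak`` series (lower wins; typically the NormFinder stability value),
    then by gene label. Returns a frame sorted by ascending mean rank with the
    input rank columns and ``mean_rank``.
    """
    if not rankings:
        raise DataValidationError("no rankings supplied")
    frames = {}
    gene_sets = [frozenset(r.index) for r in rankings.values()]
    if len(set(gene_sets)) != 1:
        raise DataValidationError("rankings cover different gene sets")
    for name, r in rankings.items():
        frames[name] = r.astype(float)
    df = pd.DataFrame(frames)
    df["mean_rank"] = df.mean(axis=1)
    if tiebreak is not None:
        df["_tb"] = tiebreak.reindex(df.index)
    else:
        df["_tb"] = 0.0
    df["_label"] = df.index
    df = df.sort_values(["mean_rank", "_tb", "_label"]).drop(columns=["_tb", "_label"])
    return df


def evaluate_nf_candidate(nf_stability: float, best_single_stability: float) -> str:
    """Accept a multi-gene NF only if strictly more stable than the best gene."""
    if nf_stability < 0 or best_single_stability < 0:
        raise DataValidationError("stability values must be >= 0")
    return "accept" if nf_stability < best_single_stability else "reject"


def _same_family(pair: tuple[str, str], family_map: GeneFamilyMap | None) -> bool:
    if not family_map:
        return False
    fa, fb = family_map.get(pair[0]), family_map.get(pair[1])
    return fa is not None and fa == fb


def validate_step(
    ct: CtTable,
    groups: list[str],
    step_label: str | None = None,
    family_map: GeneFamilyMap | None = None,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    max_nf_genes: int | None = None,
    baseline_group: str | None = None,
) -> ValidationReport:
    """Run the full three-algorithm validation on one group subset."""
    sub = ct.subset_groups(list(groups))
    label = step_label or "+".join(groups)

    bk = bestkeeper_rank(sub)
    decomp, nf_res = normfinder_stability(sub)
    expr = relative_quantities(sub)
    gn = genorm_rank(expr)

    consensus = mean_rank(
        {"bestkeeper": bk.ranking, "normfinder": nf_res.rank, "genorm": gn.ranking},
        tiebreak=nf_res.rho,
    )

    # co-regulation guard: GeNorm's top pair must not share a gene family
    excluded: dict[str, str] = {}
    gn_final = gn
    if _same_family(gn.top_pair, family_map):
        a, b = gn.top_pair
        worse = a if consensus.index.get_loc(a) > consensus.index.get_loc(b) else b
        excluded[worse] = (
            f"co-regulated family member ({family_map[worse]}); "
            "removed from GeNorm and re-run"
        )
        kept = [g for g in expr.genes if g != worse]
        gn_final = genorm_rank(expr, kept)
    gn_final = genorm_v(expr, gn_final, v_threshold)

    nf_decision = None
    if len(groups) >= 2:
        selected = normfinder_select_nf(decomp, nf_res, max_genes=max_nf_genes)
        best_single = nf_res.rank.idxmin()
        best_single_rho = nf_set_stability(decomp, [best_single])
        verdict = evaluate_nf_candidate(selected.nf_rho, best_single_rho)
        nf_decision = NFDecision(
            selected.nf_genes, selected.nf_rho, best_single, best_single_rho, verdict
        )
    else:
        warnings.warn(
            f"step {label!r}: NF selection skipped (requires >=2 groups)", stacklevel=2
        )

    baseline = baseline_group or groups[0]
    if len(groups) >= 2:
        flags = bias_table(expr, baseline, alpha)
    else:  # intergroup testing is undefined within a single group
        flags = pd.DataFrame(
            {"p_value": np.nan, "flag": "not assessed"}, index=expr.genes
        )

    return ValidationReport(
        step_label=label,
        groups=tuple(groups),
        bestkeeper=bk,
        normfinder=nf_res,
        normfinder_decomposition=decomp,
        genorm=gn,
        genorm_final=gn_final,
        consensus=consensus,
        nf_decision=nf_decision,
        v_series=gn_final.v_series,
        recommended_n=gn_final.recommended_n,
        bias_flags=flags,
        excluded_genes=excluded,
    )


def run_validation(
    ct: CtTable,
    steps: list[list[str]] | None = None,
    family_map: GeneFamilyMap | None = None,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    max_nf_genes: int | None = None,
    baseline_group: str | None = None,
) -> list[ValidationReport]:
    """Run the stepped validation strategy; one report per group subset.

    The default strategy mirrors the two-step design: all groups except the
    last, then all groups together (with fewer than three groups, a single
    all-group step).
    """
    group_names = ct.design.group_names
    if steps is None:
        steps = (
            [group_names[:-1], group_names] if len(group_names) >= 3 else [group_names]
        )
    known = set(group_names)
    for step in steps:
        unknown = [g for g in step if g not in known]
        if unknown:
            raise DataValidationError(f"step references unknown group(s): {unknown}")
    return [
        validate_step(
            ct,
            list(step),
            family_map=family_map,
            v_threshold=v_threshold,
            alpha=alpha,
            max_nf_genes=max_nf_genes,
            baseline_group=baseline_group if baseline_group in set(step) else step[0],
        )
        for step in steps
    ]


def report_to_dict(report: ValidationReport) -> dict:
    """JSON-serializable summary of one validation report."""
    return {
        "step": report.step_label,
        "groups": list(report.groups),
        "consensus_order": report.consensus_order,
        "mean_rank": {g: float(v) for g, v in report.consensus["mean_rank"].items()},
        "bestkeeper_rank": {g: int(v) for g, v in report.bestkeeper.ranking.items()},
        "normfinder_rank": {g: int(v) for g, v in report.normfinder.rank.items()},
        "normfinder_rho": {g: float(v) for g, v in report.normfinder.rho.items()},
        "genorm_rank": {g: int(v) for g, v in report.genorm.ranking.items()},
        "genorm_m": {g: float(v) for g, v in report.genorm.m.items()},
        "nf_decision": (
            None
            if report.nf_decision is None
            else {
                "genes": list(report.nf_decision.genes),
                "stability": report.nf_decision.stability,
                "best_single_gene": report.nf_decision.best_single_gene,
                "best_single_stability": report.nf_decision.best_single_stability,
                "verdict": report.nf_decision.verdict,
            }
        ),
        "v_series": {str(k): float(v) for k, v in report.v_series.items()},
        "recommended_n": report.recommended_n,
        "excluded_genes": dict(report.excluded_genes),
        "bias_flags": {
            g: {
                "p_value": None if pd.isna(row["p_value"]) else float(row["p_value"]),
                "flag": row["flag"],
            }
            for g, row in report.bias_flags.iterrows()
        },
    }
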