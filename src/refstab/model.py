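"""Model/Results facade over the validation workflow.

`ReferenceGeneStability` is constructed from a ct table (or from files) and
holds the analysis configuration; `fit()` runs the stepped three-algorithm
validation and returns a `StabilityResults` object carrying per-step reports,
a `summary()` table, and JSON/TSV export. Simulation from shipped scenario
presets hangs off the model class.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import synthetic_data
from .bias_assessment import DEFAULT_ALPHA
from .consensus import ValidationReport, report_to_dict, run_validation
from .data_model import CtTable, read_ct_table
from .genorm import DEFAULT_V_THRESHOLD

_SCENARIOS = {
    "null": synthetic_data.null_ct_scenario,
    "paper-like": synthetic_data.paper_like_ct_scenario,
    "exchangeable": synthetic_data.exchangeable_ct_scenario,
}


class ReferenceGeneStability:
    """Reference-gene stability validation model.

    Parameters
    ----------
    ct
        Validated ct table with its group design.
    steps
        Group subsets to analyze, e.g. ``[["preterm", "fullterm"],
        ["preterm", "fullterm", "adult"]]``; defaults to the two-step strategy
        (all-but-last groups, then all groups).
    family_map
        Gene label -> family label; used by the GeNorm co-regulation guard.
    v_threshold
        GeNorm pairwise-variation threshold (default 0.15).
    alpha
        Significance level for intergroup bias flags (default 0.05).
    max_nf_genes
        Optional cap on the NormFinder NF gene-set size.
    baseline_group
        Baseline for fold changes; defaults to each step's first group.
    """

    def __init__(
        self,
        ct: CtTable,
        steps: list[list[str]] | None = None,
        family_map: Mapping[str, str] | None = None,
        v_threshold: float = DEFAULT_V_THRESHOLD,
        alpha: float = DEFAULT_ALPHA,
        max_nf_genes: int | None = None,
        baseline_group: str | None = None,
    ):
        self.ct = ct
        self.steps = steps
        self.family_map = dict(family_map) if family_map else None
        self.v_threshold = v_threshold
        self.alpha = alpha
        self.max_nf_genes = max_nf_genes
        self.baseline_group = baseline_group

    @classmethod
    def from_files(cls, ct_path, design_path, **kwargs) -> "ReferenceGeneStability":
        return cls(read_ct_table(ct_path, design_path), **kwargs)

    @classmethod
    def simulate(cls, scenario: str = "paper-like", seed: int = 0, **kwargs):
        """Build a model on data drawn from a shipped synthetic scenario."""
        if scenario not in _SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(_SCENARIOS)}")
        table, _ = synthetic_data.simulate_ct(_SCENARIOS[scenario](), seed)
        return cls(table, **kwargs)

    def fit(self) -> "StabilityResults":
        reports = run_validation(
            self.ct,
            steps=self.steps,
            family_map=self.family_map,
            v_threshold=self.v_threshold,
            alpha=self.alpha,
            max_nf_genes=self.max_nf_genes,
            baseline_group=self.baseline_group,
        )
        return StabilityResults(self, reports)


class StabilityResults:
    """Fitted validation results: one :class:`ValidationReport` per step."""

    def __init__(self, model: ReferenceGeneStability, reports: list[ValidationReport]):
        self.model = model
        self.reports = reports

    def report(self, step: int | str = 0) -> ValidationReport:
        if isinstance(step, int):
            return self.reports[step]
        for r in self.reports:
            if r.step_label == step:
                return r
        raise KeyError(f"no step labelled {step!r}")

    def consensus_table(self, step: int | str = 0) -> pd.DataFrame:
        return self.report(step).consensus

    def summary(self) -> str:
        """Human-readable per-step summary of rankings, NF verdicts and flags."""
        lines: list[str] = []
        for rep in self.reports:
            lines.append(f"Step: {rep.step_label} (groups: {', '.join(rep.groups)})")
            lines.append("-" * 72)
            tab = rep.consensus.copy()
            tab["M"] = rep.genorm.m.reindex(tab.index).round(3)
            tab["rho"] = rep.normfinder.rho.reindex(tab.index).round(3)
            tab["sd_ct"] = rep.bestkeeper.table["sd_ct"].reindex(tab.index).round(3)
            tab["bias"] = rep.bias_flags["flag"].reindex(tab.index)
            lines.append(tab.to_string(float_format=lambda v: f"{v:.3f}"))
            if rep.nf_decision is not None:
                d = rep.nf_decision
                lines.append(
                    f"NF candidate {'/'.join(d.genes)}: stability {d.stability:.3f} "
                    f"vs best single {d.best_single_gene} {d.best_single_stability:.3f} "
                    f"-> {d.verdict}"
                )
            v_str = ", ".join(f"V{n}={v:.3f}" for n, v in rep.v_series.items())
            rec = (
                f"recommended NF size n={rep.recommended_n}"
                if rep.recommended_n is not None
                else "no V below threshold (none below threshold)"
            )
            lines.append(f"GeNorm V: {v_str}; {rec}")
            for gene, reason in rep.excluded_genes.items():
                lines.append(f"Excluded from GeNorm: {gene} ({reason})")
            lines.append("")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = json.dumps([report_to_dict(r) for r in self.reports], indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_tsv(self, directory) -> list[Path]:
        """Write one consensus TSV per step; returns the written paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for i, rep in enumerate(self.reports):
            out = directory / f"step{i + 1}_{rep.step_label.replace('+', '_')}.tsv"
            tab = rep.consensus.copy()
            tab["bias_flag"] = rep.bias_flags["flag"].reindex(tab.index)
            tab.index.name = "gene"
            tab.to_csv(out, sep="\t")
            written.append(out)
        return written

    def plot_stability(self, step: int | str = 0, ax=None):
        """Bar chart of consensus mean ranks for one step (requires matplotlib)."""
        import matplotlib.pyplot as plt

        rep = self.report(step)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3.5))
        tab = rep.consensus
        ax.bar(tab.index, tab["mean_rank"], color="#4878b0")
        ax.set_ylabel("mean rank (lower = more stable)")
        ax.set_title(f"Consensus stability — {rep.step_label}")
        ax.tick_params(axis="x", rotation=45)
        return ax
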