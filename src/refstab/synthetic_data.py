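"""Synthetic qPCR ct tables and RNA-seq count matrices with known ground truth.

The ct generator mirrors the structure of whole-blood RT-qPCR reference-gene
panels: per-gene baselines spanning the high-to-medium expression range
(ct ~15.6-29.6 cycles), a shared per-sample loading offset (RNA input /
reverse-transcription efficiency, common to all genes of a sample), optional
group-level shifts (age-dependent expression), and per-gene Gaussian noise:

    ct_igj = baseline_i + shift_ig + b_gj + eps_igj,
    b_gj ~ N(0, sample_effect_sd^2)  shared across genes within sample j,
    eps_igj ~ N(0, noise_sd_i^2).

The count generator draws negative-binomial reads with per-gene means and
dispersions, sample-specific (log-normal) size factors, and per-group log2
fold effects; a subset of genes can be planted to satisfy the reference-gene
screen filters by a comfortable margin.

Both generators are pure functions of (scenario, seed); tests assert
statistics of the output, never the random stream itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_model import CountMatrix, CtTable, DataValidationError, GroupDesign

__all__ = [
    "GeneSpec",
    "CtScenario",
    "CountGeneSpec",
    "CountScenario",
    "simulate_ct",
    "simulate_counts",
    "null_ct_scenario",
    "paper_like_ct_scenario",
    "perturbed_paper_like_scenario",
    "screen_bench_count_scenario",
    "exchangeable_ct_scenario",
]


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: baseline ct (cycles), per-group shifts (cycles,
    added to ct — positive = lower expression in that group), noise SD (cycles)."""

    name: str
    baseline: float
    shifts: tuple[float, ...]
    noise_sd: float


@dataclass(frozen=True)
class CtScenario:
    group_names: tuple[str, ...]
    n_per_group: int
    genes: tuple[GeneSpec, ...]
    sample_effect_sd: float

    def __post_init__(self):
        if len(self.group_names) < 1 or self.n_per_group < 1:
            raise DataValidationError("scenario needs >=1 group with >=1 sample")
        if self.sample_effect_sd < 0:
            raise DataValidationError("sample_effect_sd must be >= 0")
        for g in self.genes:
            if g.noise_sd < 0:
                raise DataValidationError(f"gene {g.name!r}: noise SD must be >= 0")
            if len(g.shifts) != len(self.group_names):
                raise DataValidationError(
                    f"gene {g.name!r}: needs one shift per group "
                    f"({len(self.group_names)} groups)"
                )


@dataclass(frozen=True)
class CountGeneSpec:
    """One simulated transcript: NB mean and dispersion (var = mu + disp*mu^2),
    per-group log2 fold effects, and whether it is a planted reference gene."""

    name: str
    mean: float
    dispersion: float
    log2_effects: tuple[float, ...]
    is_reference: bool = False


@dataclass(frozen=True)
class CountScenario:
    group_names: tuple[str, ...]
    n_per_group: int
    genes: tuple[CountGeneSpec, ...]
    size_factor_sd: float

    def __post_init__(self):
        if len(self.group_names) < 1 or self.n_per_group < 1:
            raise DataValidationError("scenario needs >=1 group with >=1 sample")
        if self.size_factor_sd < 0:
            raise DataValidationError("size_factor_sd must be >= 0")
        for g in self.genes:
            if g.mean <= 0 or g.dispersion < 0:
                raise DataValidationError(f"gene {g.name!r}: mean > 0, dispersion >= 0")
            if len(g.log2_effects) != len(self.group_names):
                raise DataValidationError(f"gene {g.name!r}: one log2 effect per group")


def simulate_ct(scenario: CtScenario, seed: int) -> tuple[CtTable, dict]:
    """Draw one ct table from the scenario; returns (table, truth record)."""
    rng = np.random.default_rng(seed)
    groups = [g for g in scenario.group_names for _ in range(scenario.n_per_group)]
    samples = [
        f"{g}_{k + 1}" for g in scenario.group_names for k in range(scenario.n_per_group)
    ]
    n = len(samples)
    b = rng.normal(0.0, scenario.sample_effect_sd, size=n)
    ct = np.empty((n, len(scenario.genes)))
    group_index = np.array(
        [scenario.group_names.index(g) for g in groups], dtype=int
    )
    for i, gene in enumerate(scenario.genes):
        shift = np.asarray(gene.shifts)[group_index]
        eps = rng.normal(0.0, gene.noise_sd, size=n)
        ct[:, i] = gene.baseline + shift + b + eps
    table = CtTable(
        pd.DataFrame(ct, index=samples, columns=[g.name for g in scenario.genes]),
        GroupDesign(pd.Series(groups, index=samples)),
    )
    truth = {
        "shifts": {g.name: dict(zip(scenario.group_names, g.shifts)) for g in scenario.genes},
        "noise_sd": {g.name: g.noise_sd for g in scenario.genes},
        "sample_effect": dict(zip(samples, b)),
    }
    return table, truth


def simulate_counts(scenario: CountScenario, seed: int) -> tuple[CountMatrix, dict]:
    """Draw one NB count matrix from the scenario; returns (matrix, truth)."""
    rng = np.random.default_rng(seed)
    groups = [g for g in scenario.group_names for _ in range(scenario.n_per_group)]
    samples = [
        f"{g}_{k + 1}" for g in scenario.group_names for k in range(scenario.n_per_group)
    ]
    n = len(samples)
    sf = np.exp(rng.normal(0.0, scenario.size_factor_sd, size=n))
    group_index = np.array([scenario.group_names.index(g) for g in groups], dtype=int)
    counts = np.empty((len(scenario.genes), n), dtype=np.int64)
    for i, gene in enumerate(scenario.genes):
        effect = np.asarray(gene.log2_effects)[group_index]
        mu = gene.mean * sf * np.power(2.0, effect)
        if gene.dispersion == 0:
            counts[i] = rng.poisson(mu)
        else:
            r = 1.0 / gene.dispersion
            counts[i] = rng.negative_binomial(r, r / (r + mu))
    matrix = CountMatrix(
        pd.DataFrame(counts, index=[g.name for g in scenario.genes], columns=samples),
        GroupDesign(pd.Series(groups, index=samples)),
    )
    truth = {
        "planted_reference_genes": [g.name for g in scenario.genes if g.is_reference],
        "size_factors": dict(zip(samples, sf)),
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# Shipped presets
# ---------------------------------------------------------------------------

_PANEL = ("ACTB", "B2M", "GAPDH", "GUSB", "HPRT", "PPIB", "RPLP0", "RPL13")
# Baselines follow the observed high-to-medium expression range (ACTB most
# expressed at ~15.6 cycles, GUSB least at ~29.6).
_BASELINES = (15.6, 21.0, 18.5, 29.6, 25.5, 22.5, 19.5, 20.5)


def null_ct_scenario(n_per_group: int = 10) -> CtScenario:
    """Three groups, no group effects, equal noise: the calibration scenario."""
    genes = tuple(
        GeneSpec(name, base, (0.0, 0.0, 0.0), 0.5)
        for name, base in zip(_PANEL, _BASELINES)
    )
    return CtScenario(("preterm", "fullterm", "adult"), n_per_group, genes, 0.5)


def exchangeable_ct_scenario(n_genes: int = 8, n_per_group: int = 10) -> CtScenario:
    """Fully exchangeable genes (identical baseline and noise, no effects).

    Under this symmetry every gene's rank in any stability analysis is
    uniformly distributed over seeds, which the varied-baseline null scenario
    only approximates.
    """
    genes = tuple(
        GeneSpec(f"G{i + 1}", 20.0, (0.0, 0.0, 0.0), 0.5) for i in range(n_genes)
    )
    return CtScenario(("preterm", "fullterm", "adult"), n_per_group, genes, 0.5)


def paper_like_ct_scenario(n_per_group: int = 10) -> CtScenario:
    """Eight-gene whole-blood panel, three age groups of 10.

    Expression rises with age: a common trend of roughly -0.3 cycles (full
    term) and -1.0 cycles (adult) relative to preterm, with small per-gene
    deviations (RPLP0 carries the mildest trend). Every gene therefore shows
    a small but statistically detectable intergroup difference at n = 10 per
    group, while the genes' deviations from each other stay modest — the
    common trend is indistinguishable from a loading effect and is absorbed
    by all three stability algorithms.
    """
    shifts = {
        "ACTB": (0.0, -0.35, -1.10),
        "B2M": (0.0, -0.40, -1.15),
        "GAPDH": (0.0, -0.30, -0.95),
        "GUSB": (0.0, -0.40, -1.10),
        "HPRT": (0.0, -0.25, -0.90),
        "PPIB": (0.0, -0.30, -1.00),
        "RPLP0": (0.0, -0.20, -0.85),
        "RPL13": (0.0, -0.25, -0.95),
    }
    genes = tuple(
        GeneSpec(name, base, shifts[name], 0.35)
        for name, base in zip(_PANEL, _BASELINES)
    )
    return CtScenario(("preterm", "fullterm", "adult"), n_per_group, genes, 0.5)


def perturbed_paper_like_scenario(
    shifted_gene: str = "HPRT",
    shift_cycles: float = 1.0,
    shifted_group: str = "fullterm",
    noisy_gene: str = "B2M",
    noise_factor: float = 3.0,
    n_per_group: int = 10,
) -> CtScenario:
    """Paper-like scenario with one extra group-shifted and one noise-inflated
    gene — the benchmark for detecting designed instability."""
    base = paper_like_ct_scenario(n_per_group)
    gidx = base.group_names.index(shifted_group)
    genes = []
    for spec in base.genes:
        if spec.name == shifted_gene:
            shifts = tuple(
                s + (shift_cycles if i == gidx else 0.0) for i, s in enumerate(spec.shifts)
            )
            spec = replace(spec, shifts=shifts)
        if spec.name == noisy_gene:
            spec = replace(spec, noise_sd=spec.noise_sd * noise_factor)
        genes.append(spec)
    return replace(base, genes=tuple(genes))


def screen_bench_count_scenario(
    n_genes: int = 2000, n_per_group: int = 8, n_reference: int = 10
) -> CountScenario:
    """Two-group cord-blood-like screen benchmark (default 2000 genes, 8+8).

    ``n_reference`` genes are planted to clear all three screen filters with
    generous margins (high mean, tiny dispersion, no group effect); the rest
    fail by construction, either on expression level (mean log2 well below 5)
    or on variability (a 4-fold group effect or a strong within-group spread).
    """
    genes: list[CountGeneSpec] = []
    for i in range(n_reference):
        genes.append(
            CountGeneSpec(f"REF{i + 1:02d}", 400.0 + 40.0 * i, 0.005, (0.0, 0.0), True)
        )
    n_rest = n_genes - n_reference
    n_shifted = max(n_rest // 10, 1)
    for i in range(n_shifted):
        # strongly regulated genes: big group fold change -> sd_log >= 1.5
        genes.append(CountGeneSpec(f"DE{i + 1:04d}", 300.0 + 5.0 * (i % 40), 0.05, (0.0, 4.0)))
    for i in range(n_rest - n_shifted):
        # low-expression background: mean log2(UQ+1) ~ 3-4.4, below filter (i)
        genes.append(
            CountGeneSpec(f"BG{i + 1:04d}", 5.0 + (i % 16), 0.1, (0.0, 0.0))
        )
    return CountScenario(("preterm", "fullterm"), n_per_group, tuple(genes), 0.2)
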