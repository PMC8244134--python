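import math

import numpy as np
import pandas as pd
import pytest

from refstab import synthetic_data as sd
from refstab.data_model import DataValidationError
from refstab.normfinder import (
    NormFinderDecomposition,
    nf_set_stability,
    normfinder_select_nf,
    normfinder_stability,
)

from conftest import make_ct, make_design


def spreadsheet_oracle(matrix, group_sizes):
    """Step-by-step loop implementation of the variance decomposition.

    matrix: samples x genes; group_sizes: list of per-group sample counts
    (samples ordered by group). Returns (d, d_shrunk, gamma2, rho) arrays.
    """
    n_samples, n_genes = matrix.shape
    G = len(group_sizes)
    bounds = np.cumsum([0] + list(group_sizes))
    # step 1: per-sample centering across genes
    z = np.empty_like(matrix, dtype=float)
    for j in range(n_samples):
        row_mean = sum(matrix[j]) / n_genes
        for i in range(n_genes):
            z[j, i] = matrix[j, i] - row_mean
    d = np.zeros((n_genes, G))
    gamma2 = np.zeros((n_genes, G))
    for i in range(n_genes):
        cell_means = []
        for g in range(G):
            cell = z[bounds[g] : bounds[g + 1], i]
            m = sum(cell) / len(cell)
            cell_means.append(m)
            gamma2[i, g] = sum((x - m) ** 2 for x in cell) / (len(cell) - 1)
        grand = sum(cell_means) / G
        for g in range(G):
            d[i, g] = cell_means[g] - grand
    d_shrunk = np.zeros_like(d)
    for i in range(n_genes):
        denom = sum(d[i, g] ** 2 for g in range(G)) / (G - 1) if G > 1 else 0.0
        for g in range(G):
            if denom == 0:
                c = 0.0
            else:
                c = max(0.0, 1.0 - (gamma2[i, g] / group_sizes[g]) / denom)
            d_shrunk[i, g] = d[i, g] * c
    rho = np.array(
        [
            sum(
                abs(d_shrunk[i, g]) + math.sqrt(gamma2[i, g] / group_sizes[g])
                for g in range(G)
            )
            / G
            for i in range(n_genes)
        ]
    )
    return d, d_shrunk, gamma2, rho


class TestStability:
    def test_identical_genes_have_zero_rho(self):
        design = make_design({"g1": 3, "g2": 3})
        col = np.array([20.0, 21, 22, 23, 24, 25])
        table = make_ct(np.column_stack([col, col]), ["A", "B"], design)
        _, result = normfinder_stability(table)
        assert result.rho.tolist() == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_gene_location_shift_leaves_rho_unchanged(self, random_ct):
        ct = random_ct(n_samples=8, n_genes=4, seed=1)
        shifted_vals = ct.ct.copy()
        shifted_vals["G2"] += 3.0
        shifted = make_ct(shifted_vals.to_numpy(), ct.genes, ct.design)
        _, r1 = normfinder_stability(ct)
        _, r2 = normfinder_stability(shifted)
        assert r1.rho["G2"] == pytest.approx(r2.rho["G2"], abs=1e-10)

    def test_matches_spreadsheet_oracle(self):
        rng = np.random.default_rng(17)
        design = make_design({"g1": 5, "g2": 5})
        vals = rng.uniform(18, 30, size=(10, 4))
        table = make_ct(vals, ["A", "B", "C", "D"], design)
        decomp, result = normfinder_stability(table)
        d, d_shrunk, gamma2, rho = spreadsheet_oracle(vals, [5, 5])
        assert decomp.d.to_numpy() == pytest.approx(d, abs=1e-10)
        assert decomp.d_shrunk.to_numpy() == pytest.approx(d_shrunk, abs=1e-10)
        assert decomp.gamma2.to_numpy() == pytest.approx(gamma2, abs=1e-10)
        assert result.rho.to_numpy() == pytest.approx(rho, abs=1e-10)

    def test_d_sums_to_zero_per_gene(self, random_ct):
        ct = random_ct(n_samples=12, n_genes=5, seed=8, groups=("a", "b", "c"))
        decomp, _ = normfinder_stability(ct)
        assert decomp.d.sum(axis=1).to_numpy() == pytest.approx(0.0, abs=1e-10)
        assert (decomp.d_shrunk.abs().to_numpy() <= decomp.d.abs().to_numpy() + 1e-12).all()
        assert (decomp.gamma2.to_numpy() >= 0).all()

    def test_single_group_rho_is_noise_sd(self):
        rng = np.random.default_rng(2)
        design = make_design({"only": 6})
        vals = rng.uniform(18, 26, size=(6, 3))
        table = make_ct(vals, ["A", "B", "C"], design)
        decomp, result = normfinder_stability(table)
        expected = np.sqrt(decomp.gamma2.iloc[:, 0].to_numpy())
        assert result.rho.to_numpy() == pytest.approx(expected, rel=1e-12)

    def test_shifted_gene_has_strictly_larger_rho(self):
        """An artificial +1-cycle group shift always increases a gene's rho."""
        scen = sd.null_ct_scenario()
        for seed in range(10):
            table, _ = sd.simulate_ct(scen, seed)
            vals = table.ct.copy()
            base_rho = normfinder_stability(table)[1].rho["ACTB"]
            vals.loc[table.design.groups == "adult", "ACTB"] += 1.0
            pert = make_ct(vals.to_numpy(), table.genes, table.design)
            assert normfinder_stability(pert)[1].rho["ACTB"] > base_rho

    def test_group_permutation_equivariance(self, random_ct):
        ct = random_ct(n_samples=8, n_genes=4, seed=4)
        _, r1 = normfinder_stability(ct)
        perm = ct.ct[["G3", "G1", "G4", "G2"]]
        _, r2 = normfinder_stability(make_ct(perm.to_numpy(), list(perm.columns), ct.design))
        for g in ct.genes:
            assert r1.rho[g] == pytest.approx(r2.rho[g], abs=1e-12)

    def test_small_group_rejected(self):
        design = make_design({"g1": 3, "g2": 1})
        with pytest.raises(DataValidationError, match="fewer than 2"):
            normfinder_stability(make_ct(np.full((4, 2), 20.0), ["A", "B"], design))


class TestNFSelection:
    def _constructed_decomp(self):
        """Hand-built decomposition: genes A/B have exactly opposite group
        bias and equal noise; C/D are unbiased but noisier. Exercises the
        cancellation mechanism deterministically."""
        genes = ["A", "B", "C", "D"]
        groups = ["g1", "g2"]
        d = pd.DataFrame(
            [[0.3, -0.3], [-0.3, 0.3], [0.05, -0.05], [-0.02, 0.02]],
            index=genes,
            columns=groups,
        )
        gamma2 = pd.DataFrame(
            [[0.04, 0.04], [0.04, 0.04], [1.5, 1.5], [1.5, 1.5]],
            index=genes,
            columns=groups,
        )
        n_g = pd.Series([10.0, 10.0], index=groups)
        return NormFinderDecomposition(d, d.copy(), gamma2, n_g)

    def test_opposite_bias_pair_cancellation(self):
        decomp = self._constructed_decomp()
        pair_rho = nf_set_stability(decomp, ["A", "B"])
        # intergroup term cancels exactly: only the pooled noise remains
        assert pair_rho == pytest.approx(math.sqrt(0.08 / (4 * 10)), rel=1e-12)
        assert pair_rho < min(
            nf_set_stability(decomp, ["A"]), nf_set_stability(decomp, ["B"])
        )
        result = normfinder_select_nf(decomp)
        assert set(result.nf_genes) == {"A", "B"}
        assert result.nf_rho == pytest.approx(pair_rho, rel=1e-12)

    def test_all_identical_genes_stop_at_one(self):
        genes = ["A", "B", "C"]
        zero = pd.DataFrame(0.0, index=genes, columns=["g1", "g2"])
        decomp = NormFinderDecomposition(
            zero, zero.copy(), zero.copy(), pd.Series([5.0, 5.0], index=["g1", "g2"])
        )
        result = normfinder_select_nf(decomp)
        assert len(result.nf_genes) == 1
        assert result.nf_rho == pytest.approx(0.0)

    def test_single_group_rejected(self):
        genes = ["A", "B"]
        zero = pd.DataFrame(0.0, index=genes, columns=["g1"])
        decomp = NormFinderDecomposition(
            zero, zero.copy(), zero.copy(), pd.Series([5.0], index=["g1"])
        )
        with pytest.raises(DataValidationError, match=">=2 groups"):
            normfinder_select_nf(decomp)

    def test_designed_pair_dominates_single_gene_choice(self):
        """In a scenario with a designed low-noise opposite-bias pair among
        noisy neutral genes, the best single gene is one of the pair."""
        genes = (
            sd.GeneSpec("b1", 20.0, (0.0, 0.2), 0.2),
            sd.GeneSpec("b2", 21.0, (0.0, -0.2), 0.2),
        ) + tuple(sd.GeneSpec(f"u{i}", 22.0 + i, (0.0, 0.0), 1.0) for i in range(4))
        scen = sd.CtScenario(("g1", "g2"), 10, genes, 0.5)
        hits = 0
        for seed in range(100):
            table, _ = sd.simulate_ct(scen, seed)
            _, result = normfinder_stability(table)
            sel = normfinder_select_nf(
                normfinder_stability(table)[0], result, max_genes=2
            )
            hits += sel.nf_genes[0] in {"b1", "b2"}
        assert hits >= 95

    def test_max_genes_cap(self):
        decomp = self._constructed_decomp()
        result = normfinder_select_nf(decomp, max_genes=1)
        assert len(result.nf_genes) == 1
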