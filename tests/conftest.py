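import numpy as np
import pandas as pd
import pytest

from refstab.data_model import CtTable, GroupDesign


def make_design(groups: dict[str, int]) -> GroupDesign:
    """Build a design with `n` samples per group, named <group>_<i>."""
    labels = {}
    for g, n in groups.items():
        for i in range(n):
            labels[f"{g}_{i + 1}"] = g
    return GroupDesign(pd.Series(labels))


def make_ct(values, genes, design: GroupDesign) -> CtTable:
    """CtTable from a (samples x genes) array and a design."""
    return CtTable(
        pd.DataFrame(np.asarray(values, dtype=float), index=design.samples, columns=genes),
        design,
    )


@pytest.fixture
def two_group_design():
    return make_design({"preterm": 3, "fullterm": 3})


@pytest.fixture
def random_ct():
    """Factory for random ct tables in a realistic range."""

    def _make(n_samples=8, n_genes=5, seed=0, groups=("g1", "g2")):
        rng = np.random.default_rng(seed)
        per = n_samples // len(groups)
        design = make_design({g: per for g in groups})
        vals = rng.uniform(18.0, 30.0, size=(per * len(groups), n_genes))
        return make_ct(vals, [f"G{i + 1}" for i in range(n_genes)], design)

    return _make
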