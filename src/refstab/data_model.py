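"""Domain containers and file I/O for qPCR ct tables and RNA-seq count matrices.

The containers are thin, validated wrappers around pandas objects:

* :class:`GroupDesign` — sample-to-group assignment (plus optional covariates).
* :class:`CtTable` — samples x genes matrix of cycle-threshold (ct) values.
* :class:`CountMatrix` — genes x samples matrix of raw RNA-seq read counts.
* :class:`ContingencyTable` — groups x categories count table for chi-square tests.

ct values are PCR cycles: the cycle at which a transcript's fluorescence crosses
the detection threshold (lower ct = higher expression, roughly log2 scale). The
qPCR protocols this package targets run 40 cycles; values are validated against a
45-cycle ceiling to leave headroom for other instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CT_MAX = 45.0  # cycles; protocol ceiling with instrument headroom


class DataValidationError(ValueError):
    """Raised when an input table violates a structural or range invariant."""


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate {what} label(s): {dups}")


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of samples to experimental groups.

    Parameters
    ----------
    groups
        Series indexed by sample id, values are group labels (e.g. ``"preterm"``,
        ``"fullterm"``, ``"adult"``). Every sample belongs to exactly one group.
    covariates
        Optional per-sample covariates (e.g. birth mode), indexed like ``groups``.
    """

    groups: pd.Series
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        g = pd.Series(self.groups).astype(str)
        g.index = g.index.astype(str)
        _check_unique(g.index, "sample")
        if len(g) == 0:
            raise DataValidationError("design is empty")
        if g.isna().any():
            raise DataValidationError("every sample must be assigned a group")
        object.__setattr__(self, "groups", g)
        if self.covariates is not None:
            cov = self.covariates.copy()
            cov.index = cov.index.astype(str)
            if not set(g.index).issubset(cov.index):
                raise DataValidationError("covariates must cover all design samples")
            object.__setattr__(self, "covariates", cov.loc[g.index])

    @property
    def samples(self) -> list[str]:
        return list(self.groups.index)

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.groups:
            seen.setdefault(v, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset(self, groups: list[str]) -> "GroupDesign":
        unknown = [g for g in groups if g not in set(self.groups)]
        if unknown:
            raise DataValidationError(f"unknown group(s): {unknown}")
        keep = self.groups[self.groups.isin(groups)]
        cov = self.covariates.loc[keep.index] if self.covariates is not None else None
        return GroupDesign(keep, cov)

    @classmethod
    def from_file(cls, path: str | Path) -> "GroupDesign":
        """Read a design file: TSV with ``sample_id`` and ``group`` columns;
        any further columns are kept as covariates."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "group"}
        if not required.issubset(df.columns):
            raise DataValidationError(
                f"design file must have columns {sorted(required)}; got {list(df.columns)}"
            )
        df = df.set_index("sample_id")
        cov_cols = [c for c in df.columns if c != "group"]
        cov = df[cov_cols] if cov_cols else None
        return cls(df["group"], cov)

    def to_file(self, path: str | Path) -> None:
        df = self.groups.rename("group").to_frame()
        if self.covariates is not None:
            df = df.join(self.covariates)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


@dataclass
class CtTable:
    """Samples x genes matrix of qPCR cycle-threshold values plus a group design.

    ``ct`` rows are samples, columns genes; all entries must be finite and in
    ``(0, CT_MAX]``. ``gene_meta`` may carry informational per-gene records such
    as amplicon length (bp) and PCR efficiency (%); it is never used in the
    stability computations.
    """

    ct: pd.DataFrame
    design: GroupDesign
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self):
        ct = self.ct.copy()
        ct.index = ct.index.astype(str)
        ct.columns = ct.columns.astype(str)
        _check_unique(ct.columns, "gene")
        _check_unique(ct.index, "sample")
        if ct.shape[1] == 0:
            raise DataValidationError("ct table has no genes")
        if ct.shape[0] == 0:
            raise DataValidationError("ct table has no samples")
        vals = ct.to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals <= 0) | (vals > CT_MAX)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataValidationError(
                f"ct value {vals[i, j]!r} for sample {ct.index[i]!r}, gene "
                f"{ct.columns[j]!r} outside (0, {CT_MAX}]"
            )
        missing = set(ct.index) - set(self.design.samples)
        if missing:
            raise DataValidationError(f"sample(s) missing from design: {sorted(missing)}")
        ct.index.name = None
        ct.columns.name = None
        self.ct = ct.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.ct.index)

    def subset_groups(self, groups: list[str]) -> "CtTable":
        design = self.design.subset(groups)
        keep = [s for s in self.samples if s in set(design.samples)]
        return CtTable(self.ct.loc[keep], design, self.gene_meta)

    def select_genes(self, genes: list[str]) -> "CtTable":
        unknown = [g for g in genes if g not in set(self.genes)]
        if unknown:
            raise DataValidationError(f"unknown gene(s): {unknown}")
        meta = self.gene_meta.loc[genes] if self.gene_meta is not None else None
        return CtTable(self.ct[genes], self.design, meta)

    def to_csv(self, path: str | Path) -> None:
        out = self.ct.copy()
        out.index.name = "sample_id"
        out.to_csv(path)


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer RNA-seq read counts."""

    counts: pd.DataFrame
    design: GroupDesign

    def __post_init__(self):
        counts = self.counts.copy()
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        _check_unique(counts.index, "gene")
        _check_unique(counts.columns, "sample")
        if counts.shape[0] == 0:
            raise DataValidationError("count matrix has no genes")
        if counts.shape[1] == 0:
            raise DataValidationError("count matrix has no samples")
        vals = counts.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise DataValidationError("counts must be finite")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise DataValidationError(
                f"negative count for gene {counts.index[i]!r}, sample {counts.columns[j]!r}"
            )
        if (vals != np.round(vals)).any():
            i, j = np.argwhere(vals != np.round(vals))[0]
            raise DataValidationError(
                f"non-integer count {vals[i, j]!r} for gene {counts.index[i]!r}, "
                f"sample {counts.columns[j]!r}"
            )
        missing = set(counts.columns) - set(self.design.samples)
        if missing:
            raise DataValidationError(f"sample(s) missing from design: {sorted(missing)}")
        counts.index.name = None
        counts.columns.name = None
        self.counts = counts.astype(np.int64)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class ContingencyTable:
    """Groups x categories count table, e.g. corticosteroid exposure by group."""

    counts: pd.DataFrame = field()

    def __post_init__(self):
        df = pd.DataFrame(self.counts)
        vals = df.to_numpy(dtype=float)
        if (vals < 0).any() or not np.isfinite(vals).all():
            raise DataValidationError("contingency counts must be finite and >= 0")
        object.__setattr__(self, "counts", df.astype(float))

    def drop_empty_categories(self) -> "ContingencyTable":
        keep = self.counts.loc[:, self.counts.sum(axis=0) > 0]
        return ContingencyTable(keep)


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV or TSV, sniffing the delimiter from the extension."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_ct_table(
    path: str | Path,
    design_path: str | Path,
    drop_incomplete_samples: bool = False,
) -> CtTable:
    """Load a ct table (samples in rows, genes in columns) and its design.

    A ``replicate`` column marks technical replicates: rows sharing a sample id
    are collapsed by the arithmetic mean of ct per gene. Missing cells are an
    error unless ``drop_incomplete_samples`` removes the affected samples.
    """
    # check the raw header: pandas silently mangles duplicate column labels
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header[1:], "gene")

    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise DataValidationError("ct table needs a sample column plus >=1 gene column")
    sample_col = raw.columns[0]
    rep_cols = [c for c in raw.columns if c.lower() == "replicate"]
    gene_cols = [c for c in raw.columns if c != sample_col and c not in rep_cols]

    num = raw[gene_cols].apply(pd.to_numeric, errors="coerce")
    for j, gene in enumerate(gene_cols):
        bad = num[gene].isna() & raw[gene].notna()
        if bad.any():
            s = raw.loc[bad, sample_col].iloc[0]
            raise DataValidationError(
                f"non-numeric ct {raw.loc[bad, gene].iloc[0]!r} for sample {s!r}, gene {gene!r}"
            )
    num.insert(0, sample_col, raw[sample_col].astype(str))

    # collapse technical replicates by arithmetic mean of ct
    collapsed = num.groupby(sample_col, sort=False).mean()

    if collapsed.isna().any().any():
        if drop_incomplete_samples:
            collapsed = collapsed.dropna(axis=0, how="any")
            if collapsed.empty:
                raise DataValidationError("all samples dropped as incomplete")
        else:
            s = collapsed.index[collapsed.isna().any(axis=1)][0]
            g = collapsed.columns[collapsed.loc[s].isna()][0]
            raise DataValidationError(
                f"missing ct for sample {s!r}, gene {g!r} "
                "(use drop_incomplete_samples to remove such samples)"
            )

    design = GroupDesign.from_file(design_path)
    missing = set(collapsed.index) - set(design.samples)
    if missing:
        raise DataValidationError(f"sample(s) missing from design: {sorted(missing)}")
    return CtTable(collapsed, design)


def read_count_matrix(path: str | Path, design_path: str | Path) -> CountMatrix:
    """Load an RNA-seq count matrix (genes in rows, ``gene_id`` first column)."""
    raw = pd.read_csv(path, sep="\t")
    if raw.shape[1] < 2:
        raise DataValidationError("count matrix needs gene_id plus >=1 sample column")
    counts = raw.set_index(raw.columns[0])
    design = GroupDesign.from_file(design_path)
    return CountMatrix(counts, design)
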