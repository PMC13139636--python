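"""Domain types, TSV/Newick readers and writers, and count-table transforms.

The pipeline's universal currency is the :class:`CountTable`, a samples x taxa
matrix of nonnegative integer read counts.  Taxonomic lineages, host metadata
(body size and BMI), and a rooted phylogeny complete the input surface.  All
readers are strict: malformed cells, duplicate identifiers and empty samples
raise immediately with the offending row or column named.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "RANKS",
    "SEASONS",
    "HABITATS",
    "CountTable",
    "TaxonomyMap",
    "SampleMetadata",
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "to_relative",
    "collapse_rank",
    "filter_taxa",
]

#: Canonical rank order used for lineage columns and collapsing.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Closed category sets for host metadata.
SEASONS = frozenset({"spring", "summer", "autumn"})
HABITATS = frozenset({"woodland", "farmland", "grassland"})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountTable:
    """Samples x taxa matrix of nonnegative integer counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns taxa, cells integer counts.  Row and column
        labels must be unique and every sample must contain at least one read.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon IDs: {dupes}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("count table contains non-integer cells")
            df = df.round().astype(np.int64)
            object.__setattr__(self, "data", df)
            arr = df.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
            )
        totals = arr.sum(axis=1)
        if (totals == 0).any():
            empty = df.index[totals == 0].tolist()
            raise ValueError(f"samples with zero total count: {empty}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def totals(self) -> pd.Series:
        """Per-sample read totals."""
        return self.data.sum(axis=1)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        """Restrict to ``sample_ids`` (order as given), dropping all-zero taxa."""
        sub = self.data.loc[list(sample_ids)]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        return CountTable(sub)


@dataclass(frozen=True)
class TaxonomyMap:
    """Mapping from taxon ID to a 7-rank lineage (domain..species).

    Unassigned ranks are empty strings.  Lineages are stored as tuples of
    length 7 in the fixed :data:`RANKS` order.
    """

    lineages: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for tid, lin in self.lineages.items():
            if len(lin) != len(RANKS):
                raise ValueError(
                    f"lineage for {tid!r} has {len(lin)} ranks, expected {len(RANKS)}"
                )

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.lineages

    def lineage(self, taxon_id: str) -> tuple[str, ...]:
        try:
            return tuple(self.lineages[taxon_id])
        except KeyError:
            raise KeyError(f"taxon {taxon_id!r} missing from taxonomy") from None

    def label_at(self, taxon_id: str, rank: str) -> str:
        """Collapsing label for ``taxon_id`` at ``rank``.

        An empty rank is pooled under ``unclassified_<parent>`` where
        ``<parent>`` is the nearest assigned ancestor rank label (or
        ``unclassified`` outright when the whole lineage is blank).
        """
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        idx = RANKS.index(rank)
        lin = self.lineage(taxon_id)
        if lin[idx]:
            return lin[idx]
        for parent in range(idx - 1, -1, -1):
            if lin[parent]:
                return f"unclassified_{lin[parent]}"
        return "unclassified"


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample host metadata: season, habitat and body-size parameters.

    BMI is body weight (g) divided by squared body length (cm), i.e. g/cm^2.
    When both weight and length are present, a stored ``bmi`` column must
    agree with that ratio; if absent it is derived.
    """

    data: pd.DataFrame

    NUMERIC = ("body_weight", "body_length", "tail_length", "bmi")

    def __post_init__(self) -> None:
        df = self.data.copy()
        if df.index.has_duplicates:
            raise ValueError("duplicate sample IDs in metadata")
        bad_season = set(df["season"].dropna()) - SEASONS
        if bad_season:
            raise ValueError(f"unknown season values: {sorted(bad_season)}")
        bad_hab = set(df["habitat"].dropna()) - HABITATS
        if bad_hab:
            raise ValueError(f"unknown habitat values: {sorted(bad_hab)}")
        expected = df["body_weight"] / df["body_length"] ** 2
        if "bmi" in df.columns and df["bmi"].notna().any():
            both = df["bmi"].notna() & expected.notna()
            if not np.allclose(df.loc[both, "bmi"], expected[both], atol=1e-9):
                raise ValueError("bmi column inconsistent with weight/length^2")
        df["bmi"] = expected
        object.__setattr__(self, "data", df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def body_size(self) -> pd.DataFrame:
        return self.data[list(self.NUMERIC)].astype(float)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_count_table(path: str | Path, taxa_as_rows: bool = True) -> CountTable:
    """Read a TSV count table.

    By default files are taxa-as-rows with samples as columns (the common
    QIIME-style export); set ``taxa_as_rows=False`` for the transpose.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate column IDs in {path}: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = None
    df.columns.name = None
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    arr = df.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ValueError(
            f"non-integer count in {path} at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    df = df.astype(np.int64)
    if taxa_as_rows:
        df = df.T
    df.index = pd.Index([str(i) for i in df.index])
    df.columns = pd.Index([str(c) for c in df.columns])
    return CountTable(df)


def write_count_table(ct: CountTable, path: str | Path, taxa_as_rows: bool = True) -> None:
    df = ct.data.T if taxa_as_rows else ct.data
    df.to_csv(path, sep="\t", index_label="id")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read taxonomy as 7 rank columns or one semicolon-delimited lineage column.

    Greengenes-style ``k__Bacteria; p__...`` prefixes are stripped; the format
    is auto-detected from the number of columns.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    if df.index.has_duplicates:
        raise ValueError("duplicate taxon IDs in taxonomy")
    lineages: dict[str, tuple[str, ...]] = {}
    if df.shape[1] == 1:
        for tid, cell in df.iloc[:, 0].items():
            parts = [p.strip() for p in str(cell).split(";")]
            parts = [p.split("__", 1)[1] if "__" in p[:4] else p for p in parts]
            parts = (parts + [""] * len(RANKS))[: len(RANKS)]
            lineages[str(tid)] = tuple(parts)
    else:
        cols = list(df.columns[: len(RANKS)])
        for tid, row in df[cols].iterrows():
            parts = [str(v).strip() for v in row.tolist()]
            parts = (parts + [""] * len(RANKS))[: len(RANKS)]
            lineages[str(tid)] = tuple(parts)
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    df = pd.DataFrame.from_dict(
        {tid: list(lin) for tid, lin in tax.lineages.items()},
        orient="index",
        columns=list(RANKS),
    )
    df.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree; validates unique tips and nonnegative lengths."""
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length at {node.name!r}")
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


def to_relative(ct: CountTable) -> pd.DataFrame:
    """Row-normalize counts to relative abundances (each row sums to 1)."""
    totals = ct.data.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("cannot normalize sample with zero total")
    return ct.data.div(totals, axis=0)


def collapse_rank(ct: CountTable, tax: TaxonomyMap, rank: str) -> CountTable:
    """Sum counts into lineage labels at ``rank``; conserves per-sample totals.

    Taxa unassigned at ``rank`` pool into ``unclassified_<parent>`` labels so
    no reads are dropped.
    """
    labels = [tax.label_at(tid, rank) for tid in ct.taxon_ids]
    collapsed = ct.data.T.groupby(pd.Index(labels, name=rank), sort=True).sum().T
    return CountTable(collapsed)


def filter_taxa(
    ct: CountTable,
    min_mean_relabund: float = 0.0,
    min_prevalence: float = 0.0,
) -> CountTable:
    """Keep taxa with mean relative abundance >= ``min_mean_relabund`` AND
    prevalence (fraction of samples with count > 0) >= ``min_prevalence``.

    Mean relative abundance is the mean of per-sample relative abundances,
    not the pooled-count share.  Sample set is unchanged; the result may have
    zero taxa.
    """
    for name, v in (("min_mean_relabund", min_mean_relabund), ("min_prevalence", min_prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    rel = to_relative(ct)
    mean_rel = rel.mean(axis=0)
    prev = (ct.data > 0).mean(axis=0)
    keep = (mean_rel >= min_mean_relabund) & (prev >= min_prevalence)
    return CountTable(ct.data.loc[:, keep[keep].index]) if keep.any() else _empty_like(ct)


def _empty_like(ct: CountTable) -> CountTable:
    # bypass the zero-total invariant: an all-filtered table is a legal,
    # explicitly-empty result the caller must handle
    empty = pd.DataFrame(
        np.zeros((ct.n_samples, 0), dtype=np.int64), index=ct.data.index
    )
    obj = object.__new__(CountTable)
    object.__setattr__(obj, "data", empty)
    return obj
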