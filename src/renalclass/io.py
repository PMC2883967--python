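"""Shared data containers and readers/writers for the pipeline's file formats.

Everything downstream operates on a small set of typed containers built on
pandas: log2 expression matrices (probes x samples) with optional two-class
labels, probe/SNP genomic annotations, SNP copy-number matrices, gene-set
collections (GMT) and 2x2 contingency tables.

Conventions:

* expression values are log2 intensities and must be finite;
* annotation positions are 1-based inclusive; BED output is 0-based half-open;
* TSV dialect is fixed: tab separator, UTF-8, ``.`` decimal, no quoting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ProbeAnnotation",
    "SnpAnnotation",
    "CnMatrix",
    "GeneSet",
    "GeneSetCollection",
    "ContingencyTable2x2",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_snp_annotation",
    "write_snp_annotation",
    "read_cn_matrix",
    "write_cn_matrix",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "write_cn_calls_bed",
]

#: Chromosomes that can be placed on the miniature/real genome.
VALID_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


def _check_unique(ids: Sequence, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Log2 expression, probes as rows, samples as columns.

    ``labels`` (optional) assigns a class label to every sample; tumor
    cohorts carry a two-level label, a normal reference cohort is stored
    as a separate unlabeled matrix.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(list(self.values.index), "probe id")
        _check_unique(list(self.values.columns), "sample id")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        if self.labels is not None:
            self.labels = pd.Series(self.labels)
            missing = [s for s in self.values.columns if s not in self.labels.index]
            if missing:
                raise ValueError(f"labels missing for samples: {missing}")
            unknown = [s for s in self.labels.index if s not in self.values.columns]
            if unknown:
                raise ValueError(f"labels reference unknown samples: {unknown}")
            self.labels = self.labels.loc[self.values.columns]

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def classes(self) -> list:
        if self.labels is None:
            return []
        return sorted(self.labels.unique())

    def subset_probes(self, probe_ids: Sequence) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(probe_ids)], self.labels)

    def samples_of(self, label) -> "ExpressionMatrix":
        if self.labels is None:
            raise ValueError("matrix carries no labels")
        cols = self.labels.index[self.labels == label]
        return ExpressionMatrix(self.values[cols], self.labels.loc[cols])


@dataclass
class ProbeAnnotation:
    """Genomic placement of probes: gene symbol, chromosome, arm, cytoband, bp.

    Rows whose chromosome is not a canonical human chromosome are retained
    but flagged ``placed == False`` and are ignored by regional analyses.
    """

    table: pd.DataFrame  # columns: probe_id, gene_symbol, chromosome, arm, cytoband, position, placed

    REQUIRED = ("probe_id", "gene_symbol", "chromosome", "arm", "cytoband", "position")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"probe annotation missing required column {col!r}")
        t = self.table.copy()
        _check_unique(list(t["probe_id"]), "probe id")
        t["chromosome"] = t["chromosome"].astype(str)
        t["position"] = t["position"].astype(int)
        if (t["position"] <= 0).any():
            bad = t.loc[t["position"] <= 0, "probe_id"].iloc[0]
            raise ValueError(f"non-positive position for probe {bad!r}")
        if "placed" not in t.columns:
            t["placed"] = t["chromosome"].isin(VALID_CHROMOSOMES)
        # arm/cytoband consistency, only where placed and both fields present
        ok = t["placed"] & t["arm"].notna() & t["cytoband"].notna()
        for _, row in t[ok].iterrows():
            if row["arm"] not in ("p", "q"):
                raise ValueError(f"invalid arm {row['arm']!r} for probe {row['probe_id']!r}")
            expected = f"{row['chromosome']}{row['arm']}"
            if not str(row["cytoband"]).startswith(expected):
                raise ValueError(
                    f"cytoband {row['cytoband']!r} inconsistent with arm {expected!r} "
                    f"for probe {row['probe_id']!r}"
                )
        self.table = t.reset_index(drop=True)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    def placed(self) -> pd.DataFrame:
        """Rows on canonical chromosomes, with an ``arm_name`` column like '1p'."""
        t = self.table[self.table["placed"]].copy()
        t["arm_name"] = t["chromosome"].astype(str) + t["arm"].astype(str)
        return t

    def arm_names(self) -> list[str]:
        return sorted(self.placed()["arm_name"].unique())


@dataclass
class SnpAnnotation:
    """SNP placement: snp_id, chromosome, position (1-based)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("snp_id", "chromosome", "position"):
            if col not in self.table.columns:
                raise ValueError(f"SNP annotation missing required column {col!r}")
        t = self.table.copy()
        _check_unique(list(t["snp_id"]), "SNP id")
        t["chromosome"] = t["chromosome"].astype(str)
        t["position"] = t["position"].astype(int)
        self.table = t.reset_index(drop=True)
        for chrom, grp in self.table.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            srt = np.sort(pos)
            if np.any(np.diff(srt) <= 0):
                raise ValueError(f"positions on chromosome {chrom} are not strictly increasing after sort")

    def is_sorted(self) -> bool:
        """True when rows follow the canonical (chromosome, position) order."""
        t = self.table
        key = list(zip(_chrom_rank(t["chromosome"]), t["position"]))
        return key == sorted(key)

    def sorted(self) -> "SnpAnnotation":
        t = self.table.copy()
        t["_rank"] = _chrom_rank(t["chromosome"])
        t = t.sort_values(["_rank", "position"], kind="mergesort").drop(columns="_rank")
        return SnpAnnotation(t.reset_index(drop=True))


def _chrom_rank(chroms: Iterable[str]) -> list[int]:
    order = {c: i for i, c in enumerate(VALID_CHROMOSOMES)}
    return [order.get(str(c), len(order)) for c in chroms]


@dataclass
class CnMatrix:
    """Per-SNP copy-number estimates (SNPs x samples) with a cohort per sample.

    Missing estimates (no-calls) are NaN and break runs in segment calling.
    """

    values: pd.DataFrame
    cohorts: pd.Series | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(list(self.values.index), "SNP id")
        _check_unique(list(self.values.columns), "sample id")
        arr = self.values.to_numpy()
        if np.any(arr[np.isfinite(arr)] < 0):
            raise ValueError("negative copy-number value")
        if self.cohorts is not None:
            self.cohorts = pd.Series(self.cohorts)
            missing = [s for s in self.values.columns if s not in self.cohorts.index]
            if missing:
                raise ValueError(f"cohort labels missing for samples: {missing}")
            self.cohorts = self.cohorts.loc[self.values.columns]

    @property
    def snp_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional acyclic parent->child relation.

    The relation supports conditional (DAG-decorrelated) enrichment testing:
    edges point from the more general term (parent) to the more specific
    child term.
    """

    sets: dict[str, GeneSet] = field(default_factory=dict)
    relations: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.relations is None:
            self.relations = []
        self.relations = [tuple(edge) for edge in self.relations]
        g = self.relation_graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("gene-set relation graph contains a cycle")

    def relation_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.sets)
        g.add_edges_from(self.relations)
        return g

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError(f"counts must be nonnegative integers, got {v!r}")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


# ---------------------------------------------------------------------------
# TSV / GMT / BED I/O
# ---------------------------------------------------------------------------

_TSV = dict(sep="\t", encoding="utf-8")


def read_expression_matrix(path, labels_path=None) -> ExpressionMatrix:
    """Read a probes-x-samples log2 TSV; header row is sample ids.

    Non-numeric cells and duplicated identifiers are hard errors. When
    ``labels_path`` is given it must be a two-column TSV (sample, label)
    covering every sample.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, **_TSV)
    _check_unique(list(df.index), "probe id")
    _check_unique(list(df.columns), "sample id")
    try:
        values = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"non-numeric expression value at probe {row!r}, sample {col!r}"
                ) from None
        raise
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, index_col=0, header=None, dtype=str, **_TSV)
        labels = lab.iloc[:, 0]
        labels.index.name = None
    return ExpressionMatrix(values, labels)


def write_expression_matrix(matrix: ExpressionMatrix, path, labels_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", encoding="utf-8")
    if labels_path is not None:
        if matrix.labels is None:
            raise ValueError("matrix carries no labels to write")
        matrix.labels.to_csv(labels_path, sep="\t", header=False, encoding="utf-8")


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, dtype={"probe_id": str, "chromosome": str}, **_TSV)
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path) -> None:
    ann.table.drop(columns=["placed"]).to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_snp_annotation(path) -> SnpAnnotation:
    df = pd.read_csv(path, dtype={"snp_id": str, "chromosome": str}, **_TSV)
    return SnpAnnotation(df)


def write_snp_annotation(ann: SnpAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_cn_matrix(path, cohorts_path=None) -> CnMatrix:
    df = pd.read_csv(path, index_col=0, **_TSV)
    cohorts = None
    if cohorts_path is not None:
        lab = pd.read_csv(cohorts_path, index_col=0, header=None, dtype=str, **_TSV)
        cohorts = lab.iloc[:, 0]
        cohorts.index.name = None
    return CnMatrix(df.astype(float), cohorts)


def write_cn_matrix(cn: CnMatrix, path, cohorts_path=None) -> None:
    cn.values.to_csv(path, sep="\t", encoding="utf-8")
    if cohorts_path is not None:
        if cn.cohorts is None:
            raise ValueError("CN matrix carries no cohorts to write")
        cn.cohorts.to_csv(cohorts_path, sep="\t", header=False, encoding="utf-8")


def read_gene_sets_gmt(path, relations_path=None) -> GeneSetCollection:
    """Read a GMT file: ``set_id <tab> description <tab> member...`` per line.

    Members are de-duplicated (first occurrence order is irrelevant: sets are
    unordered). An optional relations TSV (parent, child) attaches the DAG.
    """
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            set_id, desc, *members = fields
            if set_id in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set id {set_id!r}")
            sets[set_id] = GeneSet(set_id, desc, frozenset(m for m in members if m))
    relations: list[tuple[str, str]] = []
    if relations_path is not None:
        rel = pd.read_csv(relations_path, header=None, dtype=str, **_TSV)
        relations = [tuple(r) for r in rel.iloc[:, :2].itertuples(index=False)]
    return GeneSetCollection(sets, relations)


def write_gene_sets_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.set_id}\t{gs.description}\t{members}\n")


def write_cn_calls_bed(calls, path) -> None:
    """Write per-sample CN calls as BED: chrom, 0-based start, exclusive end.

    ``calls`` is an iterable of objects with attributes ``chromosome``,
    ``start_position``, ``end_position`` (1-based inclusive), ``kind``
    (loss|gain) and ``sample``. Output is sorted by (chromosome, start).
    """
    rows = [
        (str(c.chromosome), int(c.start_position) - 1, int(c.end_position), f"{c.sample}|{c.kind}")
        for c in calls
    ]
    rows.sort(key=lambda r: (_chrom_rank([r[0]])[0], r[1], r[2], r[3]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# chrom\tstart\tend\tname\n")
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
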