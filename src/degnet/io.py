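"""Readers, writers and core containers for the pipeline's external formats.

All tabular formats are tab-separated UTF-8 with ``#`` comment lines skipped,
matching HTSeq / BioGRID conventions. Gene symbols are uppercased at ingest so
that interactome, gene-set and annotation sources with mixed casing join
cleanly. Every filtering step (deduplicated edges, dropped self-loops,
unmapped identifiers) logs a count, so a run's accounting can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("degnet")

GROUPS = ("case", "control")
LOCUS_GROUPS = ("protein_coding", "ncRNA", "pseudogene", "other")


class FormatError(ValueError):
    """A file violated the expected dialect or an invariant of its contents."""


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Non-negative integer gene x sample count matrix with group labels.

    Parameters
    ----------
    gene_ids : ordered unique gene identifiers (rows).
    sample_ids : ordered unique sample identifiers (columns).
    counts : integer array of shape (n_genes, n_samples), all values >= 0.
    groups : mapping sample_id -> "case" or "control"; every sample must be
        labelled and each group must contain at least one sample.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                bad = np.argwhere(~np.isfinite(counts) | (counts != np.floor(counts)))[0]
                raise FormatError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            bad = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        self.counts = counts.astype(np.int64)
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise FormatError(f"samples without a group label: {missing}")
        bad_labels = {g for g in self.groups.values()} - set(GROUPS)
        if bad_labels:
            raise FormatError(f"group labels must be in {GROUPS}, got {sorted(bad_labels)}")
        for g in GROUPS:
            if not any(self.groups[s] == g for s in self.sample_ids):
                raise FormatError(f"no sample labelled {g!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([self.groups[s] == group for s in self.sample_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"sample sheet {path} needs two columns, found {list(df.columns)}")
    sample_col, group_col = df.columns[0], df.columns[1]
    _check_unique(list(df[sample_col]), "sample")
    return dict(zip(df[sample_col], df[group_col]))


def write_sample_sheet(groups: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path, sample_sheet: str | Path) -> CountMatrix:
    """Read an HTSeq-style counts TSV (first column gene ids, header = samples).

    Group labels come from the companion two-column sample sheet.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=0, index_col=0)
    groups = read_sample_sheet(sample_sheet)
    return CountMatrix(
        gene_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        counts=df.to_numpy(),
        groups={s: groups[s] for s in df.columns.astype(str) if s in groups}
        if all(s in groups for s in df.columns.astype(str))
        else _raise_missing_samples(df.columns, groups),
    )


def _raise_missing_samples(columns, groups):
    missing = [s for s in columns.astype(str) if s not in groups]
    raise FormatError(f"samples missing from sample sheet: {missing}")


def write_count_matrix(cm: CountMatrix, path: str | Path, sample_sheet: str | Path | None = None) -> None:
    cm.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")
    if sample_sheet is not None:
        write_sample_sheet({s: cm.groups[s] for s in cm.sample_ids}, sample_sheet)


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """(gene_id, symbol, locus_group) records; gene_id unique, closed locus set."""

    records: pd.DataFrame  # columns: gene_id, symbol, locus_group

    def __post_init__(self) -> None:
        df = self.records.copy()
        required = ["gene_id", "symbol", "locus_group"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"annotation table missing columns {missing}")
        df = df[required].astype(str)
        df["symbol"] = df["symbol"].str.upper()
        _check_unique(list(df["gene_id"]), "gene")
        bad = sorted(set(df["locus_group"]) - set(LOCUS_GROUPS))
        if bad:
            raise FormatError(f"locus_group values must be in {LOCUS_GROUPS}, got {bad}")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def symbol_of(self) -> dict[str, str]:
        return dict(zip(self.records["gene_id"], self.records["symbol"]))

    def locus_group_of(self) -> dict[str, str]:
        return dict(zip(self.records["gene_id"], self.records["locus_group"]))


def read_annotation(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    return AnnotationTable(df)


def write_annotation(table: AnnotationTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def intersect_annotation_universes(a: AnnotationTable, b: AnnotationTable) -> AnnotationTable:
    """Restrict to genes present in both annotation databanks.

    locus_group (and symbol) are taken from table ``a``; conflicting
    locus_group assignments are logged as warnings and ``a`` wins.
    """
    common = set(a.records["gene_id"]) & set(b.records["gene_id"])
    lg_b = b.locus_group_of()
    out = a.records[a.records["gene_id"].isin(common)].reset_index(drop=True)
    conflicts = int(sum(lg_b[g] != lg for g, lg in zip(out["gene_id"], out["locus_group"])))
    if conflicts:
        logger.warning(
            "annotation intersection: %d locus_group conflicts; first table wins", conflicts
        )
    logger.info(
        "annotation intersection: %d of %d/%d genes common to both databanks",
        len(out), len(a), len(b),
    )
    return AnnotationTable(out)


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

BIOGRID_COLS = ("Official Symbol Interactor A", "Official Symbol Interactor B")


def read_interactome(path: str | Path, dialect: str = "edge_list") -> nx.Graph:
    """Read a protein-interaction edge list into an undirected simple graph.

    dialect "edge_list": two tab-separated symbol columns, no header required.
    dialect "biogrid_tab": a header row containing the official-symbol
    interactor columns of a BioGRID tab export.

    Symbols are uppercased; self-loops and duplicate (unordered) edges are
    removed and their counts logged.
    """
    path = Path(path)
    if dialect == "edge_list":
        pairs = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"edge list line with <2 columns: {line!r}")
                pairs.append((parts[0], parts[1]))
    elif dialect == "biogrid_tab":
        df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
        missing = [c for c in BIOGRID_COLS if c not in df.columns]
        if missing:
            raise FormatError(
                f"BioGRID export missing columns {missing}; found {list(df.columns)}"
            )
        pairs = list(zip(df[BIOGRID_COLS[0]], df[BIOGRID_COLS[1]]))
    else:
        raise ValueError(f"unknown interactome dialect {dialect!r}")

    graph: nx.Graph = nx.Graph()
    n_self, n_dup = 0, 0
    for a, b in pairs:
        a, b = str(a).upper(), str(b).upper()
        if a == b:
            n_self += 1
            graph.add_node(a)
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b)
    if not pairs:
        logger.warning("interactome %s is empty", path)
    logger.info(
        "interactome %s: %d nodes, %d edges (%d self-loops and %d duplicate edges removed)",
        path.name, graph.number_of_nodes(), graph.number_of_edges(), n_self, n_dup,
    )
    return graph


def write_interactome(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: tuple[str, ...]  # uppercased, deduplicated, order of first appearance

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.term_id!r} is empty")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, term_id: str) -> GeneSet:
        for s in self.sets:
            if s.term_id == term_id:
                return s
        raise KeyError(term_id)


def make_gene_set(term_id: str, term_name: str, members: Iterable[str]) -> GeneSet:
    seen: dict[str, None] = {}
    for m in members:
        seen.setdefault(str(m).upper(), None)
    return GeneSet(term_id=term_id, term_name=term_name, members=tuple(seen))


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno} has fewer than 3 fields")
            sets.append(make_gene_set(parts[0], parts[1], parts[2:]))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.term_id, s.term_name, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ["sample_id", "group", "gene", "replicate", "ct", "is_reference"]


@dataclass
class QPCRPlate:
    """Long-format Ct measurements with a flagged reference gene.

    One row per technical replicate. Every sample must contain at least one
    reference-gene measurement, and all Ct values must be finite and > 0.
    """

    records: pd.DataFrame  # columns QPCR_COLUMNS

    def __post_init__(self) -> None:
        df = self.records.copy()
        missing = [c for c in QPCR_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"qPCR plate missing columns {missing}")
        df = df[QPCR_COLUMNS]
        df["ct"] = df["ct"].astype(float)
        df["replicate"] = df["replicate"].astype(int)
        df["is_reference"] = df["is_reference"].astype(bool)
        df["gene"] = df["gene"].astype(str).str.upper()
        if not np.all(np.isfinite(df["ct"])) or (df["ct"] <= 0).any():
            raise FormatError("Ct values must be finite and > 0")
        for sample, sub in df.groupby("sample_id"):
            if not sub["is_reference"].any():
                raise FormatError(f"sample {sample!r} has no reference-gene measurement")
        self.records = df.reset_index(drop=True)

    @property
    def reference_genes(self) -> list[str]:
        return sorted(self.records.loc[self.records["is_reference"], "gene"].unique())


def read_qpcr_plate(path: str | Path) -> QPCRPlate:
    df = pd.read_csv(path, sep="\t", comment="#", header=0)
    return QPCRPlate(df)


def write_qpcr_plate(plate: QPCRPlate, path: str | Path) -> None:
    plate.records.to_csv(path, sep="\t", index=False)
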