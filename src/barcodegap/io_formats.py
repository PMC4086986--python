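"""Readers/writers for alignments, specimen metadata tables and partitions.

Domain containers:

* :class:`AlignedSeqSet` -- named, equal-length nucleotide sequences.
* :class:`SpecimenTable` -- per-specimen metadata (morphospecies, locality,
  optional per-method cluster assignment columns).
* :class:`Partition` -- a specimen -> cluster-label map with derived cluster
  sets, the universal currency of the delimitation workflow.

Input order is canonical everywhere: matrices, Klee diagrams and partition
labels all follow the order in which specimens were first read.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    FormatError,
    IdentityError,
    InputError,
    SchemaError,
)

__all__ = [
    "AlignedSeqSet",
    "SpecimenTable",
    "Partition",
    "read_alignment",
    "write_alignment",
    "read_specimen_table",
    "partitions_from_table",
    "read_partition",
    "write_partition",
]

# IUPAC nucleotide ambiguity codes (kept verbatim in sequences; downstream
# modules decide how to treat them).
IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")
VALID_RESIDUES = set("ACGT-") | IUPAC_AMBIGUOUS


@dataclass(frozen=True)
class AlignedSeqSet:
    """An alignment: unique ordered ids and equal-length sequences."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if not self.seqs:
            raise FormatError("alignment contains no sequences")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise AlignmentError("alignment length must be >= 1")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise IdentityError(f"duplicate specimen ids: {dupes}")

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, specimen_id: str) -> str:
        try:
            return self.seqs[self.ids.index(specimen_id)]
        except ValueError:
            raise KeyError(specimen_id) from None

    def subset(self, ids: Sequence[str]) -> "AlignedSeqSet":
        index = {sid: i for i, sid in enumerate(self.ids)}
        return AlignedSeqSet(
            ids=tuple(ids), seqs=tuple(self.seqs[index[sid]] for sid in ids)
        )


def read_alignment(path: str | Path, format: str = "fasta") -> AlignedSeqSet:
    """Read an aligned FASTA file.

    Residues are upper-cased; input order is preserved. Ragged lengths raise
    :class:`AlignmentError`, duplicated ids :class:`IdentityError`, an empty
    file :class:`FormatError`.
    """
    if format != "fasta":
        raise FormatError(f"unsupported alignment format: {format!r}")
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    return AlignedSeqSet(ids=ids, seqs=seqs)


def write_alignment(aln: AlignedSeqSet, path: str | Path) -> None:
    """Write an alignment as FASTA (one record per specimen, input order)."""
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class SpecimenTable:
    """Specimen metadata indexed by specimen id.

    ``df`` is indexed by specimen id; the remaining attributes name the
    columns playing each role (``None`` when absent). ``assignment_cols``
    maps method name -> column name for per-method PSH assignments.
    """

    df: pd.DataFrame
    morpho_col: str | None = None
    locality_col: str | None = None
    genus_col: str | None = None
    region_col: str | None = None
    assignment_cols: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dupes = sorted(self.df.index[self.df.index.duplicated()].unique())
            raise IdentityError(f"duplicate specimen ids: {dupes}")
        for col in filter(None, [self.morpho_col, self.locality_col,
                                 self.genus_col, self.region_col,
                                 *self.assignment_cols.values()]):
            if col not in self.df.columns:
                raise SchemaError(f"column {col!r} not present in table")

    @property
    def specimen_ids(self) -> tuple[str, ...]:
        return tuple(self.df.index)

    def morphospecies(self) -> pd.Series:
        if self.morpho_col is None:
            raise SchemaError("no morphospecies column configured")
        return self.df[self.morpho_col]

    def localities(self) -> pd.Series:
        if self.locality_col is None:
            raise SchemaError("no locality column configured")
        return self.df[self.locality_col]

    def assignments(self, method: str) -> pd.Series:
        try:
            col = self.assignment_cols[method]
        except KeyError:
            raise SchemaError(f"unknown assignment method {method!r}") from None
        return self.df[col]


def _strip_cells(df: pd.DataFrame) -> pd.DataFrame:
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].map(
                lambda v: v.strip() if isinstance(v, str) else v
            )
            df[col] = df[col].replace("", pd.NA)
    return df


def read_specimen_table(
    path: str | Path,
    id_col: str,
    morpho_col: str | None = None,
    locality_col: str | None = None,
    assignment_cols: Mapping[str, str] | Sequence[str] | None = None,
    genus_col: str | None = None,
    region_col: str | None = None,
) -> SpecimenTable:
    """Read a specimen table from CSV/TSV or XLSX.

    Column names are passed explicitly (supplementary tables have no fixed
    naming convention). ``assignment_cols`` may be a mapping method ->
    column or a sequence of column names used as both. Whitespace is
    trimmed and empty cells become missing values.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        df = pd.read_excel(path, dtype=str)
    elif suffix in {".tsv", ".tab"}:
        df = pd.read_csv(path, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    df = _strip_cells(df)
    if id_col not in df.columns:
        raise SchemaError(f"id column {id_col!r} not present in {path.name}")
    if df[id_col].isna().any():
        raise IdentityError("table contains rows with missing specimen ids")
    df = df.set_index(id_col)
    if assignment_cols is None:
        acols: dict[str, str] = {}
    elif isinstance(assignment_cols, Mapping):
        acols = dict(assignment_cols)
    else:
        acols = {c: c for c in assignment_cols}
    return SpecimenTable(
        df=df,
        morpho_col=morpho_col,
        locality_col=locality_col,
        genus_col=genus_col,
        region_col=region_col,
        assignment_cols=acols,
    )


@dataclass(frozen=True)
class Partition:
    """A specimen -> cluster-label assignment.

    ``clusters`` derives the disjoint specimen-id sets in order of first
    appearance; labels are opaque strings.
    """

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignment:
            raise InputError("partition has no specimens")

    @property
    def specimen_ids(self) -> tuple[str, ...]:
        return tuple(self.assignment)

    @property
    def labels(self) -> tuple[str, ...]:
        """Distinct cluster labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.assignment.values():
            seen.setdefault(lab, None)
        return tuple(seen)

    @property
    def clusters(self) -> tuple[frozenset[str], ...]:
        groups: dict[str, list[str]] = {}
        for sid, lab in self.assignment.items():
            groups.setdefault(lab, []).append(sid)
        return tuple(frozenset(groups[lab]) for lab in self.labels)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, label: str) -> frozenset[str]:
        found = frozenset(
            s for s, lab in self.assignment.items() if lab == label
        )
        if not found:
            raise KeyError(label)
        return found

    def cluster_sets(self) -> frozenset[frozenset[str]]:
        return frozenset(self.clusters)

    def restrict(self, ids: Iterable[str]) -> "Partition":
        keep = set(ids)
        return Partition({s: l for s, l in self.assignment.items() if s in keep})

    @classmethod
    def from_clusters(
        cls, clusters: Sequence[Iterable[str]], prefix: str = "psh"
    ) -> "Partition":
        assignment: dict[str, str] = {}
        for k, members in enumerate(clusters, start=1):
            for sid in members:
                assignment[sid] = f"{prefix}_{k:03d}"
        return cls(assignment)

    def refines(self, other: "Partition") -> bool:
        """True if every cluster of self sits inside one cluster of other."""
        for cluster in self.clusters:
            labels = {other.assignment.get(s) for s in cluster}
            if len(labels) > 1:
                return False
        return True


def partitions_from_table(
    table: SpecimenTable, method_names: Sequence[str]
) -> dict[str, Partition]:
    """Build one :class:`Partition` per named assignment method.

    Specimens with a missing label for a method are excluded from that
    method's partition (their ids are available via the table).
    """
    out: dict[str, Partition] = {}
    for method in method_names:
        series = table.assignments(method)
        labelled = series.dropna()
        if labelled.empty:
            raise SchemaError(f"method {method!r} has no labelled specimens")
        out[method] = Partition(dict(labelled.astype(str)))
    return out


def write_partition(partition: Partition, path: str | Path) -> None:
    """Write a partition as two-column headered CSV (specimen_id, cluster)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["specimen_id", "cluster_label"])
        for sid, lab in partition.assignment.items():
            writer.writerow([sid, lab])


def read_partition(path: str | Path) -> Partition:
    """Read a two-column partition CSV written by :func:`write_partition`."""
    assignment: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or {
            "specimen_id",
            "cluster_label",
        } - set(reader.fieldnames):
            raise SchemaError(
                "partition CSV must have columns specimen_id, cluster_label"
            )
        for row in reader:
            sid = row["specimen_id"]
            if sid in assignment:
                raise IdentityError(f"duplicate specimen id: {sid}")
            assignment[sid] = row["cluster_label"]
    if not assignment:
        raise FormatError(f"no partition rows in {path}")
    return Partition(assignment)
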