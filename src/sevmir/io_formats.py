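"""Readers and writers for every external format the pipeline touches.

All downstream modules consume the validated in-memory objects defined here:
count matrices with sample metadata, mature miRNA sequence sets, interaction
edge lists, cell-type marker tables, gene-set (GMT) collections and patient
clinical tables.  TSV is the canonical tabular dialect throughout; comma
dialects are rejected, not guessed.  Sequences are stored in the RNA alphabet
(``U``); ``T`` is converted on read so that all motif matching downstream is
U-convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

CONDITIONS = ("cell", "sev")
RNA_ALPHABET = frozenset("ACGU")
_STAGE_T = {"T1", "T2", "T3", "T4"}
_STAGE_N = {"N0", "N1", "N2", "N3"}


class FormatError(ValueError):
    """A file violated the format contract or a domain-type invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """miRNA x sample non-negative integer counts with sample annotations.

    Parameters
    ----------
    counts
        DataFrame indexed by miRNA id with one column per sample id;
        values are non-negative integers.
    sample_meta
        DataFrame indexed by sample id with columns ``condition``
        (one of ``cell``/``sev``) and ``cell_line`` (free text).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate miRNA id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            raise FormatError("counts contain non-finite values")
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at miRNA {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if not np.array_equal(values, np.floor(values)):
            g, s = np.argwhere(values != np.floor(values))[0]
            raise FormatError(
                f"non-integer count at miRNA {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "mirna_id"
        self.counts.columns.name = None
        missing = self.counts.columns.difference(self.sample_meta.index)
        if len(missing):
            raise FormatError(f"samples missing from metadata: {sorted(missing)}")
        self.sample_meta = self.sample_meta.loc[self.counts.columns]
        self.sample_meta.index.name = "sample_id"
        bad = set(self.sample_meta["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown condition labels: {sorted(bad)}")

    @property
    def mirna_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def condition_mask(self, condition: str) -> np.ndarray:
        """Boolean mask over samples for one condition label."""
        if condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        return (self.sample_meta["condition"] == condition).to_numpy()


@dataclass
class SequenceSet:
    """Mature miRNA sequences over the RNA alphabet {A, C, G, U}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for mirna_id, seq in self.sequences.items():
            if not mirna_id:
                raise FormatError("empty miRNA id in sequence set")
            if not seq:
                raise FormatError(f"empty sequence for {mirna_id!r}")
            for pos, base in enumerate(seq, start=1):
                if base not in RNA_ALPHABET:
                    raise FormatError(
                        f"invalid base {base!r} at position {pos} in {mirna_id!r}"
                    )

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, mirna_id: str) -> str:
        return self.sequences[mirna_id]

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self.sequences

    def items(self):
        return self.sequences.items()

    def ids(self) -> list[str]:
        return list(self.sequences)


@dataclass
class InteractionTable:
    """Deduplicated (source, target) edge list of one interaction kind."""

    edges: pd.DataFrame  # columns: source, target
    kind: str  # "mirna-rbp" or "mirna-mrna"

    def __post_init__(self) -> None:
        if self.kind not in ("mirna-rbp", "mirna-mrna"):
            raise FormatError(f"unknown interaction kind: {self.kind!r}")
        if list(self.edges.columns) != ["source", "target"]:
            self.edges = self.edges.rename(
                columns=dict(zip(self.edges.columns, ["source", "target"]))
            )
        if (self.edges["source"].astype(str).str.len() == 0).any() or (
            self.edges["target"].astype(str).str.len() == 0
        ).any():
            raise FormatError("empty id in interaction table")
        self.edges = self.edges.drop_duplicates(ignore_index=True)

    def __len__(self) -> int:
        return len(self.edges)

    def targets_of(self, source_id: str) -> set[str]:
        sel = self.edges["source"] == source_id
        return set(self.edges.loc[sel, "target"])


@dataclass
class MarkerTable:
    """Cell-type label -> non-empty set of marker gene identifiers."""

    markers: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean = {}
        for cell_type, genes in self.markers.items():
            genes = frozenset(genes)
            if not genes:
                raise FormatError(f"empty marker set for cell type {cell_type!r}")
            clean[cell_type] = genes
        self.markers = clean

    def items(self):
        return self.markers.items()

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class ClinicalTable:
    """Per-patient expression, stages and survival outcome.

    ``data`` is indexed by patient id with columns ``time`` (days, > 0),
    ``event`` (0/1), optional stages ``pT``/``pN``/``cN`` (strings or NA;
    missing stages are first-class and never imputed), and one column per
    quantified miRNA (normalized expression).
    """

    data: pd.DataFrame
    expression_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate patient id: {dup!r}")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise FormatError(f"clinical table missing required column {col!r}")
        bad_time = self.data.index[~(self.data["time"] > 0)]
        if len(bad_time):
            raise FormatError(f"non-positive survival time for patient {bad_time[0]!r}")
        bad_event = self.data.index[~self.data["event"].isin([0, 1])]
        if len(bad_event):
            raise FormatError(f"event not in {{0,1}} for patient {bad_event[0]!r}")
        for col, allowed in (("pT", _STAGE_T), ("pN", _STAGE_N), ("cN", _STAGE_N)):
            if col in self.data.columns:
                observed = set(self.data[col].dropna()) - allowed
                if observed:
                    raise FormatError(f"unknown {col} stage labels: {sorted(observed)}")
        known = {"time", "event", "pT", "pN", "cN"}
        if not self.expression_columns:
            self.expression_columns = [c for c in self.data.columns if c not in known]

    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index

    @property
    def expression(self) -> pd.DataFrame:
        return self.data[self.expression_columns]


# ---------------------------------------------------------------------------
# Count matrix I/O
# ---------------------------------------------------------------------------


def read_count_matrix(path, meta_path) -> CountMatrix:
    """Read a miRNA x sample count TSV plus a sample-metadata TSV.

    The count file has a header row of sample ids and miRNA ids in the
    first column.  The metadata file maps ``sample_id`` to ``condition``
    and ``cell_line``.  Row and column order are preserved from the files.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    non_numeric = counts.columns[
        [not pd.api.types.is_numeric_dtype(counts[c]) for c in counts.columns]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        bad = counts[col][pd.to_numeric(counts[col], errors="coerce").isna()]
        raise FormatError(
            f"non-numeric count in column {col!r}"
            + (f" at miRNA {bad.index[0]!r}" if len(bad) else "")
        )
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    for col in ("condition", "cell_line"):
        if col not in meta.columns:
            raise FormatError(f"metadata missing required column {col!r}")
    return CountMatrix(counts=counts, sample_meta=meta)


def write_count_matrix(cm: CountMatrix, path, meta_path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="mirna_id")
    cm.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_sequences_fasta(path) -> SequenceSet:
    """Read mature miRNA sequences; uppercase and convert T to U.

    The FASTA header token up to the first whitespace is the miRNA id.
    Characters outside {A, C, G, U, T} (any case) are rejected with the
    1-based position of the first offender.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate sequence id: {record.id!r}")
        raw = str(record.seq).upper()
        for pos, base in enumerate(raw, start=1):
            if base not in "ACGUT":
                raise FormatError(
                    f"invalid base {base!r} at position {pos} in {record.id!r}"
                )
        sequences[record.id] = raw.replace("T", "U")
    return SequenceSet(sequences)


def write_sequences_fasta(seqs: SequenceSet, path) -> None:
    with open(path, "w") as handle:
        for mirna_id, seq in seqs.items():
            handle.write(f">{mirna_id}\n{seq}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    collection: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"GMT line {lineno}: empty member list")
            if name in collection:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            collection[name] = set(members)
    return collection


def write_gmt(collection: Mapping[str, set[str]], path, descriptions=None) -> None:
    """Write a gene-set collection in the GMT dialect read by :func:`read_gmt`."""
    with open(path, "w") as handle:
        for name, members in collection.items():
            if not members:
                raise FormatError(f"refusing to write empty set {name!r}")
            desc = descriptions.get(name, "na") if descriptions else "na"
            handle.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Interaction tables
# ---------------------------------------------------------------------------


def read_interaction_table(path, kind: str) -> InteractionTable:
    """Read a two-column (source, target) TSV edge list; duplicates dropped.

    A header line is recognised when its first field is one of the common
    schema names (``source``/``mirna``/``miRNA``); otherwise the first line
    is data.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"interaction line {lineno}: fewer than 2 columns")
            src, tgt = fields[0], fields[1]
            if lineno == 1 and src.lower() in {"source", "mirna", "mirna_id", "cell_type"}:
                continue
            if not src or not tgt:
                raise FormatError(f"interaction line {lineno}: empty field")
            rows.append((src, tgt))
    if not rows:
        logger.warning("interaction table %s is empty", path)
    edges = pd.DataFrame(rows, columns=["source", "target"])
    return InteractionTable(edges=edges, kind=kind)


def write_interaction_table(table: InteractionTable, path) -> None:
    table.edges.to_csv(path, sep="\t", index=False)


def write_sif(edges: pd.DataFrame, path, relation: str = "targets") -> None:
    """Write a SIF-style three-column edge list (source, relation, target)."""
    with open(path, "w") as handle:
        for _, row in edges.iterrows():
            handle.write(f"{row['source']}\t{relation}\t{row['target']}\n")


# ---------------------------------------------------------------------------
# Marker tables
# ---------------------------------------------------------------------------


def read_marker_table(path) -> MarkerTable:
    """Read a two-column TSV mapping cell_type -> marker gene (one per row)."""
    table = read_interaction_table(path, kind="mirna-mrna")  # reuse 2-col contract
    markers: dict[str, set[str]] = {}
    for _, row in table.edges.iterrows():
        markers.setdefault(row["source"], set()).add(row["target"])
    return MarkerTable({k: frozenset(v) for k, v in markers.items()})


def write_marker_table(markers: MarkerTable, path) -> None:
    with open(path, "w") as handle:
        handle.write("cell_type\tgene\n")
        for cell_type, genes in markers.items():
            for gene in sorted(genes):
                handle.write(f"{cell_type}\t{gene}\n")


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------


def read_clinical_table(path) -> ClinicalTable:
    """Read a patient TSV with required ``patient_id``, ``time``, ``event``.

    Optional columns: ``pT``/``pN``/``cN`` stages (missing values kept as
    missing) and any number of miRNA expression columns.
    """
    data = pd.read_csv(path, sep="\t", index_col="patient_id")
    data.index = data.index.astype(str)
    return ClinicalTable(data=data)


def write_clinical_table(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="patient_id")
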