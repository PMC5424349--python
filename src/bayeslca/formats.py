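"""Readers and writers for the classifier's external file formats.

Covered formats:

* FASTA query / reference sequences (via Biopython),
* BLAST-style tabular hit files — the standard 12-column tabular layout
  (``qseqid sseqid pident length mismatch gapopen qstart qend sstart send
  evalue bitscore``) plus a mandatory 13th ``qlen`` column, as produced by
  ``blastn -outfmt '6 std qlen'``,
* a two-column ``sequence id -> taxid`` mapping,
* the per-query classification result table (TSV; one row per query, each
  canonical rank emitted as ``rank:name:confidence`` or
  ``rank:unclassified``).

Coordinates in hit rows are kept 1-based inclusive throughout (the tabular
convention); conversion to Python slices happens in exactly one place, in
:mod:`bayeslca.alignment`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import CANONICAL_RANKS, load_lineage_tsv, load_taxonomy  # re-exported

__all__ = [
    "QueryRecord",
    "ReferenceRecord",
    "HitRow",
    "RankAssignment",
    "ResultRow",
    "FormatError",
    "DuplicateIdError",
    "UNCLASSIFIED",
    "read_fasta",
    "write_fasta",
    "read_reference_fasta",
    "read_taxid_map",
    "parse_hit_table",
    "group_hits_by_query",
    "write_results",
    "read_results",
    "load_taxonomy",
    "load_lineage_tsv",
]

UNCLASSIFIED = "unclassified"

_DNA = set("ACGTN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class DuplicateIdError(FormatError):
    """Two records in one input share an identifier."""


@dataclass(frozen=True)
class QueryRecord:
    """One query sequence: an OTU representative or a single read."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("query record with empty id")
        if not self.seq:
            raise FormatError(f"query {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference sequence with its taxon annotation."""

    id: str
    seq: str
    taxid: str

    def __post_init__(self):
        if not self.seq:
            raise FormatError(f"reference {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class HitRow:
    """One row of the tabular hit file (1-based inclusive coordinates).

    ``sstart > send`` encodes a minus-strand subject match.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int

    def __post_init__(self):
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise FormatError(
                f"hit {self.query_id!r}/{self.subject_id!r}: query coordinates "
                f"{self.qstart}..{self.qend} violate 1 <= qstart <= qend <= qlen={self.qlen}"
            )
        span = max(self.qend - self.qstart + 1, abs(self.send - self.sstart) + 1)
        if self.align_len < span:
            raise FormatError(
                f"hit {self.query_id!r}/{self.subject_id!r}: align_len {self.align_len} "
                f"shorter than aligned span {span}"
            )
        if not math.isfinite(self.bitscore):
            raise FormatError(
                f"hit {self.query_id!r}/{self.subject_id!r}: non-finite bitscore"
            )

    @property
    def coverage(self) -> float:
        """Percent of the query length spanned by the hit's aligned region."""
        return 100.0 * (self.qend - self.qstart + 1) / self.qlen


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _normalize_seq(raw: str, record_id: str, on_invalid: str) -> str:
    seq = raw.upper()
    bad = set(seq) - _DNA
    if bad:
        if on_invalid == "mask":
            seq = "".join(c if c in _DNA else "N" for c in seq)
        else:
            raise FormatError(
                f"record {record_id!r} contains non-DNA characters {sorted(bad)!r} "
                "(pass on_invalid='mask' to map them to N)"
            )
    return seq


def read_fasta(path: str | Path, on_invalid: str = "error") -> list[QueryRecord]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    Sequences are upper-cased; characters outside ``{A,C,G,T,N}`` either
    raise (default) or are masked to ``N`` (``on_invalid="mask"``).
    """
    if on_invalid not in ("error", "mask"):
        raise ValueError("on_invalid must be 'error' or 'mask'")
    records: list[QueryRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise FormatError(f"{path}: record #{i + 1} has an empty header")
        if rec.id in seen:
            raise DuplicateIdError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = _normalize_seq(str(rec.seq), rec.id, on_invalid)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(QueryRecord(id=rec.id, seq=seq, description=desc))
    return records


def write_fasta(records: Iterable[QueryRecord | ReferenceRecord], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description=getattr(r, "description", ""))
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_taxid_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``sequence_id<TAB>taxid``."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'seqid<TAB>taxid'")
            if parts[0] in mapping:
                raise DuplicateIdError(f"{path}:{lineno}: duplicate seqid {parts[0]!r}")
            mapping[parts[0]] = parts[1]
    return mapping


def read_reference_fasta(
    fasta_path: str | Path,
    taxid_map: Mapping[str, str] | str | Path,
    on_invalid: str = "error",
) -> list[ReferenceRecord]:
    """Read reference sequences and attach taxids from a mapping (file or dict)."""
    if not isinstance(taxid_map, Mapping):
        taxid_map = read_taxid_map(taxid_map)
    refs = []
    for rec in read_fasta(fasta_path, on_invalid=on_invalid):
        try:
            taxid = taxid_map[rec.id]
        except KeyError:
            raise FormatError(
                f"reference {rec.id!r} has no entry in the seqid->taxid mapping"
            ) from None
        refs.append(ReferenceRecord(id=rec.id, seq=rec.seq, taxid=taxid))
    return refs


# ---------------------------------------------------------------------------
# Tabular hit files
# ---------------------------------------------------------------------------

HIT_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen",
)

_INT_COLS = ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send", "qlen")
_FLOAT_COLS = ("pident", "evalue", "bitscore")


def parse_hit_table(path: str | Path) -> list[HitRow]:
    """Parse a tabular hit file (12 standard columns + ``qlen``).

    Input row order is preserved — downstream tie-breaking depends on it.
    An empty file yields an empty list.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] == len(HIT_COLUMNS) - 1:
        raise FormatError(
            f"{path}: found 12 columns but the 13-column dialect is required; "
            "regenerate the table with -outfmt '6 std qlen'"
        )
    if df.shape[1] != len(HIT_COLUMNS):
        raise FormatError(
            f"{path}: expected {len(HIT_COLUMNS)} tab-separated columns, "
            f"found {df.shape[1]}"
        )
    df.columns = list(HIT_COLUMNS)
    for col in _INT_COLS + _FLOAT_COLS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise FormatError(
                f"{path}: row {row}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r}"
            )
        df[col] = converted
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            HitRow(
                query_id=rec.qseqid,
                subject_id=rec.sseqid,
                pct_identity=float(rec.pident),
                align_len=int(rec.length),
                mismatch=int(rec.mismatch),
                gapopen=int(rec.gapopen),
                qstart=int(rec.qstart),
                qend=int(rec.qend),
                sstart=int(rec.sstart),
                send=int(rec.send),
                evalue=float(rec.evalue),
                bitscore=float(rec.bitscore),
                qlen=int(rec.qlen),
            )
        )
    return rows


def group_hits_by_query(hits: Iterable[HitRow]) -> dict[str, list[HitRow]]:
    """Group hit rows by query id, preserving within-query input order."""
    grouped: dict[str, list[HitRow]] = {}
    for hit in hits:
        grouped.setdefault(hit.query_id, []).append(hit)
    return grouped


# ---------------------------------------------------------------------------
# Result table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankAssignment:
    rank: str
    name: str  # taxon name, or UNCLASSIFIED
    confidence: float | None  # None iff name == UNCLASSIFIED

    def __post_init__(self):
        if (self.name == UNCLASSIFIED) != (self.confidence is None):
            raise ValueError(
                "confidence must be present exactly when a taxon is assigned"
            )


@dataclass(frozen=True)
class ResultRow:
    """Per-query classification: one assignment per canonical rank, root-first."""

    query_id: str
    assignments: tuple[RankAssignment, ...]

    def as_dict(self) -> dict[str, str]:
        """Rank -> assigned name (or ``unclassified``)."""
        return {a.rank: a.name for a in self.assignments}


def _format_assignment(a: RankAssignment) -> str:
    if a.name == UNCLASSIFIED:
        return f"{a.rank}:{UNCLASSIFIED}"
    if ":" in a.name or ";" in a.name:
        raise FormatError(f"taxon name {a.name!r} contains a reserved character")
    return f"{a.rank}:{a.name}:{a.confidence!r}"


def write_results(rows: Sequence[ResultRow], path: str | Path) -> None:
    """Write the classification table: ``query_id<TAB>rank:name:conf;...``."""
    with open(path, "w") as fh:
        fh.write("#query_id\tclassification\n")
        for row in rows:
            fields = ";".join(_format_assignment(a) for a in row.assignments)
            fh.write(f"{row.query_id}\t{fields}\n")


def read_results(path: str | Path) -> list[ResultRow]:
    """Parse a table written by :func:`write_results` (exact round trip)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                query_id, fields = line.split("\t")
            except ValueError:
                raise FormatError(f"{path}:{lineno}: expected two columns") from None
            assignments = []
            for item in fields.split(";"):
                parts = item.split(":")
                if len(parts) == 2 and parts[1] == UNCLASSIFIED:
                    assignments.append(RankAssignment(parts[0], UNCLASSIFIED, None))
                elif len(parts) == 3:
                    assignments.append(
                        RankAssignment(parts[0], parts[1], float(parts[2]))
                    )
                else:
                    raise FormatError(f"{path}:{lineno}: malformed field {item!r}")
            rows.append(ResultRow(query_id=query_id, assignments=tuple(assignments)))
    return rows
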