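"""Sequence containers and I/O for FASTA, BLAST-tabular hits, and design reports.

All coordinates handled by this package are 0-based half-open.  BLAST
tabular files use 1-based inclusive coordinates; they are converted once,
at import time, and never leak further in.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Sequence",
    "Transcriptome",
    "HomologyHit",
    "FastaError",
    "BlastTabError",
    "read_fasta",
    "write_fasta",
    "import_blast_tab",
    "write_report",
    "load_report",
    "write_hits_tsv",
    "write_risk_tsv",
]

_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaError(ValueError):
    """Raised for malformed or inconsistent FASTA input."""


class BlastTabError(ValueError):
    """Raised for malformed BLAST tabular (outfmt-6 style) input."""


def revcomp(residues: str) -> str:
    """Reverse complement of a normalized nucleotide string."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Sequence:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}.

    Residues are normalized on construction: upper-cased with U mapped
    to T.  Any other character raises :class:`FastaError` naming its
    0-based position.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence id must be non-empty")
        if not self.residues:
            raise FastaError(f"sequence {self.id!r} has no residues")
        normalized = self.residues.upper().replace("U", "T")
        for pos, ch in enumerate(normalized):
            if ch not in _ALPHABET:
                raise FastaError(
                    f"sequence {self.id!r}: invalid residue {ch!r} at position {pos}"
                )
        object.__setattr__(self, "residues", normalized)

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "Sequence":
        return Sequence(self.id, revcomp(self.residues))


@dataclass
class Transcriptome:
    """A keyed collection of sequences, with some ids designated as the design target.

    ``target_ids`` may include ids absent from ``entries`` (an external
    target sequence screened against this database); ids present in the
    collection are excluded from off-target scanning as self-hits.
    """

    entries: dict[str, Sequence] = field(default_factory=dict)
    target_ids: set[str] = field(default_factory=set)

    def add(self, seq: Sequence) -> None:
        if seq.id in self.entries:
            raise FastaError(f"duplicate sequence id {seq.id!r}")
        self.entries[seq.id] = seq

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.entries.values())

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.entries

    def __getitem__(self, seq_id: str) -> Sequence:
        return self.entries[seq_id]

    def non_target_entries(self) -> Iterator[Sequence]:
        for seq in self.entries.values():
            if seq.id not in self.target_ids:
                yield seq


@dataclass(frozen=True)
class HomologyHit:
    """One approximate match of a query against a subject sequence.

    Coordinates are 0-based half-open with ``start < end`` on both axes;
    ``strand`` records the orientation of the subject match.  ``gap_count``
    is the total number of gapped alignment columns.  Twelve-column BLAST
    tabular input only carries gap *openings*; on import the total is
    recomputed from the span arithmetic and ``gap_unverifiable`` is set
    when the two disagree.
    """

    query_id: str
    subject_id: str
    identity_pct: float
    aligned_len: int
    gap_count: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str = "+"
    e_value: Optional[float] = None
    bit_score: Optional[float] = None
    gap_unverifiable: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity_pct out of range: {self.identity_pct}")
        if self.aligned_len < 1:
            raise ValueError(f"aligned_len must be >= 1, got {self.aligned_len}")
        if self.gap_count < 0:
            raise ValueError("gap_count must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for lo, hi, axis in (
            (self.query_start, self.query_end, "query"),
            (self.subject_start, self.subject_end, "subject"),
        ):
            if lo < 0 or hi <= lo:
                raise ValueError(f"bad {axis} span [{lo}, {hi})")
        if self.e_value is not None and self.e_value < 0:
            raise ValueError("e_value must be positive")


def read_fasta(path, target_ids: Iterable[str] = ()) -> Transcriptome:
    """Read a multi-record FASTA file into a :class:`Transcriptome`.

    Record ids are the header up to the first whitespace.  Residues are
    normalized (upper case, U -> T); an empty file, a duplicate id, or a
    residue outside {A, C, G, T, N, U} is an error.
    """
    path = Path(path)
    tx = Transcriptome(target_ids=set(target_ids))
    n = 0
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            n += 1
            try:
                tx.add(Sequence(record.id, str(record.seq)))
            except FastaError as exc:
                raise FastaError(f"{path}: {exc}") from None
    if n == 0:
        raise FastaError(f"{path}: no FASTA records found")
    return tx


def write_fasta(sequences: Iterable[Sequence], path, width: int = 70) -> None:
    """Write sequences to ``path`` in wrapped multi-FASTA format."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


_BLAST_COLUMNS = 12


def import_blast_tab(path) -> list[HomologyHit]:
    """Parse BLAST tabular output (``-outfmt 6``: qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore).

    Subject strand is inferred from the subject coordinate order; all
    coordinates are converted to 0-based half-open.  Lines starting with
    ``#`` are skipped.
    """
    path = Path(path)
    hits: list[HomologyHit] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != _BLAST_COLUMNS:
                raise BlastTabError(
                    f"{path}:{lineno}: expected {_BLAST_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                gapopen = int(fields[5])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise BlastTabError(f"{path}:{lineno}: non-numeric field: {exc}")
            strand = "+" if sstart <= send else "-"
            s_lo, s_hi = min(sstart, send), max(sstart, send)
            q_lo, q_hi = min(qstart, qend), max(qstart, qend)
            q_span = q_hi - q_lo + 1
            s_span = s_hi - s_lo + 1
            # total gap columns are recoverable from the span arithmetic:
            # columns not consuming a query base plus columns not consuming
            # a subject base.
            gap_total = (length - q_span) + (length - s_span)
            gap_total = max(gap_total, 0)
            hits.append(
                HomologyHit(
                    query_id=qseqid,
                    subject_id=sseqid,
                    identity_pct=pident,
                    aligned_len=length,
                    gap_count=max(gap_total, gapopen),
                    query_start=q_lo - 1,
                    query_end=q_hi,
                    subject_start=s_lo - 1,
                    subject_end=s_hi,
                    strand=strand,
                    e_value=evalue,
                    bit_score=bitscore,
                    gap_unverifiable=(gap_total != gapopen),
                )
            )
    return hits


def write_report(result, path, risk_tsv_path=None) -> None:
    """Write a design result as JSON (and optionally its per-fragment risk TSV).

    ``result`` must provide ``to_dict()``; the JSON round-trips through
    :func:`load_report` to an equal dictionary.  Coordinates in the report
    are 0-based half-open (recorded in the report itself).
    """
    payload = result.to_dict()
    path = Path(path)
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")
    if risk_tsv_path is not None:
        write_risk_tsv(result.risk_profile, risk_tsv_path)


def load_report(path) -> dict:
    with open(path) as handle:
        return json.load(handle)


def write_risk_tsv(profile, path) -> None:
    """Write one row per fragment of a risk profile.

    Columns: fragment_index, start, end (0-based half-open), hit_count,
    flagged, subjects (comma-joined).
    """
    with open(path, "w", newline="") as handle:
        handle.write("# coordinates are 0-based half-open\n")
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["fragment_index", "start", "end", "hit_count", "flagged", "subjects"]
        )
        for i, (start, count, subjects) in enumerate(
            zip(profile.fragment_starts, profile.counts, profile.subjects)
        ):
            writer.writerow(
                [
                    i,
                    start,
                    start + profile.k,
                    count,
                    int(count > 0),
                    ",".join(sorted(subjects)),
                ]
            )


def write_hits_tsv(hits, path) -> None:
    """Write accepted off-target hits as TSV (0-based half-open spans)."""
    with open(path, "w", newline="") as handle:
        handle.write("# coordinates are 0-based half-open\n")
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "fragment_start",
                "subject_id",
                "subject_start",
                "subject_end",
                "strand",
                "aligned_len",
                "identity_pct",
                "gap_count",
            ]
        )
        for h in hits:
            writer.writerow(
                [
                    h.fragment_start,
                    h.subject_id,
                    h.subject_start,
                    h.subject_end,
                    h.strand,
                    h.aligned_len,
                    f"{h.identity_pct:.3f}",
                    h.gap_count,
                ]
            )
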