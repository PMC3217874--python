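"""Sequence and TM-annotation I/O.

Sequences travel as FASTA (via biopython); TM segments as a tab-separated
table with columns ``protein_id, start, end[, category]`` using 1-based
inclusive coordinates (the UniProt feature convention).  A minimal parser
for UniProt flat-file ``FT TRANSMEM`` lines is provided for convenience.
Per-segment results are written as a TSV report with two-decimal numeric
formatting, ordered by protein id then start.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .measures import TMSegment

__all__ = [
    "ProteinRecord",
    "TMReportRow",
    "read_fasta",
    "write_fasta",
    "read_tm_table",
    "write_tm_table",
    "read_ft_transmem",
    "categorize_anchor",
    "dedup_exact",
    "write_report",
]

N_TERMINAL_LIMIT = 100  # residues; anchors starting at or before this are N-terminal


@dataclass
class ProteinRecord:
    """A protein sequence plus its annotated TM segments."""

    protein_id: str
    sequence: str
    description: str = ""
    segments: list[TMSegment] = field(default_factory=list)

    def add_segment(self, start: int, end: int, category: str | None = None) -> TMSegment:
        """Attach a segment given 1-based inclusive coordinates."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(
                f"{self.protein_id}: segment {start}..{end} outside sequence "
                f"of length {len(self.sequence)}"
            )
        seg = TMSegment(
            protein_id=self.protein_id,
            start=start,
            end=end,
            sequence=self.sequence[start - 1 : end],
            category=category,
        )
        for other in self.segments:
            if seg.start <= other.end and other.start <= seg.end:
                warnings.warn(
                    f"{self.protein_id}: segment {start}..{end} overlaps "
                    f"{other.start}..{other.end}",
                    stacklevel=2,
                )
        self.segments.append(seg)
        return seg


@dataclass(frozen=True)
class TMReportRow:
    protein_id: str
    start: int
    end: int
    x_c: float
    x_phi: float
    z: float
    tm_class: str
    category: str | None = None


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read FASTA; ids are the first whitespace token, sequences upper-cased.

    Duplicate ids are rejected: the annotation join would be ambiguous.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                protein_id=rec.id,
                sequence=str(rec.seq).upper(),
                description=rec.description,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                sequences: dict[str, str] | None = None) -> None:
    """Write records to FASTA; ``sequences`` overrides per-id (masked output)."""
    out = []
    for r in records:
        seq = sequences.get(r.protein_id, r.sequence) if sequences else r.sequence
        out.append(SeqRecord(Seq(seq), id=r.protein_id, description=""))
    SeqIO.write(out, str(path), "fasta")


def read_tm_table(path: str | Path, records: Sequence[ProteinRecord]) -> None:
    """Attach TSV-annotated segments to their ProteinRecords in place.

    Columns: protein_id, start, end and an optional category; a header line
    whose second field is not an integer is skipped.
    """
    by_id = {r.protein_id: r for r in records}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.rstrip("\r\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: row {lineno}: expected >= 3 columns")
        pid, start_s, end_s = fields[0].strip(), fields[1].strip(), fields[2].strip()
        if lineno == 1 and not start_s.lstrip("-").isdigit():
            continue  # header
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"{path}: row {lineno}: non-integer coordinates") from exc
        if pid not in by_id:
            raise ValueError(f"{path}: row {lineno}: unknown protein {pid!r}")
        category = fields[3].strip() or None if len(fields) > 3 else None
        try:
            by_id[pid].add_segment(start, end, category)
        except ValueError as exc:
            raise ValueError(f"{path}: row {lineno}: {exc}") from exc


def write_tm_table(records: Iterable[ProteinRecord], path: str | Path) -> None:
    lines = ["protein_id\tstart\tend\tcategory"]
    for r in records:
        for s in sorted(r.segments, key=lambda s: s.start):
            lines.append(f"{r.protein_id}\t{s.start}\t{s.end}\t{s.category or ''}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_FT_ID = re.compile(r"^ID\s+(\S+)")
_FT_OLD = re.compile(r"^FT\s+TRANSMEM\s+(\d+)\s+(\d+)(?:\s+(.*))?$")
_FT_NEW = re.compile(r"^FT\s+TRANSMEM\s+(\d+)\.\.(\d+)\s*$")
_FT_NOTE = re.compile(r'^FT\s+/note="([^"]*)"')


def read_ft_transmem(path: str | Path, records: Sequence[ProteinRecord]) -> None:
    """Attach segments from a UniProt flat-file subset (ID + FT TRANSMEM lines).

    Both the legacy two-column coordinate layout and the modern ``start..end``
    layout are accepted; a following ``/note="..."`` line (or trailing
    description) supplies the category label.
    """
    by_id = {r.protein_id: r for r in records}
    current: ProteinRecord | None = None
    pending: tuple[int, int] | None = None

    def flush(category: str | None) -> None:
        nonlocal pending
        if current is not None and pending is not None:
            current.add_segment(pending[0], pending[1], category)
        pending = None

    for line in Path(path).read_text(encoding="utf-8").splitlines():
        m = _FT_ID.match(line)
        if m:
            flush(None)
            pid = m.group(1)
            if pid not in by_id:
                raise ValueError(f"{path}: flat file names unknown protein {pid!r}")
            current = by_id[pid]
            continue
        m = _FT_NOTE.match(line)
        if m:
            flush(m.group(1) or None)
            continue
        m = _FT_OLD.match(line)
        if m:
            flush(None)
            cat = (m.group(3) or "").strip().rstrip(".") or None
            if cat:
                if current is None:
                    raise ValueError(f"{path}: FT TRANSMEM before any ID line")
                current.add_segment(int(m.group(1)), int(m.group(2)), cat)
            else:
                pending = (int(m.group(1)), int(m.group(2)))
            continue
        m = _FT_NEW.match(line)
        if m:
            flush(None)
            pending = (int(m.group(1)), int(m.group(2)))
    flush(None)


def categorize_anchor(
    record: ProteinRecord, segment: TMSegment, keyword: str
) -> tuple[str, bool]:
    """Label a single-TM protein's anchor and flag N-terminal location.

    The anchor is N-terminal when it starts within the first 100 residues of
    the full-length sequence (where a signal peptide would sit); otherwise it
    is C-terminally located.  Categories are taken as given labels, never
    inferred.  A multi-TM record triggers a warning, since anchor categories
    are defined for single-spanning proteins.
    """
    if len(record.segments) > 1:
        warnings.warn(
            f"{record.protein_id}: anchor category on a protein with "
            f"{len(record.segments)} TM segments",
            stacklevel=2,
        )
    return keyword, segment.start <= N_TERMINAL_LIMIT


def dedup_exact(segments: Iterable[TMSegment]) -> list[TMSegment]:
    """Remove exact duplicates and substrings of longer retained sequences.

    Deterministic stand-in for redundancy removal at 100 % identity: the
    longest sequence is kept; among equal sequences the lexicographically
    lowest (protein_id, start) wins.
    """
    ordered = sorted(
        segments, key=lambda s: (-len(s.sequence), s.protein_id, s.start)
    )
    kept: list[TMSegment] = []
    for seg in ordered:
        if any(seg.sequence in k.sequence for k in kept):
            continue
        kept.append(seg)
    kept.sort(key=lambda s: (s.protein_id, s.start))
    return kept


def write_report(rows: Iterable[TMReportRow], path: str | Path) -> None:
    """Write per-segment results as TSV, numerics to 2 d.p., deterministic order."""
    header = "protein_id\tstart\tend\tx_c\tx_phi\tz\tclass\tcategory"
    lines = [header]
    for r in sorted(rows, key=lambda r: (r.protein_id, r.start)):
        lines.append(
            f"{r.protein_id}\t{r.start}\t{r.end}\t{r.x_c:.2f}\t{r.x_phi:.2f}"
            f"\t{r.z:.2f}\t{r.tm_class}\t{r.category or ''}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
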