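"""Readers/writers for FASTA, FASTQ, GFF3 and the locus-map sidecar.

All coordinates inside the package are 0-based half-open.  The single
place where the 1-based inclusive convention of GFF3 appears is
:func:`to_gff_coords` / :func:`from_gff_coords`, applied exactly at the
serialization boundary.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence with optional per-base qualities."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id {self.id!r} is empty or contains whitespace")
        if len(self.seq) < 1:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class LocusAssignment:
    scaffold_id: str
    locus_id: str


def _sanitize(seq: str, rec_id: str) -> str:
    """Uppercase and map non-ACGTN characters to N (with a warning)."""
    seq = seq.upper()
    if _NON_ACGTN.search(seq):
        warnings.warn(
            f"record {rec_id!r}: non-ACGTN characters replaced with N",
            stacklevel=3,
        )
        seq = _NON_ACGTN.sub("N", seq)
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file (arbitrary line wrapping) into records, file order."""
    path = Path(path)
    records: list[SequenceRecord] = []
    # Pre-scan for sequence data before any header: Bio.SeqIO silently skips it.
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: sequence data before any FASTA header"
                )
            break
    for rec in SeqIO.parse(path, "fasta"):
        records.append(SequenceRecord(id=rec.id, seq=_sanitize(str(rec.seq), rec.id)))
    return records


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a 4-line-record FASTQ file; enforces seq/qual length equality."""
    path = Path(path)
    records: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(path, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            records.append(
                SequenceRecord(id=rec.id, seq=_sanitize(str(rec.seq), rec.id), qual=qual)
            )
    except ValueError as exc:  # Bio.SeqIO reports id and defect in the message
        raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60
) -> None:
    """Write records as FASTA; ``wrap`` is the line width (0 = no wrapping)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            if wrap and wrap > 0:
                for i in range(0, len(rec.seq), wrap):
                    fh.write(rec.seq[i : i + wrap] + "\n")
            else:
                fh.write(rec.seq + "\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def read_locus_map(path: str | Path) -> list[LocusAssignment]:
    """Read the 2-column TSV scaffold_id -> locus_id sidecar."""
    path = Path(path)
    seen: set[str] = set()
    out: list[LocusAssignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            sid, lid = parts
            if sid in seen:
                raise FormatError(
                    f"{path}: line {lineno}: scaffold {sid!r} assigned twice"
                )
            seen.add(sid)
            out.append(LocusAssignment(scaffold_id=sid, locus_id=lid))
    return out


def write_locus_map(assignments: Iterable[LocusAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in assignments:
            fh.write(f"{a.scaffold_id}\t{a.locus_id}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def to_gff_coords(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (the only conversion point)."""
    if end <= start:
        raise ValueError(f"invalid block ({start}, {end}): end <= start")
    return start + 1, end


def from_gff_coords(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


@dataclass
class TranscriptAnnotation:
    """A transcript model on pseudo-reference coordinates for GFF3 output."""

    ref_id: str  # pseudo-reference (cluster) id — GFF3 seqid
    gene_id: str
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open

    def __post_init__(self) -> None:
        for s, e in self.exons:
            if e <= s:
                raise ValueError(
                    f"transcript {self.transcript_id!r}: invalid exon block ({s}, {e})"
                )


def write_gff(annotations: Sequence[TranscriptAnnotation], path: str | Path) -> None:
    """Serialize transcript models as GFF3 (gene / mRNA / exon lines).

    One gene line per distinct (ref_id, gene_id), one mRNA per transcript,
    one exon per block.  Coordinates are converted to 1-based inclusive here
    and nowhere else.
    """
    lines = ["##gff-version 3"]
    by_gene: dict[tuple[str, str], list[TranscriptAnnotation]] = {}
    for ann in annotations:
        by_gene.setdefault((ann.ref_id, ann.gene_id), []).append(ann)
    for (ref_id, gene_id), anns in by_gene.items():
        spans = [b for a in anns for b in a.exons]
        g1, g2 = to_gff_coords(min(s for s, _ in spans), max(e for _, e in spans))
        lines.append(
            f"{ref_id}\thybridasm\tgene\t{g1}\t{g2}\t.\t+\t.\tID={gene_id}"
        )
        for ann in anns:
            t1, t2 = to_gff_coords(
                min(s for s, _ in ann.exons), max(e for _, e in ann.exons)
            )
            lines.append(
                f"{ref_id}\thybridasm\tmRNA\t{t1}\t{t2}\t.\t+\t.\t"
                f"ID={ann.transcript_id};Parent={gene_id}"
            )
            for i, (s, e) in enumerate(sorted(ann.exons), 1):
                e1, e2 = to_gff_coords(s, e)
                lines.append(
                    f"{ref_id}\thybridasm\texon\t{e1}\t{e2}\t.\t+\t.\t"
                    f"ID={ann.transcript_id}.exon{i};Parent={ann.transcript_id}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff(path: str | Path) -> list[TranscriptAnnotation]:
    """Internal GFF3 reader for round-trip checks; understands its own output."""
    mrna_parent: dict[str, str] = {}
    mrna_ref: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: malformed GFF line: {line!r}")
            seqid, _, ftype, start1, end1, _, _, _, attrs = cols
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "mRNA":
                tid = attr["ID"]
                mrna_parent[tid] = attr.get("Parent", tid)
                mrna_ref[tid] = seqid
                exons.setdefault(tid, [])
                order.append(tid)
            elif ftype == "exon":
                tid = attr["Parent"]
                exons.setdefault(tid, []).append(
                    from_gff_coords(int(start1), int(end1))
                )
    return [
        TranscriptAnnotation(
            ref_id=mrna_ref.get(tid, ""),
            gene_id=mrna_parent.get(tid, tid),
            transcript_id=tid,
            exons=sorted(exons[tid]),
        )
        for tid in (order or sorted(exons))
    ]
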