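"""Scaffold extension by long-read overhangs and gene-locus grouping.

A long read aligned to a short-read scaffold may hang past either
scaffold end; those overhang fragments carry transcript sequence the
short-read assembly missed.  Per scaffold end, the overhangs are combined
into a majority-vote consensus which is concatenated onto the scaffold.
Scaffolds sharing a locus (per the assembler's locus map) and the long
reads aligned to them form gene groups; long reads aligned to no
scaffold are handed to k-mer clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment_core import (
    ScoringScheme,
    SplicedAlignment,
    percent_identity,
)
from .profile_msa import polished_consensus
from .sequence_io import LocusAssignment, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtensionParams:
    """Acceptance/geometry thresholds for long-read -> scaffold alignments.

    ``accept_identity`` and ``min_aligned_len`` gate whether an alignment
    counts at all (tolerant of ~15% long-read error but rejecting spurious
    hits); ``end_slack`` is how close to a scaffold end the alignment must
    reach for the read to qualify as end-covering; ``min_overhang`` is the
    minimum unaligned read length past the end worth using.
    """

    min_overhang: int = 50
    end_slack: int = 10
    accept_identity: float = 0.70
    min_aligned_len: int = 100


@dataclass(frozen=True)
class OverhangFragment:
    scaffold_id: str
    end: str  # "left" | "right"
    seq: str
    source_lr_id: str

    def __post_init__(self) -> None:
        if self.end not in ("left", "right"):
            raise ValueError(f"invalid end {self.end!r}")


@dataclass
class GeneGroup:
    locus_id: str
    scaffold_ids: list[str] = field(default_factory=list)
    lr_ids: list[str] = field(default_factory=list)


def classify_alignment(
    aln: SplicedAlignment, scaffold_len: int, params: ExtensionParams | None = None
) -> str:
    """Classify a long-read alignment to one scaffold.

    Returns one of ``contained``, ``left_overhang``, ``right_overhang``,
    ``both_overhangs``, ``unaligned``.  The read must reach within
    ``end_slack`` of a scaffold end *and* have at least ``min_overhang``
    unaligned bases past it for that end to qualify.
    """
    params = params or ExtensionParams()
    if (
        aln.is_empty
        or aln.aligned_len < params.min_aligned_len
        or percent_identity(aln) < params.accept_identity
    ):
        return "unaligned"
    left = aln.t_start <= params.end_slack and aln.q_start >= params.min_overhang
    right = (
        aln.t_end >= scaffold_len - params.end_slack
        and aln.query_len - aln.q_end >= params.min_overhang
    )
    if left and right:
        return "both_overhangs"
    if left:
        return "left_overhang"
    if right:
        return "right_overhang"
    return "contained"


def extract_overhangs(
    aln: SplicedAlignment,
    lr: SequenceRecord,
    scaffold: SequenceRecord,
    params: ExtensionParams | None = None,
) -> list[OverhangFragment]:
    """The unaligned long-read portions hanging past qualifying scaffold
    ends.  A read with both overhangs contributes to both ends."""
    params = params or ExtensionParams()
    cls = classify_alignment(aln, len(scaffold.seq), params)
    frags: list[OverhangFragment] = []
    if cls in ("left_overhang", "both_overhangs"):
        frags.append(
            OverhangFragment(
                scaffold_id=scaffold.id,
                end="left",
                seq=lr.seq[: aln.q_start],
                source_lr_id=lr.id,
            )
        )
    if cls in ("right_overhang", "both_overhangs"):
        frags.append(
            OverhangFragment(
                scaffold_id=scaffold.id,
                end="right",
                seq=lr.seq[aln.q_end :],
                source_lr_id=lr.id,
            )
        )
    return frags


def build_overhang_consensus(
    fragments: list[OverhangFragment],
    scoring: ScoringScheme | None = None,
) -> str:
    """Majority-vote consensus of the overhang fragments for one scaffold
    end, anchored at the scaffold-proximal side.

    A single fragment is returned verbatim.  For several fragments the
    sequences are anchored at the scaffold-proximal end (right-end
    overhangs start there; left-end overhangs are reversed so they do,
    then un-reversed) and combined by iterated star-alignment majority
    vote; the consensus extends as far as any fragment covers.
    """
    if not fragments:
        raise ValueError("build_overhang_consensus requires >= 1 fragment")
    ends = {f.end for f in fragments}
    if len(ends) != 1:
        raise ValueError("fragments mix scaffold ends")
    end = ends.pop()
    if len(fragments) == 1:
        return fragments[0].seq
    seqs = [f.seq for f in fragments]
    if end == "left":  # anchor at the scaffold-proximal (right) side
        seqs = [s[::-1] for s in seqs]
    cons = polished_consensus(seqs, scoring)
    return cons[::-1] if end == "left" else cons


def extend_scaffold(
    scaffold: SequenceRecord,
    left_consensus: str | None = None,
    right_consensus: str | None = None,
) -> SequenceRecord:
    """Concatenate end consensuses onto the scaffold; the original scaffold
    sequence is an unmodified contiguous substring of the result."""
    left = left_consensus or ""
    right = right_consensus or ""
    return SequenceRecord(id=scaffold.id, seq=left + scaffold.seq + right)


def group_members(
    locus_map: list[LocusAssignment],
    accepted: dict[str, list[SplicedAlignment]],
    all_scaffold_ids: list[str],
) -> list[GeneGroup]:
    """Group scaffolds by locus and attach each aligned long read to the
    group of its best-scoring scaffold (ties: longest alignment, then
    lexicographic scaffold id).

    ``accepted`` maps lr_id -> accepted alignments (one per scaffold).
    Scaffolds absent from the locus map form singleton loci.
    """
    locus_of = {a.scaffold_id: a.locus_id for a in locus_map}
    for sid in all_scaffold_ids:
        locus_of.setdefault(sid, sid)  # singleton locus
    groups: dict[str, GeneGroup] = {}
    for sid in all_scaffold_ids:
        lid = locus_of[sid]
        groups.setdefault(lid, GeneGroup(locus_id=lid)).scaffold_ids.append(sid)
    for lr_id in sorted(accepted):
        alns = accepted[lr_id]
        if not alns:
            continue
        best = min(alns, key=lambda a: (-a.score, -a.aligned_len, a.target_id))
        groups[locus_of[best.target_id]].lr_ids.append(lr_id)
    return [groups[lid] for lid in sorted(groups)]
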