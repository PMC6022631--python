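"""Alternative-exon-usage calling and isoform structure annotation.

Each cluster member is spliced-aligned to its pseudo-reference.  A target
gap of at least ``min_gap_len`` (default 43 bp) in the best alignment is
a *candidate* alternative exon usage event: the pseudo-reference carries
an exon this transcript skips.  A candidate is *confirmed* when short
reads provide two independent pieces of evidence: at least
``min_splice_reads`` short reads align across the gap with concordant
boundaries, and the gapped (skipped) region itself is expressed at
``min_gap_coverage``-fold mean short-read depth — i.e. both the skipping
and the non-skipping isoform are observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .alignment_core import SplicedAlignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationParams:
    min_gap_len: int = 43
    min_splice_reads: int = 10
    min_gap_coverage: float = 10.0
    boundary_slack: int = 5
    gap_coverage_stat: str = "mean"  # or "min"

    def __post_init__(self) -> None:
        if self.min_gap_len < 1 or self.min_splice_reads < 1:
            raise ValueError("thresholds must be positive")
        if self.min_gap_coverage <= 0 or self.boundary_slack < 0:
            raise ValueError("thresholds must be positive")
        if self.gap_coverage_stat not in ("mean", "min"):
            raise ValueError("gap_coverage_stat must be 'mean' or 'min'")


@dataclass(frozen=True)
class AltExonEvent:
    cluster_id: str
    transcript_id: str
    gap_start: int  # on the pseudo-reference, 0-based half-open
    gap_end: int
    n_splice_reads: int = 0
    mean_gap_coverage: float = 0.0
    status: str = "candidate"  # candidate | confirmed | rejected


@dataclass
class IsoformAnnotation:
    cluster_id: str
    transcript_id: str
    blocks: list[tuple[int, int]] = field(default_factory=list)  # pseudo-ref coords
    supporting_transcripts: list[str] = field(default_factory=list)


def detect_candidate_events(
    aln: SplicedAlignment,
    cluster_id: str,
    params: AnnotationParams | None = None,
) -> list[AltExonEvent]:
    """Candidate events: inter-block *target* gaps >= min_gap_len in the
    best alignment of one transcript to its pseudo-reference.  Query-side
    gaps never produce events (without a genome, transcript-only
    insertions are indistinguishable from pseudo-reference gaps)."""
    params = params or AnnotationParams()
    events = [
        AltExonEvent(
            cluster_id=cluster_id,
            transcript_id=aln.query_id,
            gap_start=gs,
            gap_end=ge,
        )
        for gs, ge in aln.target_gaps()
        if ge - gs >= params.min_gap_len
    ]
    return sorted(events, key=lambda e: e.gap_start)


def coverage_profile(
    sr_alignments: list[SplicedAlignment], ref_len: int
) -> np.ndarray:
    """Per-base short-read depth on a pseudo-reference from all aligned
    blocks (spliced or not)."""
    delta = np.zeros(ref_len + 1, dtype=np.int64)
    for aln in sr_alignments:
        for _, _, ts, te in aln.blocks:
            delta[ts] += 1
            delta[te] -= 1
    return np.cumsum(delta[:-1])


def confirm_event(
    event: AltExonEvent,
    sr_alignments: list[SplicedAlignment],
    params: AnnotationParams | None = None,
    depth: np.ndarray | None = None,
) -> AltExonEvent:
    """Set the event status from short-read evidence.

    ``n_splice_reads`` counts short reads whose alignment contains a
    target gap with both boundaries within ``boundary_slack`` of the
    event's; gap coverage is the mean (or min) per-base depth inside
    [gap_start, gap_end).  Confirmation requires both thresholds.
    Idempotent: status is a total function of the evidence.
    """
    params = params or AnnotationParams()
    n_splice = 0
    for aln in sr_alignments:
        for gs, ge in aln.target_gaps():
            if (
                abs(gs - event.gap_start) <= params.boundary_slack
                and abs(ge - event.gap_end) <= params.boundary_slack
            ):
                n_splice += 1
                break
    if depth is None:
        ref_len = max(
            [event.gap_end] + [a.t_end for a in sr_alignments if not a.is_empty]
        )
        depth = coverage_profile(sr_alignments, ref_len)
    window = depth[event.gap_start : event.gap_end]
    if window.size == 0:
        cov = 0.0
    elif params.gap_coverage_stat == "mean":
        cov = float(window.mean())
    else:
        cov = float(window.min())
    status = (
        "confirmed"
        if n_splice >= params.min_splice_reads and cov >= params.min_gap_coverage
        else "rejected"
    )
    return replace(
        event, n_splice_reads=n_splice, mean_gap_coverage=cov, status=status
    )


def _fused_blocks(
    aln: SplicedAlignment, min_gap_len: int
) -> list[tuple[int, int]]:
    """Alignment blocks on the target with gaps < min_gap_len fused into
    their flanks (alignment noise, not structure)."""
    merged: list[list[int]] = []
    for _, _, ts, te in aln.blocks:
        if merged and ts - merged[-1][1] < min_gap_len:
            merged[-1][1] = te
        else:
            merged.append([ts, te])
    return [(s, e) for s, e in merged]


def _blocks_match(
    a: list[tuple[int, int]], b: list[tuple[int, int]], slack: int
) -> bool:
    if len(a) != len(b):
        return False
    return all(
        abs(s1 - s2) <= slack and abs(e1 - e2) <= slack
        for (s1, e1), (s2, e2) in zip(a, b)
    )


def annotate_isoforms(
    cluster_id: str,
    transcript_alignments: list[SplicedAlignment],
    params: AnnotationParams | None = None,
) -> list[IsoformAnnotation]:
    """Isoform structures on pseudo-reference coordinates.

    Each transcript's exon blocks are its (noise-fused) alignment blocks;
    transcripts whose block sets agree within ``boundary_slack`` at every
    boundary collapse into one isoform record whose representative is the
    longest transcript (by aligned target span, ties by id)."""
    params = params or AnnotationParams()
    annotated: list[IsoformAnnotation] = []
    order = sorted(
        (a for a in transcript_alignments if not a.is_empty),
        key=lambda a: (-(a.t_end - a.t_start), a.query_id),
    )
    for aln in order:
        blocks = _fused_blocks(aln, params.min_gap_len)
        if not blocks:
            continue
        for iso in annotated:
            if _blocks_match(iso.blocks, blocks, params.boundary_slack):
                iso.supporting_transcripts.append(aln.query_id)
                break
        else:
            annotated.append(
                IsoformAnnotation(
                    cluster_id=cluster_id,
                    transcript_id=aln.query_id,
                    blocks=blocks,
                    supporting_transcripts=[aln.query_id],
                )
            )
    return annotated
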