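"""Per-cluster pseudo-reference construction by iterative consensus.

The pseudo-reference of a gene cluster is a consensus sequence meant to
contain *every* expressed exonic region of the gene, built from the
cluster's transcript sequences (extended scaffolds and/or long reads).
Members are processed longest-first: the three longest seed the profile,
then two more are folded in per round until none remain.  Members with
less than ``min_identity_to_longest`` identity to the longest member are
dropped (and never reconsidered).  Consensus emission uses union
semantics — a base present in a single member survives — because an exon
covered by only one read must appear in the pseudo-reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment_core import ScoringScheme, local_align
from .profile_msa import Profile, structural_star_round

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PseudoRefParams:
    min_identity_to_longest: float = 0.30
    init_batch: int = 3
    step_batch: int = 2
    strict_majority: bool = False  # strict per-column majority instead of union
    polish_rounds: int = 2  # structure-aware majority re-votes after the build

    def __post_init__(self) -> None:
        if not 0 < self.min_identity_to_longest <= 1:
            raise ValueError("min_identity_to_longest must be in (0, 1]")
        if self.init_batch < 1 or self.step_batch < 1:
            raise ValueError("batch sizes must be >= 1")


@dataclass
class PseudoReference:
    cluster_id: str
    seq: str
    member_ids: list[str] = field(default_factory=list)
    depth: list[int] = field(default_factory=list)


def msa_consensus(
    seqs: list[str],
    scoring: ScoringScheme | None = None,
    *,
    strict_majority: bool = False,
    polish: bool = True,
) -> str:
    """Consensus of 2-5 sequences by progressive profile alignment (guide
    order = input order).  Union semantics by default: columns that are a
    gap in most rows are still emitted when any row has a base, so
    insertion content (exons present in a single member) is retained.
    Error-scale disagreements are then settled by a structure-aware
    majority re-vote plus local Steiner refinement (``polish``)."""
    from .profile_msa import _steiner_refine, CONSENSUS_SCORING

    if len(seqs) < 2:
        raise ValueError("msa_consensus requires >= 2 sequences")
    if any(not s for s in seqs):
        raise ValueError("sequences must be non-empty")
    prof = Profile(scoring)
    for s in seqs:
        prof.merge(s)
    cons, _ = prof.consensus(strict=strict_majority)
    if polish:
        for _ in range(2):
            new, _ = structural_star_round(seqs, cons)
            if not new or new == cons:
                break
            cons = new
        cons = _steiner_refine(seqs, cons, CONSENSUS_SCORING, structural=True)
    return cons


def build_pseudo_reference(
    cluster_id: str,
    members: dict[str, str],
    params: PseudoRefParams | None = None,
    scoring: ScoringScheme | None = None,
) -> PseudoReference:
    """Iterative consensus over length-sorted cluster members.

    Members sort by descending length (ties: id).  A singleton cluster is
    its own pseudo-reference.  Otherwise members below the identity floor
    versus the longest member are dropped, the ``init_batch`` longest
    members seed the profile and ``step_batch`` more are folded in per
    round.  The profile (per-column votes and depth) is carried across
    rounds so the depth vector reflects every contributing member.
    """
    params = params or PseudoRefParams()
    scoring = scoring or ScoringScheme()
    if not members:
        raise ValueError("cluster has no members")
    order = sorted(members, key=lambda mid: (-len(members[mid]), mid))
    if len(order) == 1:
        mid = order[0]
        return PseudoReference(
            cluster_id=cluster_id,
            seq=members[mid],
            member_ids=[mid],
            depth=[1] * len(members[mid]),
        )
    longest = members[order[0]]
    retained = [order[0]]
    for mid in order[1:]:
        # identity over the member's length, not over the (match-dominated)
        # local alignment columns: unrelated sequence must score low
        aln = local_align(members[mid], longest, scoring)
        ident = aln.matches / min(len(members[mid]), len(longest))
        if ident >= params.min_identity_to_longest:
            retained.append(mid)
        else:
            logger.debug(
                "cluster %s: dropping %s (identity %.2f to longest)",
                cluster_id, mid, ident,
            )
    prof = Profile(scoring)
    for mid in retained[: params.init_batch]:
        prof.merge(members[mid])
    pos = params.init_batch
    while pos < len(retained):
        for mid in retained[pos : pos + params.step_batch]:
            prof.merge(members[mid])
        pos += params.step_batch
    cons, depth = prof.consensus(strict=params.strict_majority)
    # structure-aware polish: re-vote every member against the union
    # consensus so error-scale noise is outvoted while minority exons
    # (decided only by the members carrying them) are preserved
    member_seqs = [members[mid] for mid in retained]
    for _ in range(params.polish_rounds):
        new, new_depth = structural_star_round(member_seqs, cons)
        if not new or new == cons:
            break
        cons, depth = new, new_depth
    return PseudoReference(
        cluster_id=cluster_id, seq=cons, member_ids=retained, depth=depth
    )
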