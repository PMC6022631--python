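"""Progressive profile alignment and column-vote consensus.

Two consensus engines share the pairwise end-free aligner:

* ``Profile`` — progressive union profile: sequences are folded in one at
  a time (guide order = input order); every column with at least one base
  vote survives, so content present in a single member (e.g. an exon
  covered by one long read only) is retained.  Used for pseudo-reference
  construction.
* ``star_majority_consensus`` — star re-alignment with column-wise
  majority vote: all fragments are aligned to a fixed reference, each
  reference column and each inter-column insertion is decided by
  plurality among the rows covering it, and the vote is iterated (the
  round-1 consensus becomes the round-2 reference).  Used for overhang
  consensus where per-base accuracy matters most.

A light noise filter distinguishes single-row insertion *runs* of 1-2
columns (the signature of third-generation indel errors) from real
inserted content (exons, tens to hundreds of bases): short unsupported
runs are dropped when at least three rows cover the position, which is
when a vote is meaningful.  With fewer than three covering rows nothing
is dropped, so two-sequence consensus keeps all insertions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .alignment_core import ScoringScheme, overlap_align, overlap_spliced_align

_BASE_TO_I = {"A": 0, "C": 1, "G": 2, "T": 3}
_I_TO_BASE = "ACGT"


@dataclass
class _Col:
    counts: list[int] = field(default_factory=lambda: [0, 0, 0, 0])
    span: int = 0  # rows whose alignment covers this column (base or gap)

    def add(self, base: str) -> None:
        i = _BASE_TO_I.get(base)
        if i is not None:
            self.counts[i] += 1
        self.span += 1

    @property
    def depth(self) -> int:
        return sum(self.counts)

    def plurality(self) -> str:
        best = max(self.counts)
        return _I_TO_BASE[self.counts.index(best)]  # index() -> lowest code wins ties


class Profile:
    """Progressive union profile over sequences in input order."""

    def __init__(self, scoring: ScoringScheme | None = None):
        self.scoring = scoring or ScoringScheme()
        self.cols: list[_Col] = []
        self.n_rows = 0

    @classmethod
    def from_seq(cls, seq: str, scoring: ScoringScheme | None = None) -> "Profile":
        p = cls(scoring)
        p.merge(seq)
        return p

    def consensus_string(self) -> str:
        return "".join(c.plurality() for c in self.cols)

    def merge(self, seq: str) -> None:
        """Align ``seq`` to the current consensus and fold it in."""
        if not self.cols:
            for base in seq:
                col = _Col()
                col.add(base)
                self.cols.append(col)
            self.n_rows = 1
            return
        cons = self.consensus_string()
        # structural merge: exon-scale gaps on either side cost one open
        aln = overlap_spliced_align(seq, cons, self.scoring)
        new_cols: list[_Col] = []

        def insert_run(sub: str) -> None:
            for base in sub:
                col = _Col()
                col.add(base)
                col.span = 0  # neighbour-span fixup below
                new_cols.append(col)

        if aln.is_empty:
            new_cols = list(self.cols)
            insert_run(seq)
        else:
            tpos = qpos = 0
            # leading: uncovered consensus columns, then the query overhang
            for tpos in range(aln.t_start):
                new_cols.append(self.cols[tpos])
            tpos = aln.t_start
            insert_run(seq[: aln.q_start])
            qpos = aln.q_start
            threshold = self.scoring.target_gap_free_threshold
            for bi, (qs, qe, ts, te) in enumerate(aln.blocks):
                if bi > 0:
                    # inter-block consensus columns: a short gap is an
                    # error-scale deletion (the row covers the column and
                    # votes gap); an exon-scale gap is structure — the row
                    # simply lacks the region and casts no vote at all
                    structural = ts - aln.blocks[bi - 1][3] >= threshold
                    while tpos < ts:
                        if not structural:
                            self.cols[tpos].span += 1
                        new_cols.append(self.cols[tpos])
                        tpos += 1
                    insert_run(seq[qpos:qs])
                    qpos = qs
                for _ in range(qe - qs):
                    self.cols[tpos].add(seq[qpos])
                    new_cols.append(self.cols[tpos])
                    tpos += 1
                    qpos += 1
            # trailing: query overhang, then uncovered consensus columns
            insert_run(seq[qpos:])
            while tpos < len(self.cols):
                new_cols.append(self.cols[tpos])
                tpos += 1
        self.cols = new_cols
        self.n_rows += 1
        self._fix_inserted_spans()

    def _fix_inserted_spans(self) -> None:
        """Freshly inserted columns inherit the smaller neighbour span, so
        majority logic knows how many rows pass through the insertion."""
        for i, col in enumerate(self.cols):
            if col.span == 0 and col.depth > 0:
                left = next(
                    (self.cols[j].span for j in range(i - 1, -1, -1)
                     if self.cols[j].span > 0), None)
                right = next(
                    (self.cols[j].span for j in range(i + 1, len(self.cols))
                     if self.cols[j].span > 0), None)
                candidates = [s for s in (left, right) if s is not None]
                col.span = min(candidates) if candidates else 1

    def consensus(
        self,
        *,
        strict: bool = False,
        min_depth: int = 1,
        noise_filter: bool = True,
    ) -> tuple[str, list[int]]:
        """Emit the consensus and its per-position depth (base votes).

        ``strict`` keeps a column only when at least half its covering
        rows have a base; otherwise any base vote suffices (union).
        """
        keep = []
        for col in self.cols:
            d = col.depth
            if d < max(min_depth, 1):
                keep.append(False)
            elif strict and 2 * d < col.span:
                keep.append(False)
            else:
                keep.append(True)
        if noise_filter:
            # drop unsupported 1-2 column insertion runs when >=3 rows cover
            i, n = 0, len(self.cols)
            while i < n:
                if keep[i] and self.cols[i].depth == 1 and self.cols[i].span >= 3:
                    j = i
                    while (
                        j < n and keep[j]
                        and self.cols[j].depth == 1 and self.cols[j].span >= 3
                    ):
                        j += 1
                    if j - i <= 2:
                        for t in range(i, j):
                            keep[t] = False
                    i = j
                else:
                    i += 1
        seq, depth = [], []
        for col, k in zip(self.cols, keep):
            if k:
                seq.append(col.plurality())
                depth.append(col.depth)
        return "".join(seq), depth


def hp_compress_runs(seq: str) -> tuple[str, list[int]]:
    """Homopolymer-compress, keeping the run length of every kept base."""
    if not seq:
        return "", []
    bases: list[str] = [seq[0]]
    runs: list[int] = [1]
    for c in seq[1:]:
        if c == bases[-1]:
            runs[-1] += 1
        else:
            bases.append(c)
            runs.append(1)
    return "".join(bases), runs


def _median_int(values: list[int]) -> int:
    """Deterministic integer median (upper of the two middles)."""
    s = sorted(values)
    return s[len(s) // 2]


def _star_round(
    frag_pairs: list[tuple[str, list[int]]],
    reference: str,
    scoring: ScoringScheme,
) -> str:
    """One star-alignment majority vote against a fixed reference, in
    homopolymer-compressed space with per-column run-length voting.

    Each fragment is a (compressed sequence, run lengths) pair and the
    reference is a compressed sequence.  Every reference column is decided
    by plurality base among covering rows, and its emitted run length is
    the median of the run lengths of the rows voting for that base —
    which is what makes homopolymer-length indel noise cancel.  Inserted
    content between columns is voted the same way: among rows covering
    the junction, the plurality inserted (compressed) string wins, with
    no insertion counting as an empty-string vote.
    """
    ncol = len(reference)
    counts = [[0, 0, 0, 0] for _ in range(ncol)]
    run_votes: list[dict[int, list[int]]] = [{} for _ in range(ncol)]
    span = [0] * ncol
    ins_votes: dict[int, Counter] = {}
    ins_runs: dict[tuple[int, str], list[list[int]]] = {}
    junction_cover = [0] * (ncol + 1)

    def vote_insertion(j: int, cseq: str, runs: list[int]) -> None:
        ins_votes.setdefault(j, Counter())[cseq] += 1
        ins_runs.setdefault((j, cseq), []).append(runs)

    for cseq, runs in frag_pairs:
        aln = overlap_align(cseq, reference, scoring)
        if aln.is_empty:
            continue
        for j in range(aln.t_start, aln.t_end + 1):
            junction_cover[j] += 1
        qpos = aln.q_start
        if aln.q_start:  # leading overhang = insertion before t_start
            vote_insertion(aln.t_start, cseq[: aln.q_start], runs[: aln.q_start])
        for bi, (qs, qe, ts, te) in enumerate(aln.blocks):
            if bi > 0:
                prev_te = aln.blocks[bi - 1][3]
                for t in range(prev_te, ts):
                    span[t] += 1
                if qs > qpos:
                    vote_insertion(ts, cseq[qpos:qs], runs[qpos:qs])
                qpos = qs
            for off in range(qe - qs):
                b = _BASE_TO_I.get(cseq[qpos])
                if b is not None:
                    counts[ts + off][b] += 1
                    run_votes[ts + off].setdefault(b, []).append(runs[qpos])
                span[ts + off] += 1
                qpos += 1
        if qpos < len(cseq):  # trailing overhang = insertion after t_end
            vote_insertion(aln.t_end, cseq[qpos:], runs[qpos:])
    out: list[str] = []
    for j in range(ncol + 1):
        votes = ins_votes.get(j)
        if votes is not None:
            n_cover = junction_cover[j]
            # rows covering the junction without an insertion vote ""
            n_empty = max(0, n_cover - sum(votes.values()))
            tally = votes.copy()
            tally[""] += n_empty
            # plurality string; ties: shorter, then lexicographic
            winner = min(
                tally.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0])
            )[0]
            if winner and tally[winner] * 2 >= max(n_cover, 1):
                runs_list = ins_runs[(j, winner)]
                for pos, base in enumerate(winner):
                    out.append(base * _median_int([r[pos] for r in runs_list]))
        if j < ncol:
            d = sum(counts[j])
            if d == 0 or 2 * d < span[j]:
                continue
            best = max(counts[j])
            b = counts[j].index(best)
            out.append(_I_TO_BASE[b] * _median_int(run_votes[j][b]))
    return "".join(out)


# consensus votes want edit-distance-like economics: a mismatch must cost
# more than a gap, or reads absorb spurious reference columns as mismatches
# instead of gapping them out and the vote can never converge
CONSENSUS_SCORING = ScoringScheme(
    match=2, mismatch=-5, gap_open=-2, gap_extend=-2
)


def star_majority_consensus(
    fragments: list[str],
    scoring: ScoringScheme | None = None,
    *,
    rounds: int = 2,
) -> str:
    """Iterated star-alignment majority consensus of error-prone fragments.

    The vote runs in homopolymer-compressed space (run lengths voted
    separately per column).  The initial reference is the longest
    fragment (ties: first in input order); each round re-aligns every
    fragment to the current consensus and re-votes.  Deterministic for a
    fixed input order.
    """
    scoring = scoring or CONSENSUS_SCORING
    if not fragments:
        raise ValueError("at least one fragment required")
    if len(fragments) == 1:
        return fragments[0]
    frag_pairs = [hp_compress_runs(f) for f in fragments]
    consensus = max(fragments, key=len)
    reference = hp_compress_runs(consensus)[0]
    for _ in range(rounds):
        new = _star_round(frag_pairs, reference, scoring)
        if not new or new == consensus:
            break
        consensus = new
        reference = hp_compress_runs(new)[0]
    return consensus


def structural_star_round(
    members: list[str],
    reference: str,
    scoring: ScoringScheme | None = None,
    *,
    min_depth: int = 1,
) -> tuple[str, list[int]]:
    """One majority re-vote of transcript members against a fixed
    reference, aware of exon structure: members are aligned with long-gap
    states on both sides, and a member whose alignment *skips* a region
    (structural target gap) casts no vote there — so an exon carried by a
    minority of members is decided only by the members that have it.
    Columns and insertions are voted by plurality among covering rows.
    Returns (consensus, per-column depth)."""
    scoring = scoring or CONSENSUS_SCORING
    ncol = len(reference)
    counts = [[0, 0, 0, 0] for _ in range(ncol)]
    span = [0] * ncol
    ins_votes: dict[int, Counter] = {}
    junction_cover = [0] * (ncol + 1)
    threshold = scoring.target_gap_free_threshold
    for seq in members:
        aln = overlap_spliced_align(seq, reference, scoring)
        if aln.is_empty:
            continue
        qpos = aln.q_start
        if aln.q_start:
            ins_votes.setdefault(aln.t_start, Counter())[seq[: aln.q_start]] += 1
        covered: list[tuple[int, int]] = []
        for bi, (qs, qe, ts, te) in enumerate(aln.blocks):
            if bi > 0:
                prev_te = aln.blocks[bi - 1][3]
                if ts - prev_te < threshold:  # error-scale deletion: covers
                    for t in range(prev_te, ts):
                        span[t] += 1
                    covered.append((prev_te, ts))
                if qs > qpos:
                    ins_votes.setdefault(ts, Counter())[seq[qpos:qs]] += 1
                qpos = qs
            for off in range(qe - qs):
                b = _BASE_TO_I.get(seq[qpos])
                if b is not None:
                    counts[ts + off][b] += 1
                span[ts + off] += 1
                qpos += 1
            covered.append((ts, te))
        if qpos < len(seq):
            ins_votes.setdefault(aln.t_end, Counter())[seq[qpos:]] += 1
        for lo, hi in covered:
            for j in range(lo, hi + 1):
                junction_cover[j] += 1
    out: list[str] = []
    depth: list[int] = []
    for j in range(ncol + 1):
        votes = ins_votes.get(j)
        if votes is not None:
            n_cover = junction_cover[j]
            n_empty = max(0, n_cover - sum(votes.values()))
            tally = votes.copy()
            tally[""] += n_empty
            winner = min(
                tally.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0])
            )[0]
            if winner and tally[winner] * 2 >= max(n_cover, 1):
                out.append(winner)
                depth.extend([tally[winner]] * len(winner))
        if j < ncol:
            d = sum(counts[j])
            if d < min_depth or 2 * d < span[j]:
                continue
            best = max(counts[j])
            out.append(_I_TO_BASE[counts[j].index(best)])
            depth.append(d)
    return "".join(out), depth


def _levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _row_segment(aln, seq: str, a: int, b: int) -> str:
    """The bases of ``seq`` that its alignment places inside consensus
    interval [a, b), including insertions anchored inside it."""
    out: list[str] = []
    for bi, (qs, qe, ts, te) in enumerate(aln.blocks):
        if bi > 0:
            prev_qe, prev_te = aln.blocks[bi - 1][1], aln.blocks[bi - 1][3]
            if a <= prev_te < b:
                out.append(seq[prev_qe:qs])
        lo, hi = max(ts, a), min(te, b)
        if lo < hi:
            out.append(seq[qs + (lo - ts) : qs + (hi - ts)])
    return "".join(out)


def _steiner_refine(
    fragments: list[str],
    cons: str,
    scoring: ScoringScheme,
    window: int = 12,
    structural: bool = False,
) -> str:
    """Local Steiner-string refinement: per consensus window, replace the
    consensus segment by the candidate (a row's segment or the current
    one) minimizing the total edit distance to all covering rows.  This
    resolves the residual vote-splitting that column-wise voting cannot
    (equivalent gap placements in short repeats).

    With ``structural`` the rows are aligned with exon-scale gap states
    and a row whose structural gap overlaps a window casts no vote there,
    so members that skip an exon cannot delete it from the consensus."""
    threshold = scoring.target_gap_free_threshold

    def covers(aln, a: int, b: int) -> bool:
        if aln.is_empty or aln.t_start > a or aln.t_end < b:
            return False
        if structural:
            for gs, ge in aln.target_gaps():
                if ge - gs >= threshold and gs < b and ge > a:
                    return False
        return True

    align_fn = overlap_spliced_align if structural else overlap_align
    alns = [align_fn(f, cons, scoring) for f in fragments]
    pieces: list[str] = []
    for a in range(0, len(cons), window):
        b = min(len(cons), a + window)
        segs = [
            _row_segment(aln, f, a, b)
            for aln, f in zip(alns, fragments)
            if covers(aln, a, b)
        ]
        current = cons[a:b]
        cands = sorted(set(segs + [current]))
        if len(cands) > 1 and segs:
            best = min(
                cands,
                key=lambda c: (sum(_levenshtein(c, s) for s in segs), c != current, c),
            )
        else:
            best = current
        pieces.append(best)
    return "".join(pieces)


def polished_consensus(
    fragments: list[str],
    scoring: ScoringScheme | None = None,
) -> str:
    """High-accuracy consensus of indel-noisy fragments.

    Three stages, all deterministic for a fixed input order: (i) two
    partial-order-alignment rounds build the structural consensus (the
    second round re-folds every fragment into a graph seeded with the
    first consensus); (ii) a star-alignment vote in homopolymer-
    compressed space settles per-column bases and run lengths; (iii) a
    windowed Steiner-string refinement replaces each consensus window by
    the candidate minimizing total edit distance to the covering rows.
    """
    from .poa import PoaGraph, poa_consensus

    scoring = scoring or CONSENSUS_SCORING
    if not fragments:
        raise ValueError("at least one fragment required")
    if len(fragments) == 1:
        return fragments[0]
    cons = poa_consensus(fragments)
    graph = PoaGraph()
    graph.add(cons)
    for frag in fragments:
        graph.add(frag)
    cons = graph.consensus() or cons
    frag_pairs = [hp_compress_runs(f) for f in fragments]
    cons = _star_round(frag_pairs, hp_compress_runs(cons)[0], scoring) or cons
    return _steiner_refine(fragments, cons, scoring)
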