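"""Internal desk-scale pairwise aligners.

Two modes of one affine-gap (Gotoh) dynamic program:

* ``local`` — Smith-Waterman-style local alignment, used for long-read vs
  scaffold and transcript vs pseudo-reference comparisons.
* ``overlap`` — end-free global alignment (no penalty for leading/trailing
  gaps on either sequence), used by the progressive consensus builders.

For spliced alignment a fourth DP state models a *long target gap*: a run
of target positions at least ``target_gap_free_threshold`` long that is
skipped for a single ``gap_open`` charge, independent of its length.  This
is how a transcript missing an exon aligns cleanly across the exon it
skips.  Without a genome there are no splice motifs to exploit, so the gap
state is purely length-based.

Gap cost convention: a (short) gap of length L costs
``gap_open + L * gap_extend``; a long target gap costs ``gap_open`` only.

Coordinates are 0-based half-open throughout.  Minus-strand alignments
carry query coordinates on the reverse-complemented read (so block
coordinates stay strictly increasing on both axes); ``strand`` records the
flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

NEG = np.int32(-(10**8))

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTN", "TGCAN")


class ResourceError(RuntimeError):
    """Sequence too long for the exact DP; use an external-aligner adapter."""


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores; penalties are non-positive.

    ``target_gap_free_threshold``: target-side gaps at least this long are
    treated as structural (skipped exons) — one gap_open charge, excluded
    from identity columns.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -3
    gap_extend: int = -1
    target_gap_free_threshold: int = 30
    # flat cost of a structural gap, independent of its length; stiff enough
    # that chance micro-anchors inside a skipped exon cannot pay for
    # splitting one real skip into several
    long_gap_open: int = -15

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if self.long_gap_open > 0:
            raise ValueError("penalties must be <= 0")
        if self.target_gap_free_threshold < 1:
            raise ValueError("target_gap_free_threshold must be >= 1")


@dataclass
class SplicedAlignment:
    """Query-to-target mapping as ordered co-linear equal-length blocks."""

    query_id: str
    target_id: str
    strand: str = "+"
    blocks: list[tuple[int, int, int, int]] = field(default_factory=list)
    matches: int = 0
    aligned_len: int = 0
    score: int = 0
    query_len: int = 0

    @property
    def is_empty(self) -> bool:
        return not self.blocks

    @property
    def q_start(self) -> int:
        return self.blocks[0][0]

    @property
    def q_end(self) -> int:
        return self.blocks[-1][1]

    @property
    def t_start(self) -> int:
        return self.blocks[0][2]

    @property
    def t_end(self) -> int:
        return self.blocks[-1][3]

    def target_gaps(self) -> list[tuple[int, int]]:
        """Target intervals between consecutive blocks (possibly empty)."""
        return [
            (self.blocks[i][3], self.blocks[i + 1][2])
            for i in range(len(self.blocks) - 1)
        ]


def validate_alignment(aln: SplicedAlignment) -> None:
    """Assert the structural invariants of a block list (used by tests)."""
    prev_q = prev_t = -1
    for qs, qe, ts, te in aln.blocks:
        assert qe - qs == te - ts > 0, f"block length mismatch {(qs, qe, ts, te)}"
        assert qs > prev_q and ts > prev_t, "blocks not strictly increasing"
        prev_q, prev_t = qe - 1, te - 1
    assert 0 <= aln.matches <= max(aln.aligned_len, 0)


# DP ops: 0 diag, 1 query-gap (consumes query), 2 short target gap,
# 3 long target gap (consumes target, identity-free),
# 4 long query gap (consumes query, identity-free)
@njit(cache=True)
def _gotoh(q, t, match, mismatch, go, ge, lgo, long_gap, long_gap_q, local_mode):  # pragma: no cover
    n, m = q.shape[0], t.shape[0]
    neg = -(10**8)
    H = np.full((n + 1, m + 1), neg, dtype=np.int32)
    E = np.full((n + 1, m + 1), neg, dtype=np.int32)
    F = np.full((n + 1, m + 1), neg, dtype=np.int32)
    use_j = long_gap > 0
    use_k = long_gap_q > 0
    J = np.full((n + 1, m + 1), neg, dtype=np.int32) if use_j else np.empty((1, 1), dtype=np.int32)
    K = np.full((n + 1, m + 1), neg, dtype=np.int32) if use_k else np.empty((1, 1), dtype=np.int32)
    # both modes start free: local by definition, overlap via free end gaps
    for j in range(m + 1):
        H[0, j] = 0
    for i in range(n + 1):
        H[i, 0] = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = H[i - 1, j] + go + ge
            if E[i - 1, j] + ge > e:
                e = E[i - 1, j] + ge
            E[i, j] = e
            f = H[i, j - 1] + go + ge
            if F[i, j - 1] + ge > f:
                f = F[i, j - 1] + ge
            F[i, j] = f
            sub = match if (qi == t[j - 1] and qi < 4) else mismatch
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if use_j:
                jj = J[i, j - 1]
                if j >= long_gap and H[i, j - long_gap] + lgo > jj:
                    jj = H[i, j - long_gap] + lgo
                J[i, j] = jj
                if jj > h:
                    h = jj
            if use_k:
                kk = K[i - 1, j]
                if i >= long_gap_q and H[i - long_gap_q, j] + lgo > kk:
                    kk = H[i - long_gap_q, j] + lgo
                K[i, j] = kk
                if kk > h:
                    h = kk
            if local_mode == 0 and h < 0:
                h = 0
            H[i, j] = h
    # end cell
    best = neg
    ei = ej = 0
    if local_mode == 0:
        for i in range(n + 1):
            for j in range(m + 1):
                if H[i, j] > best:
                    best = H[i, j]
                    ei, ej = i, j
    else:
        for j in range(m + 1):
            if H[n, j] > best:
                best = H[n, j]
                ei, ej = n, j
        for i in range(n + 1):
            if H[i, m] > best:
                best = H[i, m]
                ei, ej = i, m
    # traceback
    ops = np.empty(n + m + 2, dtype=np.int8)
    nops = 0
    i, j = ei, ej
    state = 0  # 0=H 1=E 2=F 3=J 4=K
    while True:
        if state == 0:
            if local_mode == 0 and H[i, j] == 0:
                break
            if i == 0 or j == 0:
                break
            qi = q[i - 1]
            sub = match if (qi == t[j - 1] and qi < 4) else mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                ops[nops] = 0
                nops += 1
                i -= 1
                j -= 1
            elif use_j and H[i, j] == J[i, j]:
                state = 3
            elif use_k and H[i, j] == K[i, j]:
                state = 4
            elif H[i, j] == F[i, j]:
                state = 2
            elif H[i, j] == E[i, j]:
                state = 1
            else:  # numerical impossibility guard
                break
        elif state == 1:
            ops[nops] = 1
            nops += 1
            if i > 1 and E[i, j] == E[i - 1, j] + ge:
                i -= 1
            else:
                i -= 1
                state = 0
        elif state == 2:
            ops[nops] = 2
            nops += 1
            if j > 1 and F[i, j] == F[i, j - 1] + ge:
                j -= 1
            else:
                j -= 1
                state = 0
        elif state == 3:  # long target gap
            if J[i, j] == J[i, j - 1]:
                ops[nops] = 3
                nops += 1
                j -= 1
            else:
                for _ in range(long_gap):
                    ops[nops] = 3
                    nops += 1
                j -= long_gap
                state = 0
        else:  # long query gap
            if K[i, j] == K[i - 1, j]:
                ops[nops] = 4
                nops += 1
                i -= 1
            else:
                for _ in range(long_gap_q):
                    ops[nops] = 4
                    nops += 1
                i -= long_gap_q
                state = 0
    return best, i, j, ops[:nops][::-1].copy()


def _ops_to_alignment(
    query: str,
    target: str,
    score: int,
    si: int,
    sj: int,
    ops: np.ndarray,
    query_id: str,
    target_id: str,
    strand: str,
) -> SplicedAlignment:
    blocks: list[tuple[int, int, int, int]] = []
    qi, ti = si, sj
    bq = bt = -1
    blen = 0
    matches = 0
    aligned_len = 0
    for op in ops:
        if op == 0:
            if blen == 0:
                bq, bt = qi, ti
            if query[qi] == target[ti] and query[qi] != "N":
                matches += 1
            aligned_len += 1
            qi += 1
            ti += 1
            blen += 1
        else:
            if blen:
                blocks.append((bq, bq + blen, bt, bt + blen))
                blen = 0
            if op == 1:
                qi += 1
                aligned_len += 1
            elif op == 2:
                ti += 1
                aligned_len += 1
            elif op == 3:  # long target gap, identity-free
                ti += 1
            else:  # op 4: long query gap, identity-free
                qi += 1
    if blen:
        blocks.append((bq, bq + blen, bt, bt + blen))
    return SplicedAlignment(
        query_id=query_id,
        target_id=target_id,
        strand=strand,
        blocks=blocks,
        matches=matches,
        aligned_len=aligned_len,
        score=int(score),
        query_len=len(query),
    )


def _check_cap(query: str, target: str, max_len: int) -> None:
    if len(query) > max_len or len(target) > max_len:
        raise ResourceError(
            f"sequence length exceeds DP cap ({max_len} bp); "
            "use an external-aligner adapter"
        )


def _align(
    query: str,
    target: str,
    scoring: ScoringScheme,
    long_gap: int,
    mode: int,
    query_id: str,
    target_id: str,
    strand: str,
    long_gap_q: int = 0,
) -> SplicedAlignment:
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    score, si, sj, ops = _gotoh(
        encode(query),
        encode(target),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
        scoring.long_gap_open,
        long_gap,
        long_gap_q,
        mode,
    )
    if score <= 0 and mode == 0:
        return SplicedAlignment(
            query_id=query_id, target_id=target_id, strand=strand,
            query_len=len(query),
        )
    return _ops_to_alignment(
        query, target, score, si, sj, ops, query_id, target_id, strand
    )


def local_align(
    query: str,
    target: str,
    scoring: ScoringScheme | None = None,
    *,
    query_id: str = "query",
    target_id: str = "target",
    both_strands: bool = False,
    max_len: int = 200_000,
) -> SplicedAlignment:
    """Optimal affine-gap local alignment (single DP, no long-gap state)."""
    scoring = scoring or ScoringScheme()
    _check_cap(query, target, max_len)
    aln = _align(query, target, scoring, 0, 0, query_id, target_id, "+")
    if both_strands:
        rc = _align(revcomp(query), target, scoring, 0, 0, query_id, target_id, "-")
        if rc.score > aln.score:
            aln = rc
    return aln


def spliced_align(
    query: str,
    target: str,
    scoring: ScoringScheme | None = None,
    *,
    query_id: str = "query",
    target_id: str = "target",
    both_strands: bool = False,
    max_len: int = 200_000,
) -> SplicedAlignment:
    """Local alignment where target gaps >= threshold cost one gap_open.

    With ``target_gap_free_threshold`` larger than the target this reduces
    exactly to :func:`local_align`.
    """
    scoring = scoring or ScoringScheme()
    _check_cap(query, target, max_len)
    long_gap = scoring.target_gap_free_threshold
    if long_gap > len(target):
        long_gap = 0  # unreachable state: plain local alignment
    aln = _align(query, target, scoring, long_gap, 0, query_id, target_id, "+")
    if both_strands:
        rc = _align(
            revcomp(query), target, scoring, long_gap, 0, query_id, target_id, "-"
        )
        if rc.score > aln.score:
            aln = rc
    return aln


def overlap_align(
    query: str,
    target: str,
    scoring: ScoringScheme | None = None,
    *,
    query_id: str = "query",
    target_id: str = "target",
) -> SplicedAlignment:
    """End-free global alignment: leading/trailing gaps on either sequence
    are free.  Used by the progressive consensus builders."""
    scoring = scoring or ScoringScheme()
    return _align(query, target, scoring, 0, 1, query_id, target_id, "+")


def overlap_spliced_align(
    query: str,
    target: str,
    scoring: ScoringScheme | None = None,
    *,
    query_id: str = "query",
    target_id: str = "target",
) -> SplicedAlignment:
    """End-free global alignment with long-gap states on *both* sides:
    internal gaps at least ``target_gap_free_threshold`` long cost one
    gap_open whichever sequence carries them.  This is the aligner for
    folding transcripts into a consensus profile, where a member may
    both skip an exon the profile has (long target gap) and carry an
    exon the profile lacks (long query gap)."""
    scoring = scoring or ScoringScheme()
    lg = scoring.target_gap_free_threshold
    return _align(
        query, target, scoring, min(lg, len(target)) if lg <= len(target) else 0,
        1, query_id, target_id, "+",
        long_gap_q=lg if lg <= len(query) else 0,
    )


def percent_identity(aln: SplicedAlignment) -> float:
    """matches / aligned columns; gaps count in the denominator except
    structural (long) target gaps.  Empty alignment -> 0.0."""
    if aln.aligned_len == 0:
        return 0.0
    return aln.matches / aln.aligned_len


# ---------------------------------------------------------------------------
# Seed-and-extend acceleration for many-queries-vs-one-target alignment
# ---------------------------------------------------------------------------

class TargetIndex:
    """Exact k-mer position index of one target sequence (seed lookup)."""

    def __init__(self, target_id: str, seq: str, k: int = 11):
        self.target_id = target_id
        self.seq = seq
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)
        self._index = index

    def seed_hits(self, query: str) -> list[tuple[int, int]]:
        k = self.k
        hits: list[tuple[int, int]] = []
        for qpos in range(len(query) - k + 1):
            for tpos in self._index.get(query[qpos : qpos + k], ()):
                hits.append((qpos, tpos))
        return hits

    def count_shared(self, query: str) -> int:
        k = self.k
        n = 0
        for qpos in range(0, len(query) - k + 1, k):
            if query[qpos : qpos + k] in self._index:
                n += 1
        return n


def seeded_spliced_align(
    query: str,
    index: TargetIndex,
    scoring: ScoringScheme | None = None,
    *,
    query_id: str = "query",
    pad: int = 50,
) -> SplicedAlignment:
    """Spliced alignment restricted to the target window implied by exact
    k-mer seed hits; returns the empty sentinel when no seed matches."""
    scoring = scoring or ScoringScheme()
    hits = index.seed_hits(query)
    if not hits:
        return SplicedAlignment(
            query_id=query_id, target_id=index.target_id, query_len=len(query)
        )
    lo = max(0, min(t - q for q, t in hits) - pad)
    hi = min(len(index.seq), max(t + (len(query) - q) for q, t in hits) + pad)
    aln = spliced_align(
        query,
        index.seq[lo:hi],
        scoring,
        query_id=query_id,
        target_id=index.target_id,
    )
    if aln.is_empty:
        return aln
    aln.blocks = [(qs, qe, ts + lo, te + lo) for qs, qe, ts, te in aln.blocks]
    return aln
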