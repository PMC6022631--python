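"""Partial-order-alignment (POA) consensus for error-prone fragments.

Sequences are folded one at a time into a DAG whose nodes are bases and
whose edge weights count the reads traversing them; mismatching bases
become alternative nodes of the same column instead of overwriting each
other, and insertions become branch paths.  The consensus is the
heaviest path (maximum total edge weight), which is how indel-heavy
read errors — individually light branches — are voted away.

Alignment of a read to the graph is semi-global (leading/trailing
unaligned read or graph content is free) with linear gap costs, computed
over the topologically sorted nodes by a numba kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BASE_TO_I = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_I_TO_BASE = "ACGTN"

NEG = -(10**8)


@njit(cache=True)
def _poa_align(read, bases, pred_ptr, pred_idx, match, mismatch, gap):  # pragma: no cover
    """Semi-global read-to-DAG alignment.  Nodes are 1..N in topological
    order; pred lists hold topological indices (0 = virtual source).
    Returns (ops_j, ops_i) reversed arrays: (j, i) consumed per step,
    -1 where a side is gapped."""
    n = read.shape[0]
    N = bases.shape[0]
    H = np.zeros((n + 1, N + 1), dtype=np.int32)
    # free leading gaps on both sides: H[0][j] = H[i][0] = 0
    for i in range(1, n + 1):
        ri = read[i - 1]
        for j in range(1, N + 1):
            sub = match if (ri == bases[j - 1] and ri < 4) else mismatch
            best = H[i - 1, j] + gap  # insertion (consume read base)
            p0, p1 = pred_ptr[j - 1], pred_ptr[j]
            if p1 == p0:  # no predecessors: virtual source
                v = H[i - 1, 0] + sub
                if v > best:
                    best = v
                v = H[i, 0] + gap
                if v > best:
                    best = v
            for pi in range(p0, p1):
                p = pred_idx[pi]
                v = H[i - 1, p] + sub
                if v > best:
                    best = v
                v = H[i, p] + gap  # deletion (consume node, no read base)
                if v > best:
                    best = v
            H[i, j] = best
    # free trailing: best over the last read row (graph suffix unaligned)
    # and over the last column of every sink handled via row max
    bi, bj, best = n, 0, NEG
    for j in range(N + 1):
        if H[n, j] > best:
            best = H[n, j]
            bj = j
    ops_j = np.empty(n + N + 2, dtype=np.int64)
    ops_i = np.empty(n + N + 2, dtype=np.int64)
    nops = 0
    i, j = bi, bj
    while i > 0 and j > 0:
        ri = read[i - 1]
        sub = match if (ri == bases[j - 1] and ri < 4) else mismatch
        h = H[i, j]
        p0, p1 = pred_ptr[j - 1], pred_ptr[j]
        moved = False
        # preference: align to an existing node first, then node-skip,
        # then read-insertion — keeps reads on the backbone at ties
        if p1 == p0:
            if h == H[i - 1, 0] + sub:
                ops_j[nops] = j - 1
                ops_i[nops] = i - 1
                nops += 1
                i -= 1
                j = 0
                moved = True
            elif h == H[i, 0] + gap:
                ops_j[nops] = j - 1
                ops_i[nops] = -1
                nops += 1
                j = 0
                moved = True
        else:
            for pi in range(p0, p1):
                p = pred_idx[pi]
                if h == H[i - 1, p] + sub:
                    ops_j[nops] = j - 1
                    ops_i[nops] = i - 1
                    nops += 1
                    i -= 1
                    j = p
                    moved = True
                    break
            if not moved:
                for pi in range(p0, p1):
                    p = pred_idx[pi]
                    if h == H[i, p] + gap:
                        ops_j[nops] = j - 1
                        ops_i[nops] = -1
                        nops += 1
                        j = p
                        moved = True
                        break
        if not moved and h == H[i - 1, j] + gap:
            ops_j[nops] = -1
            ops_i[nops] = i - 1
            nops += 1
            i -= 1
            moved = True
        if not moved:  # boundary: free leading region reached
            break
    # leading unaligned read bases
    while i > 0:
        ops_j[nops] = -1
        ops_i[nops] = i - 1
        nops += 1
        i -= 1
    return ops_j[:nops][::-1].copy(), ops_i[:nops][::-1].copy()


class PoaGraph:
    """Growable POA graph with heaviest-path consensus."""

    def __init__(self, match: int = 2, mismatch: int = -4, gap: int = -4):
        self.match = match
        self.mismatch = mismatch
        self.gap = gap
        self.base: list[int] = []  # per node
        self.col: list[int] = []  # column id per node (mismatch alternatives)
        self.col_nodes: dict[tuple[int, int], int] = {}  # (col, base) -> node
        self.out_edges: dict[int, dict[int, int]] = {}  # u -> {v: weight}
        self.in_edges: dict[int, dict[int, int]] = {}
        self.n_reads = 0
        self._next_col = 0

    # -- construction -----------------------------------------------------

    def _new_node(self, base_i: int, col: int | None = None) -> int:
        nid = len(self.base)
        if col is None:
            col = self._next_col
            self._next_col += 1
        self.base.append(base_i)
        self.col.append(col)
        self.col_nodes[(col, base_i)] = nid
        self.out_edges[nid] = {}
        self.in_edges[nid] = {}
        return nid

    def _add_edge(self, u: int | None, v: int) -> None:
        if u is None:
            return
        self.out_edges[u][v] = self.out_edges[u].get(v, 0) + 1
        self.in_edges[v][u] = self.in_edges[v].get(u, 0) + 1

    def _topo_order(self) -> list[int]:
        indeg = {n: len(self.in_edges[n]) for n in range(len(self.base))}
        # deterministic Kahn: smallest node id first
        import heapq

        heap = [n for n, d in indeg.items() if d == 0]
        heapq.heapify(heap)
        order = []
        while heap:
            u = heapq.heappop(heap)
            order.append(u)
            for v in sorted(self.out_edges[u]):
                indeg[v] -= 1
                if indeg[v] == 0:
                    heapq.heappush(heap, v)
        return order

    def add(self, seq: str) -> None:
        codes = [_BASE_TO_I.get(c, 4) for c in seq]
        if not self.base:
            prev = None
            for b in codes:
                nid = self._new_node(b)
                self._add_edge(prev, nid)
                prev = nid
            self.n_reads = 1
            return
        order = self._topo_order()
        pos_of = {n: k for k, n in enumerate(order)}  # topo position (0-based)
        bases = np.array([self.base[n] for n in order], dtype=np.uint8)
        preds: list[list[int]] = []
        for n in order:
            preds.append(sorted(pos_of[u] + 1 for u in self.in_edges[n]))
        pred_ptr = np.zeros(len(order) + 1, dtype=np.int64)
        for k, p in enumerate(preds):
            pred_ptr[k + 1] = pred_ptr[k] + len(p)
        pred_idx = np.array(
            [x for p in preds for x in p] or [0], dtype=np.int64
        )[: pred_ptr[-1]] if pred_ptr[-1] else np.zeros(0, dtype=np.int64)
        ops_j, ops_i = _poa_align(
            np.array(codes, dtype=np.uint8), bases, pred_ptr, pred_idx,
            self.match, self.mismatch, self.gap,
        )
        prev = None
        for j, i in zip(ops_j, ops_i):
            if i >= 0 and j >= 0:  # (mis)match against node order[j]
                node = order[j]
                if self.base[node] != codes[i]:
                    key = (self.col[node], codes[i])
                    node = self.col_nodes.get(key)
                    if node is None:
                        node = self._new_node(codes[i], self.col[order[j]])
                self._add_edge(prev, node)
                prev = node
            elif i >= 0:  # insertion: new branch node
                node = self._new_node(codes[i])
                self._add_edge(prev, node)
                prev = node
            # j >= 0, i < 0: node deleted by this read: no step
        self.n_reads += 1

    # -- consensus --------------------------------------------------------

    def consensus(self) -> str:
        """Heaviest path by total edge weight (ties: smaller node id),
        then majority-support pruning: a path node is emitted only if the
        number of reads through it is at least half the local coverage
        (total reads leaving the previous kept node).  This removes
        reinforced-but-minority insertion branches."""
        if not self.base:
            return ""
        order = self._topo_order()
        score = {n: 0 for n in order}
        back: dict[int, int | None] = {n: None for n in order}
        for u in order:
            for v, w in self.out_edges[u].items():
                s = score[u] + w
                if s > score[v] or (s == score[v] and (back[v] is None or u < back[v])):
                    score[v] = s
                    back[v] = u
        end = max(order, key=lambda n: (score[n], -n))
        path = []
        node: int | None = end
        while node is not None:
            path.append(node)
            node = back[node]
        path.reverse()

        def through(v: int) -> int:
            return max(
                sum(self.in_edges[v].values()), sum(self.out_edges[v].values()), 1
            )

        # trim short terminal runs of minority support: a read's error-bearing
        # first/last bases form light source/sink chains that the heaviest
        # path (a sum) would otherwise collect.  Long single-coverage tails
        # (genuine overhang content) stay: only runs <= max_trim go.
        max_trim = 15
        core = max(through(v) for v in path)
        lo, hi = 0, len(path)
        while (
            lo < len(path) and lo < max_trim and through(path[lo]) * 2 < core
        ):
            lo += 1
        if lo >= max_trim:
            lo = 0
        while hi > lo and (len(path) - hi) < max_trim and through(path[hi - 1]) * 2 < core:
            hi -= 1
        if len(path) - hi >= max_trim:
            hi = len(path)
        path = path[lo:hi]
        out: list[str] = []
        prev_kept: int | None = None
        for v in path:
            support = sum(self.in_edges[v].values()) or 1  # source node
            if prev_kept is not None:
                local = sum(self.out_edges[prev_kept].values())
                if support * 2 < local:
                    continue
            out.append(_I_TO_BASE[self.base[v]])
            prev_kept = v
        return "".join(out)


def poa_consensus(
    fragments: list[str], match: int = 2, mismatch: int = -4, gap: int = -4
) -> str:
    """POA consensus of fragments in the given order (first fragment seeds
    the backbone; deterministic)."""
    if not fragments:
        raise ValueError("at least one fragment required")
    if len(fragments) == 1:
        return fragments[0]
    graph = PoaGraph(match, mismatch, gap)
    # seed with the longest fragment for a maximal backbone (ties: first)
    seed = max(range(len(fragments)), key=lambda i: len(fragments[i]))
    graph.add(fragments[seed])
    for i, frag in enumerate(fragments):
        if i != seed:
            graph.add(frag)
    return graph.consensus()
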