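"""Greedy k-mer clustering of unaligned long reads into putative genes.

CD-HIT-style greedy pass: reads are homopolymer-compressed, sorted by
descending compressed length, and each read either joins the existing
cluster whose frozen representative shares the largest fraction of its
k-mers (if that fraction reaches ``C_threshold``) or founds a new cluster.
Representative k-mer sets are held in bloom filters so membership queries
are O(1) in the number of stored k-mers.

Homopolymer compression collapses runs of an identical base to one base,
neutralising the dominant indel error mode of third-generation reads
before k-mers are compared.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import SequenceRecord

logger = logging.getLogger(__name__)

_HP_RUN = re.compile(r"(.)\1+")


@dataclass(frozen=True)
class ClusteringParams:
    k: int = 15
    C_threshold: float = 0.05
    bloom_fp_rate: float = 1e-4
    bloom_capacity_factor: float = 1.2
    canonical_kmers: bool = False
    exact_sets: bool = False  # oracle mode: exact k-mer sets beside the blooms

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 31:
            raise ValueError("k must be in [1, 31]")
        if not 0 < self.C_threshold < 1:
            raise ValueError("C_threshold must be in (0, 1)")
        if not 0 < self.bloom_fp_rate < 1:
            raise ValueError("bloom_fp_rate must be in (0, 1)")


def homopolymer_compress(seq: str) -> str:
    """Collapse every maximal run of one base to a single base (idempotent)."""
    return _HP_RUN.sub(r"\1", seq)


# ---------------------------------------------------------------------------
# 2-bit k-mer encoding and a deterministic bloom filter
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode_kmers(seq: str, k: int, canonical: bool = False) -> np.ndarray:
    """Distinct k-mers of ``seq`` as 2-bit-packed uint64 values.

    K-mers containing N (or any non-ACGT base) are dropped.  With
    ``canonical`` each k-mer is replaced by min(kmer, revcomp) so both
    strands collapse.
    """
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.shape[0]
    if n < k:
        warnings.warn(f"sequence shorter than k={k}; empty k-mer set")
        return np.empty(0, dtype=np.uint64)
    valid = codes != 255
    # rolling 2-bit pack over all windows, then mask windows containing N
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    weights = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    packed = (win[ok].astype(np.uint64) * weights).sum(axis=1, dtype=np.uint64)
    if canonical:
        rc = np.zeros_like(packed)
        tmp = packed.copy()
        for _ in range(k):
            rc = (rc << np.uint64(2)) | (np.uint64(3) - (tmp & np.uint64(3)))
            tmp >>= np.uint64(2)
        packed = np.minimum(packed, rc)
    return np.unique(packed)


def kmer_set(seq: str, k: int, canonical: bool = False) -> set[int]:
    """Distinct k-mers as a Python set of packed integers (exact backend)."""
    return set(encode_kmers(seq, k, canonical).tolist())


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    return x ^ (x >> np.uint64(31))


class BloomFilter:
    """Fixed-capacity bloom filter over uint64 items (no false negatives).

    Bit-array size m and hash count h follow the standard optimal formulas
    for the requested capacity and false-positive rate; the h indices per
    item come from double hashing of two splitmix64 streams, so behaviour
    is fully deterministic across processes.
    """

    def __init__(self, capacity: int, fp_rate: float):
        capacity = max(1, int(capacity))
        m = math.ceil(-capacity * math.log(fp_rate) / (math.log(2) ** 2))
        self.m = max(8, m)
        self.h = max(1, round(self.m / capacity * math.log(2)))
        self.bits = np.zeros(self.m, dtype=bool)
        self.n_inserted = 0
        self.capacity = capacity
        self.fp_rate = fp_rate

    def _indices(self, items: np.ndarray) -> np.ndarray:
        h1 = _splitmix64(items)
        h2 = _splitmix64(items ^ np.uint64(0xA5A5A5A5A5A5A5A5)) | np.uint64(1)
        i = np.arange(self.h, dtype=np.uint64)[:, None]
        return ((h1[None, :] + i * h2[None, :]) % np.uint64(self.m)).astype(np.int64)

    def add(self, items: np.ndarray) -> None:
        if items.size == 0:
            return
        self.bits[self._indices(items).ravel()] = True
        self.n_inserted += int(items.size)

    def contains(self, items: np.ndarray) -> np.ndarray:
        if items.size == 0:
            return np.zeros(0, dtype=bool)
        return self.bits[self._indices(items)].all(axis=0)


@dataclass
class Cluster:
    """A putative gene: frozen representative plus members in join order."""

    cluster_id: str
    representative_id: str
    kmer_store: BloomFilter
    exact_kmers: set[int] | None = None
    member_ids: list[str] = field(default_factory=list)


def shared_kmer_fraction(
    query_kmers: np.ndarray, store: BloomFilter | set[int]
) -> float:
    """Fraction of the query's distinct k-mers found in the representative
    store (query-based denominator)."""
    if query_kmers.size == 0:
        warnings.warn("empty query k-mer set; shared fraction defined as 0")
        return 0.0
    if isinstance(store, set):
        hits = sum(1 for x in query_kmers.tolist() if x in store)
        return hits / query_kmers.size
    return float(store.contains(query_kmers).sum()) / query_kmers.size


def cluster_unaligned_lrs(
    lrs: list[SequenceRecord], params: ClusteringParams | None = None
) -> list[Cluster]:
    """Greedy single-pass clustering of long reads by shared-k-mer fraction.

    Reads are processed in descending order of homopolymer-compressed
    length (ties: lexicographic id).  The first read seeds cluster 1; each
    later read joins the argmax cluster if its best shared fraction clears
    ``C_threshold`` (ties: earliest-created cluster), else founds a new
    cluster.  Representatives never change after creation.
    """
    params = params or ClusteringParams()
    if not lrs:
        return []
    compressed = {r.id: homopolymer_compress(r.seq) for r in lrs}
    order = sorted(lrs, key=lambda r: (-len(compressed[r.id]), r.id))
    clusters: list[Cluster] = []
    n_comparisons = 0
    for rec in order:
        kmers = encode_kmers(compressed[rec.id], params.k, params.canonical_kmers)
        best_frac, best_idx = -1.0, -1
        for idx, cl in enumerate(clusters):
            n_comparisons += 1
            store = cl.exact_kmers if params.exact_sets else cl.kmer_store
            frac = shared_kmer_fraction(kmers, store)
            if frac > best_frac:  # strict: ties keep the earliest cluster
                best_frac, best_idx = frac, idx
        if best_idx >= 0 and best_frac >= params.C_threshold:
            clusters[best_idx].member_ids.append(rec.id)
        else:
            bloom = BloomFilter(
                max(1, int(kmers.size * params.bloom_capacity_factor)),
                params.bloom_fp_rate,
            )
            bloom.add(kmers)
            clusters.append(
                Cluster(
                    cluster_id=f"cluster{len(clusters) + 1}",
                    representative_id=rec.id,
                    kmer_store=bloom,
                    exact_kmers=set(kmers.tolist()) if params.exact_sets else None,
                    member_ids=[rec.id],
                )
            )
    logger.info(
        "clustered %d LRs into %d clusters (%d representative comparisons)",
        len(lrs),
        len(clusters),
        n_comparisons,
    )
    return clusters


def clustering_metrics(
    predicted: dict[str, str], truth: dict[str, str]
) -> tuple[float, float, float, float]:
    """Pair-counting (Jaccard, precision, recall, F-measure) of a predicted
    element->label partition against the truth partition.

    Over all unordered element pairs: TP co-clustered in both, FP in
    predicted only, FN in truth only.
    """
    if set(predicted) != set(truth):
        raise ValueError("predicted and truth partitions cover different elements")
    elements = sorted(predicted)
    tp = fp = fn = 0
    for i in range(len(elements)):
        for j in range(i + 1, len(elements)):
            a, b = elements[i], elements[j]
            same_p = predicted[a] == predicted[b]
            same_t = truth[a] == truth[b]
            if same_p and same_t:
                tp += 1
            elif same_p:
                fp += 1
            elif same_t:
                fn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    jaccard = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    f_measure = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return jaccard, precision, recall, f_measure
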