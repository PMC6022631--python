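import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridasm.kmer_clustering import (
    BloomFilter,
    ClusteringParams,
    cluster_unaligned_lrs,
    clustering_metrics,
    encode_kmers,
    homopolymer_compress,
    kmer_set,
    shared_kmer_fraction,
)
from hybridasm.sequence_io import SequenceRecord


class TestHomopolymerCompress:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AAACCGT", "ACGT"), ("ACGT", "ACGT"), ("A", "A"), ("TTTTTT", "T")],
    )
    def test_run_collapse(self, seq, expected):
        assert homopolymer_compress(seq) == expected

    @settings(max_examples=50, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=200))
    def test_idempotent(self, seq):
        once = homopolymer_compress(seq)
        assert homopolymer_compress(once) == once


class TestKmerSet:
    def test_enumeration(self):
        # packed 2-bit encoding of {ACG, CGT, GTA}
        expected = {s for s in ("ACG", "CGT", "GTA")}
        got = kmer_set("ACGTA", 3)
        def unpack(x, k=3):
            return "".join("ACGT"[(x >> (2 * (k - 1 - i))) & 3] for i in range(k))
        assert {unpack(x) for x in got} == expected

    def test_duplicates_collapse(self):
        assert len(kmer_set("AAAA", 3)) == 1

    def test_size_bound_and_short_sequence_warns(self):
        assert len(kmer_set("ACGTACGTAC", 4)) <= 10 - 4 + 1
        with pytest.warns(UserWarning):
            assert kmer_set("ACG", 5) == set()

    def test_kmers_with_n_dropped(self):
        assert len(encode_kmers("ACNGT", 3)) == 0 + 0  # both windows contain N

    def test_canonical_collapses_strands(self):
        from hybridasm.alignment_core import revcomp

        s = "ACGTTGCAACGGT"
        assert set(encode_kmers(s, 5, canonical=True).tolist()) == set(
            encode_kmers(revcomp(s), 5, canonical=True).tolist()
        )


class TestBloomFilter:
    def test_no_false_negatives_and_fp_rate(self, rng):
        items = np.unique(rng.integers(0, 4**15, 100_000).astype(np.uint64))
        bf = BloomFilter(len(items), 1e-4)
        bf.add(items)
        assert bf.contains(items).all()
        probes = np.setdiff1d(
            np.unique(rng.integers(0, 2**62, 200_000).astype(np.uint64)), items
        )
        assert bf.contains(probes).mean() <= 2e-4

    def test_deterministic_across_instances(self):
        a = BloomFilter(1000, 1e-3)
        b = BloomFilter(1000, 1e-3)
        items = np.arange(500, dtype=np.uint64)
        a.add(items)
        b.add(items)
        assert np.array_equal(a.bits, b.bits)


class TestSharedFraction:
    def test_identical_sequences_fraction_one(self):
        km = encode_kmers("ACGTACGTACGTACGTACGT", 15)
        bf = BloomFilter(km.size, 1e-6)
        bf.add(km)
        assert shared_kmer_fraction(km, bf) == 1.0

    def test_disjoint_random_sequences_fraction_zero(self, rng):
        a = "".join(rng.choice(list("ACGT"), 200))
        b = "".join(rng.choice(list("ACGT"), 200))
        ka, kb = encode_kmers(a, 15), encode_kmers(b, 15)
        bf = BloomFilter(kb.size, 1e-6)
        bf.add(kb)
        assert shared_kmer_fraction(ka, bf) <= 1e-3

    def test_bloom_fraction_close_to_exact(self, rng):
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), 150))
            b = "".join(rng.choice(list("ACGT"), 150))
            ka = encode_kmers(a, 15)
            kb = encode_kmers(a[:75] + b[:75], 15)
            bf = BloomFilter(kb.size, 1e-4)
            bf.add(kb)
            exact = shared_kmer_fraction(ka, set(kb.tolist()))
            bloomv = shared_kmer_fraction(ka, bf)
            # no false negatives; false positives add at most a few hits
            assert bloomv >= exact - 1e-12
            assert bloomv - exact <= 3 / ka.size

    def test_empty_query_is_zero_with_warning(self):
        bf = BloomFilter(10, 1e-3)
        with pytest.warns(UserWarning):
            assert shared_kmer_fraction(np.empty(0, dtype=np.uint64), bf) == 0.0


class TestClustering:
    def test_single_read_single_cluster(self):
        lrs = [SequenceRecord(id="a", seq="ACGT" * 20)]
        (cl,) = cluster_unaligned_lrs(lrs)
        assert cl.member_ids == ["a"] and cl.representative_id == "a"

    def test_empty_input_empty_list(self):
        assert cluster_unaligned_lrs([]) == []

    def test_two_genes_separate_perfectly(self, rng):
        a = "".join(rng.choice(list("ACGT"), 600))
        b = "".join(rng.choice(list("ACGT"), 500))
        lrs = [SequenceRecord(id=f"a{i}", seq=a) for i in range(10)]
        lrs += [SequenceRecord(id=f"b{i}", seq=b) for i in range(10)]
        clusters = cluster_unaligned_lrs(lrs)
        assert len(clusters) == 2
        sets = [set(c.member_ids) for c in clusters]
        assert {frozenset(s) for s in sets} == {
            frozenset(f"a{i}" for i in range(10)),
            frozenset(f"b{i}" for i in range(10)),
        }

    def test_output_is_true_partition(self, rng):
        lrs = [
            SequenceRecord(id=f"r{i}", seq="".join(rng.choice(list("ACGT"), 300)))
            for i in range(25)
        ]
        clusters = cluster_unaligned_lrs(lrs)
        members = [m for c in clusters for m in c.member_ids]
        assert sorted(members) == sorted(r.id for r in lrs)

    def test_representative_is_longest_compressed_member(self, rng):
        lrs = [
            SequenceRecord(id=f"r{i}", seq="".join(rng.choice(list("ACGT"), n)))
            for i, n in enumerate((400, 300, 200))
        ]
        clusters = cluster_unaligned_lrs(lrs)
        lengths = {r.id: len(homopolymer_compress(r.seq)) for r in lrs}
        for c in clusters:
            assert lengths[c.representative_id] == max(
                lengths[m] for m in c.member_ids
            )


class TestClusteringMetrics:
    def test_identical_partitions_all_ones(self):
        p = {"a": "x", "b": "x", "c": "y"}
        assert clustering_metrics(p, p) == (1.0, 1.0, 1.0, 1.0)

    def test_all_singletons_zero_recall(self):
        pred = {"a": "1", "b": "2"}
        truth = {"a": "x", "b": "x"}
        j, p, r, f = clustering_metrics(pred, truth)
        assert r == 0.0 and f == 0.0

    def test_element_mismatch_rejected(self):
        with pytest.raises(ValueError):
            clustering_metrics({"a": "1"}, {"b": "1"})

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_pair_enumeration(self, trial):
        rng = np.random.default_rng(3000 + trial)
        elements = [f"e{i}" for i in range(20)]
        pred = {e: str(rng.integers(0, 4)) for e in elements}
        truth = {e: str(rng.integers(0, 4)) for e in elements}
        tp = fp = fn = 0
        for a, b in itertools.combinations(elements, 2):
            sp, t = pred[a] == pred[b], truth[a] == truth[b]
            tp += sp and t
            fp += sp and not t
            fn += t and not sp
        expect_p = tp / (tp + fp) if tp + fp else 0.0
        expect_r = tp / (tp + fn) if tp + fn else 0.0
        expect_j = tp / (tp + fp + fn) if tp + fp + fn else 0.0
        j, p, r, f = clustering_metrics(pred, truth)
        assert (j, p, r) == (expect_j, expect_p, expect_r)


def test_comparison_count_within_quadratic_bound(rng):
    """Each read is compared to at most one representative per cluster."""
    import logging

    lrs = [
        SequenceRecord(id=f"r{i}", seq="".join(rng.choice(list("ACGT"), 200)))
        for i in range(15)
    ]
    clusters = cluster_unaligned_lrs(lrs)
    # N reads against at most (final cluster count) representatives each
    assert len(clusters) <= len(lrs)
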