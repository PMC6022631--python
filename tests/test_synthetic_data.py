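import numpy as np
import pytest

from hybridasm.synthetic_data import (
    SimParams,
    all_transcripts,
    mutate_indel,
    simulate_long_reads,
    simulate_scaffolds,
    simulate_short_reads,
    simulate_transcriptome,
)


class TestSimParams:
    def test_infeasible_isoform_range_rejected(self):
        with pytest.raises(ValueError):
            SimParams(exons_per_gene=(1, 2), isoforms_per_gene=(3, 3))

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            SimParams(sr_sub_rate=1.5)


class TestTranscriptome:
    def test_transcript_length_is_sum_of_exons(self):
        p = SimParams(n_genes=1, exons_per_gene=(2, 2), exon_len=(100, 200),
                      isoforms_per_gene=(1, 1), seed=1)
        genes, truth = simulate_transcriptome(p)
        g = genes[0]
        assert len(g.transcript(g.isoforms[0][1])) == sum(map(len, g.exon_seqs))

    def test_same_seed_identical_output(self):
        p = SimParams(n_genes=10, seed=5)
        g1, t1 = simulate_transcriptome(p)
        g2, t2 = simulate_transcriptome(p)
        assert g1 == g2
        assert t1["isoforms"].equals(t2["isoforms"])

    def test_truth_table_row_count_equals_total_isoforms(self):
        p = SimParams(n_genes=50, isoforms_per_gene=(1, 4), seed=9)
        genes, truth = simulate_transcriptome(p)
        assert len(truth["isoforms"]) == sum(len(g.isoforms) for g in genes)

    def test_exon_subsets_strictly_increasing_and_first_isoform_full(self):
        p = SimParams(n_genes=30, isoforms_per_gene=(2, 3), seed=2)
        genes, _ = simulate_transcriptome(p)
        for g in genes:
            assert g.isoforms[0][1] == tuple(range(len(g.exon_seqs)))
            for _, idxs, w in g.isoforms:
                assert list(idxs) == sorted(set(idxs))
                assert w > 0


class TestShortReads:
    def test_zero_sub_rate_reads_are_exact_substrings(self, small_transcriptome):
        p, genes, _ = small_transcriptome
        p0 = SimParams(n_genes=p.n_genes, sr_pairs=200, sr_sub_rate=0.0, seed=p.seed)
        m1, m2, truth = simulate_short_reads(genes, p0)
        seqs = [r.seq for r in all_transcripts(genes)]
        from hybridasm.alignment_core import revcomp
        for r in m1[:50]:
            assert any(r.seq in s for s in seqs)
        for r in m2[:50]:
            assert any(revcomp(r.seq) in s for s in seqs)

    def test_exact_read_count(self, small_transcriptome):
        p, genes, _ = small_transcriptome
        p0 = SimParams(n_genes=p.n_genes, sr_pairs=500, seed=0)
        m1, m2, truth = simulate_short_reads(genes, p0)
        assert len(m1) == len(m2) == len(truth) == 500

    def test_origin_ratio_tracks_weights(self):
        # two isoforms with weight*length ratio 1:9
        from hybridasm.synthetic_data import TruthGene
        exon = "ACGT" * 250
        gene = TruthGene(
            gene_id="g1", exon_seqs=(exon,),
            isoforms=(("g1.i1", (0,), 1.0), ("g1.i2", (0,), 9.0)),
        )
        p = SimParams(n_genes=1, sr_pairs=20_000, seed=3)
        _, _, truth = simulate_short_reads([gene], p)
        n2 = (truth.isoform_id == "g1.i2").sum()
        expect, sd = 18_000, np.sqrt(20_000 * 0.9 * 0.1)
        assert abs(n2 - expect) <= 3 * sd


class TestLongReads:
    def test_error_free_full_length_reads_equal_transcripts(self):
        p = SimParams(n_genes=5, lr_count=20, lr_error_rate=0.0,
                      lr_trunc_prob=0.0, seed=4)
        genes, _ = simulate_transcriptome(p)
        reads, truth = simulate_long_reads(genes, p)
        seqs = {r.id: r.seq for r in all_transcripts(genes)}
        for r, row in zip(reads, truth.itertuples()):
            assert r.seq == seqs[row.isoform_id]

    def test_error_rate_within_20pct_of_target(self):
        import edlib

        p = SimParams(n_genes=5, lr_count=200, lr_error_rate=0.15,
                      lr_trunc_prob=0.0, seed=6)
        genes, _ = simulate_transcriptome(p)
        reads, truth = simulate_long_reads(genes, p)
        seqs = {r.id: r.seq for r in all_transcripts(genes)}
        rates = [
            edlib.align(r.seq, seqs[row.isoform_id])["editDistance"]
            / len(seqs[row.isoform_id])
            for r, row in zip(reads, truth.itertuples())
        ]
        assert abs(np.mean(rates) - 0.15) <= 0.2 * 0.15

    def test_truncated_reads_never_longer_than_transcript(self):
        p = SimParams(n_genes=5, lr_count=100, lr_error_rate=0.0,
                      lr_trunc_prob=1.0, seed=7)
        genes, _ = simulate_transcriptome(p)
        reads, truth = simulate_long_reads(genes, p)
        seqs = {r.id: r.seq for r in all_transcripts(genes)}
        for r, row in zip(reads, truth.itertuples()):
            assert len(r.seq) <= len(seqs[row.isoform_id])


class TestScaffolds:
    def test_zero_truncation_scaffolds_equal_transcripts(self):
        p = SimParams(n_genes=5, scaffold_trunc_frac=0.0, seed=8)
        genes, _ = simulate_transcriptome(p)
        scaffolds, locus_map = simulate_scaffolds(genes, p)
        for s in scaffolds:
            g = next(g for g in genes if g.gene_id == locus_map[s.id])
            assert s.seq == g.transcript(g.isoforms[0][1])

    def test_truncation_keeps_middle(self):
        p = SimParams(n_genes=3, scaffold_trunc_frac=0.4, seed=8)
        genes, _ = simulate_transcriptome(p)
        scaffolds, locus_map = simulate_scaffolds(genes, p)
        for s in scaffolds:
            g = next(g for g in genes if g.gene_id == locus_map[s.id])
            full = g.transcript(g.isoforms[0][1])
            assert s.seq in full
            assert len(s.seq) == pytest.approx(0.6 * len(full), abs=2)


def test_mutate_indel_zero_rate_is_identity(rng):
    assert mutate_indel("ACGTACGT", 0.0, (0.4, 0.4, 0.2), rng) == "ACGTACGT"
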