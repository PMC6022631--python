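import numpy as np
import pytest

from hybridasm.alignment_core import ScoringScheme, spliced_align
from hybridasm.scaffold_extension import (
    ExtensionParams,
    GeneGroup,
    OverhangFragment,
    build_overhang_consensus,
    classify_alignment,
    extend_scaffold,
    extract_overhangs,
    group_members,
)
from hybridasm.sequence_io import LocusAssignment, SequenceRecord
from hybridasm.synthetic_data import mutate_indel


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def make_aln(lr_seq, scaffold_seq, lr_id="lr", sid="s"):
    return spliced_align(lr_seq, scaffold_seq, query_id=lr_id, target_id=sid)


class TestClassifyAlignment:
    def test_spanning_read_with_both_overhangs(self, rng):
        scaf = random_dna(rng, 500)
        lr = random_dna(rng, 200) + scaf + random_dna(rng, 200)
        aln = make_aln(lr, scaf)
        assert classify_alignment(aln, 500) == "both_overhangs"

    def test_interior_read_is_contained(self, rng):
        scaf = random_dna(rng, 600)
        aln = make_aln(scaf[150:450], scaf)
        assert classify_alignment(aln, 600) == "contained"

    def test_overhang_below_min_is_contained(self, rng):
        scaf = random_dna(rng, 500)
        lr = random_dna(rng, 40) + scaf  # 40 < min_overhang 50
        aln = make_aln(lr, scaf)
        assert classify_alignment(aln, 500) == "contained"

    def test_low_identity_alignment_unaligned(self, rng):
        scaf = random_dna(rng, 300)
        junk = random_dna(rng, 300)
        aln = make_aln(junk, scaf)
        assert classify_alignment(aln, 300) == "unaligned"

    def test_one_sided_overhangs(self, rng):
        scaf = random_dna(rng, 500)
        left = random_dna(rng, 120) + scaf
        right = scaf + random_dna(rng, 120)
        assert classify_alignment(make_aln(left, scaf), 500) == "left_overhang"
        assert classify_alignment(make_aln(right, scaf), 500) == "right_overhang"


class TestExtractOverhangs:
    def test_fragments_carry_the_unaligned_portions(self, rng):
        scaf = SequenceRecord(id="s", seq=random_dna(rng, 400))
        ext_l, ext_r = random_dna(rng, 150), random_dna(rng, 130)
        lr = SequenceRecord(id="lr", seq=ext_l + scaf.seq + ext_r)
        aln = make_aln(lr.seq, scaf.seq)
        frags = extract_overhangs(aln, lr, scaf)
        by_end = {f.end: f.seq for f in frags}
        assert set(by_end) == {"left", "right"}
        assert by_end["left"] == ext_l and by_end["right"] == ext_r


class TestOverhangConsensus:
    def test_single_fragment_verbatim(self):
        f = OverhangFragment("s", "right", "ACGTACGT", "lr1")
        assert build_overhang_consensus([f]) == "ACGTACGT"

    def test_error_free_copies_exact(self, rng):
        seq = random_dna(rng, 300)
        frags = [OverhangFragment("s", "right", seq, f"lr{i}") for i in range(5)]
        assert build_overhang_consensus(frags) == seq

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_overhang_consensus([])

    def test_mixed_ends_rejected(self):
        frags = [
            OverhangFragment("s", "left", "ACGTACGT", "a"),
            OverhangFragment("s", "right", "ACGTACGT", "b"),
        ]
        with pytest.raises(ValueError):
            build_overhang_consensus(frags)

    def test_noisy_fragments_recover_truth(self, rng):
        import edlib

        truth = random_dna(rng, 300)
        for end in ("left", "right"):
            frags = [
                OverhangFragment(
                    "s", end, mutate_indel(truth, 0.10, (0.4, 0.4, 0.2), rng), f"l{i}"
                )
                for i in range(7)
            ]
            cons = build_overhang_consensus(frags)
            assert 1 - edlib.align(cons, truth)["editDistance"] / 300 >= 0.98


class TestExtendScaffold:
    def test_no_overhangs_unchanged(self):
        s = SequenceRecord(id="s", seq="ACGT" * 50)
        assert extend_scaffold(s).seq == s.seq

    def test_length_additivity_and_substring_invariant(self, rng):
        s = SequenceRecord(id="s", seq=random_dna(rng, 500))
        left, right = random_dna(rng, 100), random_dna(rng, 80)
        ext = extend_scaffold(s, left, right)
        assert len(ext.seq) == 680
        assert s.seq in ext.seq
        assert ext.seq.startswith(left) and ext.seq.endswith(right)


class TestGroupMembers:
    def _aln(self, lr_id, sid, score, aligned_len=200):
        from hybridasm.alignment_core import SplicedAlignment

        return SplicedAlignment(
            query_id=lr_id, target_id=sid, score=score,
            aligned_len=aligned_len, matches=aligned_len,
            blocks=[(0, aligned_len, 0, aligned_len)],
        )

    def test_scaffolds_sharing_locus_form_one_group(self):
        locus = [LocusAssignment("s1", "L1"), LocusAssignment("s2", "L1")]
        accepted = {f"lr{i}": [self._aln(f"lr{i}", "s1", 100)] for i in range(3)}
        groups = group_members(locus, accepted, ["s1", "s2"])
        assert len(groups) == 1
        assert set(groups[0].scaffold_ids) == {"s1", "s2"}
        assert len(groups[0].lr_ids) == 3

    def test_lr_joins_best_scoring_locus_only(self):
        locus = [LocusAssignment("s1", "L1"), LocusAssignment("s2", "L2")]
        accepted = {"lr1": [self._aln("lr1", "s1", 100), self._aln("lr1", "s2", 150)]}
        groups = group_members(locus, accepted, ["s1", "s2"])
        by_locus = {g.locus_id: g.lr_ids for g in groups}
        assert by_locus == {"L1": [], "L2": ["lr1"]}

    def test_score_tie_breaks_on_length_then_id(self):
        locus = [LocusAssignment("s1", "L1"), LocusAssignment("s2", "L2")]
        accepted = {
            "lr1": [self._aln("lr1", "s2", 100, 150), self._aln("lr1", "s1", 100, 150)]
        }
        groups = group_members(locus, accepted, ["s1", "s2"])
        by_locus = {g.locus_id: g.lr_ids for g in groups}
        assert by_locus["L1"] == ["lr1"]  # lexicographic s1 < s2

    def test_unmapped_scaffold_forms_singleton_locus(self):
        groups = group_members([], {}, ["sX"])
        assert groups[0].locus_id == "sX" and groups[0].scaffold_ids == ["sX"]


def test_consensus_permutation_stable_for_error_free_input(rng):
    seq = "".join(rng.choice(list("ACGT"), 200))
    frags = [OverhangFragment("s", "right", seq, f"l{i}") for i in range(4)]
    import itertools

    results = {
        build_overhang_consensus(list(p))
        for p in itertools.permutations(frags, 4)
    }
    assert results == {seq}
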