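import numpy as np
import pytest

from hybridasm.alignment_core import SplicedAlignment
from hybridasm.isoform_annotation import AnnotationParams, IsoformAnnotation
from hybridasm.quantification import (
    SegmentModel,
    build_segment_model,
    lr_abundance,
    lr_supports_isoform,
    poisson_loglik,
    sr_abundance_mle,
)


def iso(tid, blocks, cid="c1"):
    return IsoformAnnotation(cluster_id=cid, transcript_id=tid, blocks=blocks)


def sr(start, qid="r", end=None):
    end = end if end is not None else start + 100
    n = end - start
    return SplicedAlignment(
        query_id=qid, target_id="c1", blocks=[(0, n, start, end)],
        matches=n, aligned_len=n,
    )


class TestSegmentModel:
    def test_single_isoform_single_segment(self):
        m = build_segment_model([iso("i1", [(0, 1000)])], [sr(10), sr(500)], 2)
        assert m.segments == [(0, 1000)]
        assert m.lengths.tolist() == [1000.0]
        assert m.counts.tolist() == [2]

    def test_skipped_exon_gives_three_segments(self):
        isos = [iso("i1", [(0, 900)]), iso("i2", [(0, 300), (500, 900)])]
        m = build_segment_model(isos, [], 0)
        assert m.segments == [(0, 300), (300, 500), (500, 900)]
        assert m.A.tolist() == [[1, 1], [1, 0], [1, 1]]

    @pytest.mark.parametrize("trial", range(10))
    def test_segments_match_bruteforce_boundary_enumeration(self, trial):
        rng = np.random.default_rng(5000 + trial)
        isos = []
        for i in range(3):
            bounds = sorted(rng.choice(np.arange(0, 500, 10), 4, replace=False))
            isos.append(iso(f"i{i}", [(int(bounds[0]), int(bounds[1])),
                                      (int(bounds[2]), int(bounds[3]))]))
        m = build_segment_model(isos, [], 0)
        # brute force: all boundary-adjacent intervals covered by >= 1 isoform
        bs = sorted({b for it in isos for s, e in it.blocks for b in (s, e)})
        expect = []
        for s, e in zip(bs[:-1], bs[1:]):
            if s < e and any(
                any(bs2 <= s and e <= be for bs2, be in it.blocks) for it in isos
            ):
                expect.append((s, e))
        assert m.segments == expect

    def test_read_assigned_by_leftmost_aligned_base(self):
        isos = [iso("i1", [(0, 200)])]
        m = build_segment_model(isos, [sr(0), sr(99, end=150)], 2)
        assert m.counts.tolist() == [2]


class TestSrAbundanceMle:
    def test_single_isoform_closed_form_rpkm(self):
        m = SegmentModel(
            "c1", ["i1"], [(0, 1000)], np.ones((1, 1)),
            np.array([1000.0]), np.array([200]), 10**6,
        )
        rpkm, theta = sr_abundance_mle(m)
        assert rpkm["i1"] == pytest.approx(200.0, rel=1e-9)
        assert theta["i1"] == pytest.approx(0.2, rel=1e-9)

    def test_all_zero_counts_zero_vector(self):
        m = SegmentModel(
            "c1", ["i1", "i2"], [(0, 100), (100, 200)],
            np.array([[1.0, 1.0], [1.0, 0.0]]),
            np.array([100.0, 100.0]), np.array([0, 0]), 100,
        )
        rpkm, _ = sr_abundance_mle(m)
        assert rpkm == {"i1": 0.0, "i2": 0.0}

    def test_single_isoform_mle_is_total_counts_over_total_length(self):
        m = SegmentModel(
            "c1", ["i1"], [(0, 300), (300, 1000)], np.ones((2, 1)),
            np.array([300.0, 700.0]), np.array([60, 140]), 10**6,
        )
        _, theta = sr_abundance_mle(m)
        assert theta["i1"] == pytest.approx(200 / 1000, rel=1e-8)

    def test_rpkm_scale_invariance(self):
        A = np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        L = np.array([300.0, 200.0, 400.0])
        c = np.array([90, 20, 120])
        m1 = SegmentModel("c", ["a", "b"], [(0, 300), (300, 500), (500, 900)],
                          A, L, c, 1000)
        m2 = SegmentModel("c", ["a", "b"], [(0, 300), (300, 500), (500, 900)],
                          A, L, 2 * c, 2000)
        r1, _ = sr_abundance_mle(m1)
        r2, _ = sr_abundance_mle(m2)
        for k in r1:
            assert r1[k] == pytest.approx(r2[k], rel=1e-4)

    def test_loglik_nondecreasing_over_em_iterations(self):
        rng = np.random.default_rng(0)
        A = np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        L = np.array([300.0, 200.0, 400.0])
        c = rng.poisson(L * (A @ np.array([0.2, 0.5])))
        m = SegmentModel("c", ["a", "b"], [(0, 300), (300, 500), (500, 900)],
                         A, L, c, 10**6)
        # manual EM replay asserting monotonicity
        denom = A.T @ L
        theta = np.full(2, c.sum() / L.sum() / 2)
        prev = poisson_loglik(m, theta)
        for _ in range(200):
            lam = A @ theta
            resp = A * theta[None, :] / np.maximum(lam, 1e-300)[:, None]
            theta = (resp * c[:, None]).sum(axis=0) / denom
            cur = poisson_loglik(m, theta)
            assert cur >= prev - 1e-9
            prev = cur


class TestLrAbundance:
    def _lr(self, blocks, qid="lr1"):
        n = sum(e - s for s, e, *_ in [(b[0], b[1]) for b in blocks])
        return SplicedAlignment(query_id=qid, target_id="c1", blocks=blocks,
                                matches=n, aligned_len=n)

    def test_full_length_read_supports_matching_isoform(self):
        i1 = iso("i1", [(0, 500)])
        aln = self._lr([(0, 500, 0, 500)])
        assert lr_supports_isoform(aln, i1, AnnotationParams())

    def test_read_spanning_skipped_exon_does_not_support_skipper(self):
        # isoform skips (200, 300); read aligns straight through it
        i2 = iso("i2", [(0, 200), (300, 500)])
        aln = self._lr([(0, 500, 0, 500)])
        assert not lr_supports_isoform(aln, i2, AnnotationParams())

    def test_read_with_matching_gap_supports_skipper_not_full(self):
        i1 = iso("i1", [(0, 500)])
        i2 = iso("i2", [(0, 200), (300, 500)])
        aln = self._lr([(0, 200, 0, 200), (200, 400, 300, 500)])
        params = AnnotationParams()
        assert lr_supports_isoform(aln, i2, params)
        assert not lr_supports_isoform(aln, i1, params)

    def test_counts_bounded_by_lr_total(self):
        i1 = iso("i1", [(0, 500)])
        alns = [self._lr([(0, 500, 0, 500)], qid=f"lr{i}") for i in range(7)]
        counts = lr_abundance([i1], alns)
        assert counts["i1"] == 7

    def test_truncated_read_supports_both_compatible_isoforms(self):
        i1 = iso("i1", [(0, 500)])
        i2 = iso("i2", [(0, 200), (300, 500)])
        aln = self._lr([(0, 150, 0, 150)])  # within shared first exon
        params = AnnotationParams()
        assert lr_supports_isoform(aln, i1, params)
        assert lr_supports_isoform(aln, i2, params)
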