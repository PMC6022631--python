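"""Dual transcript abundance indices.

Short-read index: the pseudo-reference of a cluster is cut into segments
at the union of all isoform block boundaries; read starts per segment are
modelled as Poisson with rate L_s * sum_i A[s,i] * theta_i, where theta_i
is isoform i's read density (reads per base).  The maximum-likelihood
theta is found by EM (monotone in the log-likelihood) and reported as
RPKM (reads per kilobase per million mapped reads).

Long-read index: the number of long reads compatible with an isoform —
every sufficiently long target gap of the read's alignment matches one of
the isoform's gaps, and the read's aligned span stays inside the
isoform's blocks.  One read may support several isoforms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .alignment_core import SplicedAlignment
from .isoform_annotation import AnnotationParams, IsoformAnnotation, _fused_blocks

logger = logging.getLogger(__name__)


@dataclass
class SegmentModel:
    """Segment decomposition of one pseudo-reference for deconvolution."""

    cluster_id: str
    isoform_ids: list[str]
    segments: list[tuple[int, int]]  # tiling of the annotated span, no overlap
    A: np.ndarray  # (n_segments, n_isoforms) membership, 0/1
    lengths: np.ndarray  # L_s in bp
    counts: np.ndarray  # observed SR start counts c_s
    total_mapped: int  # M

    def __post_init__(self) -> None:
        assert self.A.shape == (len(self.segments), len(self.isoform_ids))
        assert (self.counts >= 0).all()


def build_segment_model(
    isoforms: list[IsoformAnnotation],
    sr_alignments: list[SplicedAlignment],
    total_mapped: int,
) -> SegmentModel:
    """Cut the pseudo-reference at the union of isoform block boundaries.

    A segment belongs to isoform i iff it lies inside one of i's blocks;
    segments inside no isoform are dropped.  Each short read is counted in
    the segment containing its leftmost aligned base.  ``total_mapped`` is
    the run-wide number M of mapped short reads (RPKM denominator).
    """
    if not isoforms:
        raise ValueError("no isoforms to model")
    cluster_id = isoforms[0].cluster_id
    bounds = sorted({b for iso in isoforms for s, e in iso.blocks for b in (s, e)})
    segments: list[tuple[int, int]] = []
    rows: list[list[int]] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e <= s:
            warnings.warn(f"cluster {cluster_id}: zero-length segment at {s} dropped")
            continue
        member = [
            1 if any(bs <= s and e <= be for bs, be in iso.blocks) else 0
            for iso in isoforms
        ]
        if any(member):
            segments.append((s, e))
            rows.append(member)
    A = np.array(rows, dtype=np.float64)
    lengths = np.array([e - s for s, e in segments], dtype=np.float64)
    counts = np.zeros(len(segments), dtype=np.int64)
    starts = np.array(
        [aln.t_start for aln in sr_alignments if not aln.is_empty], dtype=np.int64
    )
    for i, (s, e) in enumerate(segments):
        counts[i] = int(((starts >= s) & (starts < e)).sum())
    return SegmentModel(
        cluster_id=cluster_id,
        isoform_ids=[iso.transcript_id for iso in isoforms],
        segments=segments,
        A=A,
        lengths=lengths,
        counts=counts,
        total_mapped=total_mapped,
    )


def poisson_loglik(model: SegmentModel, theta: np.ndarray) -> float:
    """Poisson log-likelihood (up to the c_s! constant)."""
    lam = model.lengths * (model.A @ theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(model.counts > 0, model.counts * np.log(lam), 0.0)
    if np.any((lam == 0) & (model.counts > 0)):
        return -np.inf
    return float((term - lam).sum())


def sr_abundance_mle(
    model: SegmentModel,
    *,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[dict[str, float], dict[str, float]]:
    """EM maximum-likelihood estimate of per-isoform read density.

    Returns (RPKM per isoform, theta per isoform).  theta_i is in reads
    per base; RPKM_i = theta_i * 1e9 / M.  The EM update

        theta_i <- sum_s A[s,i] c_s r[s,i] / sum_s A[s,i] L_s,
        r[s,i] = theta_i / sum_j A[s,j] theta_j

    never decreases the log-likelihood.  All-zero counts return zeros
    without iterating.
    """
    n_iso = len(model.isoform_ids)
    if model.counts.sum() == 0 or model.total_mapped == 0:
        zero = {tid: 0.0 for tid in model.isoform_ids}
        return zero, dict(zero)
    denom = model.A.T @ model.lengths  # total length of each isoform's segments
    theta = np.full(n_iso, model.counts.sum() / model.lengths.sum() / n_iso)
    ll = poisson_loglik(model, theta)
    for _ in range(max_iter):
        lam_density = model.A @ theta  # per-segment total density
        with np.errstate(divide="ignore", invalid="ignore"):
            resp = np.where(
                (model.A * theta[None, :]) > 0,
                model.A * theta[None, :] / np.maximum(lam_density, 1e-300)[:, None],
                0.0,
            )
        theta_new = (resp * model.counts[:, None]).sum(axis=0) / np.maximum(
            denom, 1e-300
        )
        ll_new = poisson_loglik(model, theta_new)
        theta = theta_new
        if ll_new - ll <= tol * max(1.0, abs(ll)):
            ll = ll_new
            break
        ll = ll_new
    # EM is monotone but linearly convergent; finish with a bounded
    # quasi-Newton step to reach the stationary point tightly
    res = optimize.minimize(
        lambda th: -poisson_loglik(model, th),
        theta,
        jac=lambda th: -(
            model.A.T @ (model.counts / np.maximum(model.A @ th, 1e-300))
            - denom
        ),
        bounds=[(1e-12, None)] * n_iso,
        method="L-BFGS-B",
        options={"ftol": 1e-15, "gtol": 1e-10},
    )
    if np.isfinite(res.fun) and -res.fun >= ll:
        theta = np.maximum(res.x, 0.0)
    rpkm = {
        tid: float(theta[i] * 1e9 / model.total_mapped)
        for i, tid in enumerate(model.isoform_ids)
    }
    return rpkm, {tid: float(theta[i]) for i, tid in enumerate(model.isoform_ids)}


def _span_within(
    span: tuple[int, int], blocks: list[tuple[int, int]], slack: int
) -> bool:
    """Aligned span lies inside the isoform's block envelope (terminal
    slack allowed)."""
    return span[0] >= blocks[0][0] - slack and span[1] <= blocks[-1][1] + slack


def lr_supports_isoform(
    aln: SplicedAlignment,
    isoform: IsoformAnnotation,
    params: AnnotationParams,
) -> bool:
    """A long read supports an isoform iff every target gap >= min_gap_len
    in its alignment matches one of the isoform's gaps within
    boundary_slack, its aligned span lies within the isoform's envelope,
    and it does not span across content the isoform skips."""
    if aln.is_empty:
        return False
    read_blocks = _fused_blocks(aln, params.min_gap_len)
    iso_gaps = [
        (isoform.blocks[i][1], isoform.blocks[i + 1][0])
        for i in range(len(isoform.blocks) - 1)
    ]
    read_gaps = [
        (read_blocks[i][1], read_blocks[i + 1][0])
        for i in range(len(read_blocks) - 1)
    ]
    if not _span_within(
        (read_blocks[0][0], read_blocks[-1][1]), isoform.blocks, params.boundary_slack
    ):
        return False
    for gs, ge in read_gaps:
        if not any(
            abs(gs - igs) <= params.boundary_slack
            and abs(ge - ige) <= params.boundary_slack
            for igs, ige in iso_gaps
        ):
            return False
    # the read must not align across a gap the isoform has: any isoform gap
    # interior to the read span must be matched by a read gap
    for igs, ige in iso_gaps:
        if read_blocks[0][0] < igs and ige < read_blocks[-1][1]:
            if not any(
                abs(gs - igs) <= params.boundary_slack
                and abs(ge - ige) <= params.boundary_slack
                for gs, ge in read_gaps
            ):
                return False
    return True


def lr_abundance(
    isoforms: list[IsoformAnnotation],
    lr_alignments: list[SplicedAlignment],
    params: AnnotationParams | None = None,
) -> dict[str, int]:
    """Supporting-long-read count per isoform (one read may support
    several isoforms; integer counting)."""
    params = params or AnnotationParams()
    counts = {iso.transcript_id: 0 for iso in isoforms}
    for aln in lr_alignments:
        for iso in isoforms:
            if lr_supports_isoform(aln, iso, params):
                counts[iso.transcript_id] += 1
    return counts


@dataclass
class AbundanceRecord:
    transcript_id: str
    cluster_id: str
    sr_index: float  # RPKM
    lr_index: int

    def __post_init__(self) -> None:
        if self.sr_index < 0 or self.lr_index < 0:
            raise ValueError("abundance indices must be non-negative")
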