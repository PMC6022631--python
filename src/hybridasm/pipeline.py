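"""End-to-end orchestration: assembly augmentation -> annotation -> quantification.

The pipeline takes pre-assembled short-read scaffolds (with an optional
scaffold -> locus map), long reads and short reads, and produces extended
scaffolds, gene clusters, pseudo-references, alternative-exon events,
isoform annotations (GFF3) and the two abundance indices, plus a JSON run
manifest.  Short-read-only assembly is an external precondition; the
``simulate`` entry point manufactures every input from a synthetic
transcriptome so the full pipeline runs with no external tools.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .alignment_core import (
    ScoringScheme,
    SplicedAlignment,
    TargetIndex,
    revcomp,
    seeded_spliced_align,
    spliced_align,
)
from .isoform_annotation import (
    AnnotationParams,
    annotate_isoforms,
    confirm_event,
    coverage_profile,
    detect_candidate_events,
)
from .kmer_clustering import ClusteringParams, cluster_unaligned_lrs
from .pseudo_reference import PseudoRefParams, build_pseudo_reference
from .quantification import (
    build_segment_model,
    lr_abundance,
    sr_abundance_mle,
)
from .scaffold_extension import (
    ExtensionParams,
    build_overhang_consensus,
    classify_alignment,
    extend_scaffold,
    extract_overhangs,
    group_members,
)
from .sequence_io import (
    LocusAssignment,
    SequenceRecord,
    TranscriptAnnotation,
    read_fasta,
    read_fastq,
    read_locus_map,
    write_fasta,
    write_fastq,
    write_gff,
    write_locus_map,
)
from .synthetic_data import (
    SimParams,
    all_transcripts,
    simulate_long_reads,
    simulate_scaffolds,
    simulate_short_reads,
    simulate_transcriptome,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    scaffold_fasta: str = ""
    locus_tsv: str | None = None
    lr_path: str = ""
    sr1_path: str = ""
    sr2_path: str | None = None
    outdir: str = "hybridasm_out"
    seed: int = 0
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    extension: ExtensionParams = field(default_factory=ExtensionParams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    pseudo_ref: PseudoRefParams = field(default_factory=PseudoRefParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    sim: SimParams = field(default_factory=SimParams)
    lr_candidates: int = 3  # scaffolds tried per long read (seed prefilter)
    seed_k: int = 13  # seed k-mer length for candidate selection


def _read_reads(path: str) -> list[SequenceRecord]:
    p = str(path)
    if p.endswith((".fastq", ".fq")):
        return read_fastq(p)
    return read_fasta(p)


# ---------------------------------------------------------------------------
# stage a: long-read -> scaffold alignment, extension, grouping
# ---------------------------------------------------------------------------

def align_lrs_to_scaffolds(
    lrs: list[SequenceRecord],
    scaffolds: list[SequenceRecord],
    config: PipelineConfig,
) -> dict[str, list[SplicedAlignment]]:
    """Best-candidate spliced alignment of each long read against the
    scaffolds sharing sampled seed k-mers with it."""
    indexes = [TargetIndex(s.id, s.seq, k=config.seed_k) for s in scaffolds]
    out: dict[str, list[SplicedAlignment]] = {}
    for lr in lrs:
        shared = [(idx.count_shared(lr.seq), i) for i, idx in enumerate(indexes)]
        shared = sorted((c, i) for c, i in shared if c >= 2)
        candidates = [i for _, i in shared[-config.lr_candidates :]]
        alns = []
        for i in candidates:
            aln = spliced_align(
                lr.seq,
                scaffolds[i].seq,
                config.scoring,
                query_id=lr.id,
                target_id=scaffolds[i].id,
            )
            if not aln.is_empty:
                alns.append(aln)
        out[lr.id] = alns
    return out


def run_assembly_stage(
    scaffolds: list[SequenceRecord],
    locus_map: list[LocusAssignment],
    lrs: list[SequenceRecord],
    config: PipelineConfig,
):
    """Extension + grouping + clustering.  Returns (extended scaffolds,
    gene groups, k-mer clusters, unaligned lr ids, per-lr alignments)."""
    lr_by_id = {r.id: r for r in lrs}
    scaf_by_id = {s.id: s for s in scaffolds}
    alignments = align_lrs_to_scaffolds(lrs, scaffolds, config)
    accepted: dict[str, list[SplicedAlignment]] = {}
    overhangs: dict[tuple[str, str], list] = {}
    for lr_id in sorted(alignments):
        keep = []
        for aln in alignments[lr_id]:
            frags = extract_overhangs(
                aln, lr_by_id[lr_id], scaf_by_id[aln.target_id], config.extension
            )
            cls = classify_alignment(
                aln, len(scaf_by_id[aln.target_id].seq), config.extension
            )
            if cls != "unaligned":
                keep.append(aln)
                for f in frags:
                    overhangs.setdefault((f.scaffold_id, f.end), []).append(f)
        if keep:
            accepted[lr_id] = keep
    extended = []
    for s in scaffolds:
        left = overhangs.get((s.id, "left"))
        right = overhangs.get((s.id, "right"))
        # consensus uses its own edit-like scoring, not the aligner scheme
        lc = build_overhang_consensus(left) if left else None
        rc = build_overhang_consensus(right) if right else None
        extended.append(extend_scaffold(s, lc, rc))
    groups = group_members(locus_map, accepted, [s.id for s in scaffolds])
    unaligned = [lr_by_id[i] for i in sorted(lr_by_id) if i not in accepted]
    clusters = cluster_unaligned_lrs(unaligned, config.clustering)
    return extended, groups, clusters, [r.id for r in unaligned], accepted


# ---------------------------------------------------------------------------
# stage b/c helpers
# ---------------------------------------------------------------------------

def assign_sr_alignments(
    srs: list[SequenceRecord],
    pseudo_refs: dict[str, str],
    config: PipelineConfig,
) -> dict[str, list[SplicedAlignment]]:
    """Align each short read (best orientation) to the pseudo-reference of
    its best-seeding cluster; cross-cluster seed-count ties are dropped."""
    indexes = {cid: TargetIndex(cid, seq, k=config.seed_k) for cid, seq in
               sorted(pseudo_refs.items())}
    out: dict[str, list[SplicedAlignment]] = {cid: [] for cid in indexes}
    for sr in srs:
        best = None  # (count, cid, oriented_seq)
        tied = False
        for orient_seq in (sr.seq, revcomp(sr.seq)):
            for cid, idx in indexes.items():
                c = idx.count_shared(orient_seq)
                if c == 0:
                    continue
                if best is None or c > best[0]:
                    best, tied = (c, cid, orient_seq), False
                elif c == best[0] and cid != best[1]:
                    tied = True
        if best is None or tied:
            continue
        _, cid, oriented = best
        aln = seeded_spliced_align(
            oriented, indexes[cid], config.scoring, query_id=sr.id
        )
        if not aln.is_empty:
            out[cid].append(aln)
    return out


@dataclass
class ClusterResult:
    cluster_id: str
    pseudo_ref_seq: str
    depth: list[int]
    member_ids: list[str]
    events: list = field(default_factory=list)
    isoforms: list = field(default_factory=list)
    sr_rpkm: dict = field(default_factory=dict)
    lr_counts: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all three stages and write outputs + manifest to
    ``config.outdir``.  Deterministic given the config."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scaffolds = read_fasta(config.scaffold_fasta) if config.scaffold_fasta else []
    locus_map = read_locus_map(config.locus_tsv) if config.locus_tsv else []
    lrs = _read_reads(config.lr_path) if config.lr_path else []
    srs: list[SequenceRecord] = []
    if config.sr1_path:
        srs += read_fastq(config.sr1_path)
    if config.sr2_path:
        srs += read_fastq(config.sr2_path)
    if not lrs:
        logger.warning("no long reads supplied; proceeding scaffold-only")
    extended, groups, clusters, unaligned_ids, accepted = run_assembly_stage(
        scaffolds, locus_map, lrs, config
    )
    ext_by_id = {s.id: s for s in extended}
    lr_by_id = {r.id: r for r in lrs}

    # cluster membership: gene groups (locus_*) then novel k-mer clusters
    members_of: dict[str, dict[str, str]] = {}
    for g in groups:
        mem = {sid: ext_by_id[sid].seq for sid in g.scaffold_ids}
        mem.update({i: lr_by_id[i].seq for i in g.lr_ids})
        members_of[f"locus:{g.locus_id}"] = mem
    for cl in clusters:
        members_of[f"novel:{cl.cluster_id}"] = {
            i: lr_by_id[i].seq for i in cl.member_ids
        }

    results: list[ClusterResult] = []
    for cid in sorted(members_of):
        pr = build_pseudo_reference(
            cid, members_of[cid], config.pseudo_ref, config.scoring
        )
        results.append(
            ClusterResult(
                cluster_id=cid,
                pseudo_ref_seq=pr.seq,
                depth=pr.depth,
                member_ids=pr.member_ids,
            )
        )

    # transcripts -> pseudo-reference alignments and candidate events
    tx_alns: dict[str, list[SplicedAlignment]] = {}
    for res in results:
        alns = []
        for mid in res.member_ids:
            seq = members_of[res.cluster_id][mid]
            aln = spliced_align(
                seq, res.pseudo_ref_seq, config.scoring,
                query_id=mid, target_id=res.cluster_id,
            )
            if not aln.is_empty:
                alns.append(aln)
        tx_alns[res.cluster_id] = alns

    sr_alns = assign_sr_alignments(
        srs, {r.cluster_id: r.pseudo_ref_seq for r in results}, config
    )
    total_mapped = sum(len(v) for v in sr_alns.values())

    for res in results:
        cluster_sr = sr_alns.get(res.cluster_id, [])
        depth_prof = coverage_profile(cluster_sr, len(res.pseudo_ref_seq))
        events = []
        for aln in tx_alns[res.cluster_id]:
            for ev in detect_candidate_events(aln, res.cluster_id, config.annotation):
                events.append(
                    confirm_event(ev, cluster_sr, config.annotation, depth_prof)
                )
        res.events = events
        res.isoforms = annotate_isoforms(
            res.cluster_id, tx_alns[res.cluster_id], config.annotation
        )
        if res.isoforms and total_mapped > 0:
            model = build_segment_model(res.isoforms, cluster_sr, total_mapped)
            res.sr_rpkm, _ = sr_abundance_mle(model)
        else:
            res.sr_rpkm = {iso.transcript_id: 0.0 for iso in res.isoforms}
        lr_cluster_alns = [
            a for a in tx_alns[res.cluster_id] if a.query_id in lr_by_id
        ]
        res.lr_counts = lr_abundance(res.isoforms, lr_cluster_alns, config.annotation)

    manifest = _write_outputs(
        outdir, config, extended, clusters, unaligned_ids, results, lrs, srs,
        total_mapped,
    )
    return manifest


def _write_outputs(
    outdir: Path, config, extended, clusters, unaligned_ids, results, lrs, srs,
    total_mapped,
) -> dict:
    write_fasta(extended, outdir / "extended_scaffolds.fasta")
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("lr_id\tcluster_id\tis_representative\n")
        for cl in clusters:
            for mid in cl.member_ids:
                rep = int(mid == cl.representative_id)
                fh.write(f"{mid}\t{cl.cluster_id}\t{rep}\n")
    write_fasta(
        [SequenceRecord(id=r.cluster_id, seq=r.pseudo_ref_seq)
         for r in results if r.pseudo_ref_seq],
        outdir / "pseudo_references.fasta",
    )
    with open(outdir / "pseudo_reference_depth.tsv", "w") as fh:
        fh.write("cluster_id\tpos\tdepth\n")
        for r in results:
            for pos, d in enumerate(r.depth):
                fh.write(f"{r.cluster_id}\t{pos}\t{d}\n")
    with open(outdir / "events.tsv", "w") as fh:
        fh.write(
            "cluster_id\ttranscript_id\tgap_start\tgap_end\t"
            "n_splice_reads\tmean_gap_coverage\tstatus\n"
        )
        for r in results:
            for e in r.events:
                fh.write(
                    f"{e.cluster_id}\t{e.transcript_id}\t{e.gap_start}\t"
                    f"{e.gap_end}\t{e.n_splice_reads}\t"
                    f"{e.mean_gap_coverage:.3f}\t{e.status}\n"
                )
    annotations = [
        TranscriptAnnotation(
            ref_id=r.cluster_id,
            gene_id=r.cluster_id,
            transcript_id=iso.transcript_id,
            exons=list(iso.blocks),
        )
        for r in results
        for iso in r.isoforms
    ]
    write_gff(annotations, outdir / "isoforms.gff3")
    with open(outdir / "abundance.tsv", "w") as fh:
        fh.write("transcript_id\tcluster_id\tsr_rpkm\tlr_count\n")
        for r in results:
            for iso in r.isoforms:
                tid = iso.transcript_id
                fh.write(
                    f"{tid}\t{r.cluster_id}\t{r.sr_rpkm.get(tid, 0.0):.4f}\t"
                    f"{r.lr_counts.get(tid, 0)}\n"
                )
    n_unaligned = len(unaligned_ids)
    mean_l = (
        float(np.mean([len(r.seq) for r in lrs])) if lrs else 0.0
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "clustering": asdict(config.clustering),
            "pseudo_ref": asdict(config.pseudo_ref),
            "annotation": asdict(config.annotation),
            "extension": asdict(config.extension),
            "scoring": asdict(config.scoring),
        },
        "counts": {
            "scaffolds": len(extended),
            "long_reads": len(lrs),
            "short_reads": len(srs),
            "unaligned_long_reads": n_unaligned,
            "kmer_clusters": len(clusters),
            "total_clusters": len(results),
            "sr_mapped": total_mapped,
            "isoforms": sum(len(r.isoforms) for r in results),
            "events_confirmed": sum(
                1 for r in results for e in r.events if e.status == "confirmed"
            ),
            "events_total": sum(len(r.events) for r in results),
        },
        "unaligned_lr_stats": {"N": n_unaligned, "mean_length": mean_l},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# simulate: write a ready-to-run fixture directory
# ---------------------------------------------------------------------------

SIMULATE_FILES = (
    "transcripts.fasta",
    "scaffolds.fasta",
    "locus_map.tsv",
    "lr.fasta",
    "sr_1.fastq",
    "sr_2.fastq",
    "truth.json",
)


def simulate(params: SimParams, outdir: str | Path) -> Path:
    """Generate a complete synthetic input set (reads, scaffolds, locus map
    and truth tables) under ``outdir``; deterministic given params.seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, truth = simulate_transcriptome(params)
    write_fasta(all_transcripts(genes), outdir / "transcripts.fasta")
    scaffolds, locus_map = simulate_scaffolds(genes, params)
    write_fasta(scaffolds, outdir / "scaffolds.fasta")
    write_locus_map(
        [LocusAssignment(scaffold_id=k, locus_id=v) for k, v in locus_map.items()],
        outdir / "locus_map.tsv",
    )
    lr_records, lr_truth = simulate_long_reads(genes, params)
    write_fasta(lr_records, outdir / "lr.fasta")
    mate1, mate2, sr_truth = simulate_short_reads(genes, params)
    write_fastq(mate1, outdir / "sr_1.fastq")
    write_fastq(mate2, outdir / "sr_2.fastq")
    truth_obj = {
        "isoforms": truth["isoforms"].to_dict(orient="records"),
        "exons": truth["exons"].to_dict(orient="records"),
        "gene_exons": truth["gene_exons"].to_dict(orient="records"),
        "sr_reads": sr_truth.to_dict(orient="records"),
        "lr_reads": lr_truth.to_dict(orient="records"),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_obj, fh, sort_keys=True)
    return outdir


def config_for_simulated(
    fixture_dir: str | Path, outdir: str | Path, **overrides
) -> PipelineConfig:
    """A PipelineConfig wired to a :func:`simulate` fixture directory."""
    d = Path(fixture_dir)
    return PipelineConfig(
        scaffold_fasta=str(d / "scaffolds.fasta"),
        locus_tsv=str(d / "locus_map.tsv"),
        lr_path=str(d / "lr.fasta"),
        sr1_path=str(d / "sr_1.fastq"),
        sr2_path=str(d / "sr_2.fastq"),
        outdir=str(outdir),
        **overrides,
    )
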