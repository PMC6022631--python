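"""Ground-truthed synthetic transcriptomes and reads.

Emulates the inputs of a hybrid-sequencing experiment at desk scale:
multi-isoform genes whose isoforms share exons, paired-end short reads
with substitution errors, and long reads with high indel-dominated error
rates, variable lengths and 5'/3' truncation.  Every generator is
deterministic given the seed, and truth tables are emitted so each
pipeline stage can be scored against known labels and coordinates.

Genes are sequence-independent by construction (exons drawn i.i.d.
uniform over ACGT), so inter-gene k-mer sharing is rare and the
clustering truth is unambiguous.  An optional gene-family mode shares a
fraction of exons between gene pairs to stress-test that assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment_core import revcomp
from .sequence_io import SequenceRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic experiment.

    Long-read errors are indel-dominated (default 40% insertion, 40%
    deletion, 20% substitution) to match third-generation platform
    character; short reads carry substitutions only.  Truncation removes
    an independent uniform fraction (up to ``lr_trunc_max_frac``) from
    each read end with probability ``lr_trunc_prob``.
    """

    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_len: tuple[int, int] = (100, 400)
    isoforms_per_gene: tuple[int, int] = (1, 3)
    sr_len: int = 100
    sr_frag_len: tuple[int, int] = (180, 350)
    sr_pairs: int = 2000
    sr_sub_rate: float = 0.005
    lr_count: int = 100
    lr_error_rate: float = 0.12
    lr_error_split: tuple[float, float, float] = (0.4, 0.4, 0.2)  # ins, del, sub
    lr_trunc_prob: float = 0.3
    lr_trunc_max_frac: float = 0.3
    scaffold_trunc_frac: float = 0.4  # total fraction removed (split over both ends)
    gene_family_frac: float = 0.0  # fraction of genes sharing exons with a partner
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sr_sub_rate", "lr_error_rate",
                     "lr_trunc_max_frac", "scaffold_trunc_frac"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("lr_trunc_prob", "gene_family_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("exons_per_gene", "exon_len", "isoforms_per_gene", "sr_frag_len"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} range ({lo}, {hi}) is empty or invalid")
        if self.isoforms_per_gene[1] > 2 ** self.exons_per_gene[0]:
            raise ValueError(
                "isoforms_per_gene max exceeds the number of distinct exon "
                "subsets available at exons_per_gene min"
            )
        if abs(sum(self.lr_error_split) - 1.0) > 1e-9:
            raise ValueError("lr_error_split must sum to 1")


@dataclass(frozen=True)
class TruthGene:
    gene_id: str
    exon_seqs: tuple[str, ...]
    # (isoform_id, strictly increasing exon-index tuple, abundance weight)
    isoforms: tuple[tuple[str, tuple[int, ...], float], ...]

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise ValueError(f"gene {self.gene_id} has no isoforms")
        for iso_id, idxs, w in self.isoforms:
            if w <= 0:
                raise ValueError(f"isoform {iso_id}: weight must be > 0")
            if list(idxs) != sorted(set(idxs)):
                raise ValueError(f"isoform {iso_id}: exon subset not strictly increasing")
            if idxs and (idxs[0] < 0 or idxs[-1] >= len(self.exon_seqs)):
                raise ValueError(f"isoform {iso_id}: exon index out of range")

    def transcript(self, idxs: tuple[int, ...]) -> str:
        return "".join(self.exon_seqs[i] for i in idxs)

    def transcripts(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(id=iso_id, seq=self.transcript(idxs))
            for iso_id, idxs, _ in self.isoforms
        ]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def simulate_transcriptome(
    params: SimParams,
) -> tuple[list[TruthGene], dict[str, pd.DataFrame]]:
    """Generate genes with shared-exon isoforms plus truth tables.

    Isoform 1 of every gene always contains all exons (the gene's
    full-length transcript); additional isoforms skip a random non-empty
    subset of internal exons, so every alternative event is a clean exon
    skip with known coordinates.  Abundance weights are log-uniform over
    one decade to exercise lowly-expressed transcripts.

    Returns the genes and truth tables: ``isoforms`` (one row per
    isoform), ``exons`` (per-isoform transcript coordinates of each exon)
    and ``gene_exons`` (exon coordinates on the full-length transcript).
    """
    rng = np.random.default_rng(params.seed)
    genes: list[TruthGene] = []
    family_partner: dict[int, int] = {}
    if params.gene_family_frac > 0:
        n_fam = int(params.n_genes * params.gene_family_frac) // 2 * 2
        for a in range(0, n_fam, 2):
            family_partner[a + 1] = a
    for g in range(params.n_genes):
        n_ex = int(rng.integers(params.exons_per_gene[0], params.exons_per_gene[1] + 1))
        exon_seqs = [
            _random_seq(rng, int(rng.integers(params.exon_len[0], params.exon_len[1] + 1)))
            for _ in range(n_ex)
        ]
        if g in family_partner:  # share ~half the exons with the partner gene
            donor = genes[family_partner[g]].exon_seqs
            for i in range(min(len(donor), n_ex) // 2):
                exon_seqs[i] = donor[i]
        n_iso = int(
            rng.integers(params.isoforms_per_gene[0], params.isoforms_per_gene[1] + 1)
        )
        subsets: list[tuple[int, ...]] = [tuple(range(n_ex))]
        internal = list(range(1, n_ex - 1))
        attempts = 0
        while len(subsets) < n_iso and attempts < 100:
            attempts += 1
            if not internal:
                break
            n_skip = int(rng.integers(1, len(internal) + 1))
            skipped = set(rng.choice(internal, size=n_skip, replace=False).tolist())
            subset = tuple(i for i in range(n_ex) if i not in skipped)
            if subset not in subsets:
                subsets.append(subset)
        weights = 10 ** rng.uniform(-1, 1, size=len(subsets))
        genes.append(
            TruthGene(
                gene_id=f"g{g + 1}",
                exon_seqs=tuple(exon_seqs),
                isoforms=tuple(
                    (f"g{g + 1}.i{j + 1}", subsets[j], float(weights[j]))
                    for j in range(len(subsets))
                ),
            )
        )
    iso_rows, exon_rows, gene_exon_rows = [], [], []
    for gene in genes:
        off = 0
        for i, ex in enumerate(gene.exon_seqs):
            gene_exon_rows.append(
                {"gene_id": gene.gene_id, "exon_index": i,
                 "start": off, "end": off + len(ex)}
            )
            off += len(ex)
        for iso_id, idxs, w in gene.isoforms:
            iso_rows.append(
                {"gene_id": gene.gene_id, "isoform_id": iso_id,
                 "exon_indices": ",".join(map(str, idxs)),
                 "length": sum(len(gene.exon_seqs[i]) for i in idxs),
                 "weight": w}
            )
            pos = 0
            for i in idxs:
                exon_rows.append(
                    {"isoform_id": iso_id, "exon_index": i,
                     "tx_start": pos, "tx_end": pos + len(gene.exon_seqs[i])}
                )
                pos += len(gene.exon_seqs[i])
    truth = {
        "isoforms": pd.DataFrame(iso_rows),
        "exons": pd.DataFrame(exon_rows),
        "gene_exons": pd.DataFrame(gene_exon_rows),
    }
    return genes, truth


def all_transcripts(genes: list[TruthGene]) -> list[SequenceRecord]:
    return [rec for g in genes for rec in g.transcripts()]


def _isoform_weights(genes: list[TruthGene], by_length: bool):
    ids, seqs, w = [], [], []
    for g in genes:
        for iso_id, idxs, weight in g.isoforms:
            seq = g.transcript(idxs)
            ids.append(iso_id)
            seqs.append(seq)
            w.append(weight * (len(seq) if by_length else 1.0))
    w = np.asarray(w)
    return ids, seqs, w / w.sum()


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    if hit.any():
        # substitute with one of the three other bases
        shift = rng.integers(1, 4, size=int(hit.sum()))
        idx = np.searchsorted(np.array(list("ACGT")), arr[hit])
        arr[hit] = _BASES[(idx + shift) % 4]
    return "".join(arr)


def simulate_short_reads(
    genes: list[TruthGene], params: SimParams, rng: np.random.Generator | None = None
) -> tuple[list[SequenceRecord], list[SequenceRecord], pd.DataFrame]:
    """Paired-end short reads (FR orientation, mate 2 reverse-complemented).

    Fragments are uniform within a transcript chosen proportional to
    weight x length; substitution errors only.  Returns (mate1, mate2,
    truth table read_id -> isoform_id).
    """
    rng = rng or np.random.default_rng(params.seed + 1)
    ids, seqs, probs = _isoform_weights(genes, by_length=True)
    shortest = min(len(s) for s in seqs)
    if params.sr_len > shortest:
        raise ValueError(
            f"sr_len {params.sr_len} exceeds shortest transcript ({shortest} bp)"
        )
    mate1, mate2, rows = [], [], []
    choices = rng.choice(len(ids), size=params.sr_pairs, p=probs)
    for n, t in enumerate(choices):
        seq = seqs[t]
        frag = int(
            rng.integers(params.sr_frag_len[0], params.sr_frag_len[1] + 1)
        )
        frag = min(frag, len(seq))
        frag = max(frag, params.sr_len)
        start = int(rng.integers(0, len(seq) - frag + 1))
        fragment = seq[start : start + frag]
        r1 = _substitute(fragment[: params.sr_len], params.sr_sub_rate, rng)
        r2 = _substitute(
            revcomp(fragment[-params.sr_len :]), params.sr_sub_rate, rng
        )
        rid = f"sr{n + 1}"
        qual = "I" * params.sr_len
        mate1.append(SequenceRecord(id=rid + "/1", seq=r1, qual=qual))
        mate2.append(SequenceRecord(id=rid + "/2", seq=r2, qual=qual))
        rows.append({"read_id": rid, "isoform_id": ids[t], "frag_start": start,
                     "frag_end": start + frag})
    return mate1, mate2, pd.DataFrame(rows)


def mutate_indel(
    seq: str,
    rate: float,
    split: tuple[float, float, float],
    rng: np.random.Generator,
    ins_dup_prob: float = 0.75,
) -> str:
    """Apply indel-dominated errors at the given per-base rate.

    Insertions duplicate the current base with probability
    ``ins_dup_prob`` (homopolymer-length errors, the dominant
    third-generation indel mode) and insert a uniform random base
    otherwise; deletions and substitutions are uniform.
    """
    if rate <= 0:
        return seq
    p_ins, p_del, _ = split
    out: list[str] = []
    u = rng.random(len(seq))
    kind = rng.random(len(seq))
    dup = rng.random(len(seq)) < ins_dup_prob
    extra = _BASES[rng.integers(0, 4, len(seq))]
    for i, base in enumerate(seq):
        if u[i] >= rate:
            out.append(base)
        elif kind[i] < p_ins:
            out.append(base if dup[i] else extra[i])
            out.append(base)
        elif kind[i] < p_ins + p_del:
            continue
        else:
            out.append(extra[i] if extra[i] != base else "ACGT"[("ACGT".index(base) + 1) % 4])
    return "".join(out) or seq[:1]


def simulate_long_reads(
    genes: list[TruthGene], params: SimParams, rng: np.random.Generator | None = None
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Long reads: (possibly end-truncated) transcript copies with
    indel-dominated errors.  Transcript chosen proportional to weight
    (molar abundance — full-length cDNA reads are length-independent)."""
    rng = rng or np.random.default_rng(params.seed + 2)
    ids, seqs, probs = _isoform_weights(genes, by_length=False)
    records, rows = [], []
    choices = rng.choice(len(ids), size=params.lr_count, p=probs)
    for n, t in enumerate(choices):
        seq = seqs[t]
        lo, hi = 0, len(seq)
        if rng.random() < params.lr_trunc_prob:
            lo = int(len(seq) * rng.uniform(0, params.lr_trunc_max_frac))
        if rng.random() < params.lr_trunc_prob:
            hi = len(seq) - int(len(seq) * rng.uniform(0, params.lr_trunc_max_frac))
        raw = seq[lo:hi] or seq[:1]
        read = mutate_indel(raw, params.lr_error_rate, params.lr_error_split, rng)
        rid = f"lr{n + 1}"
        records.append(SequenceRecord(id=rid, seq=read))
        rows.append({"read_id": rid, "isoform_id": ids[t],
                     "tx_start": lo, "tx_end": hi})
    return records, pd.DataFrame(rows)


def simulate_scaffolds(
    genes: list[TruthGene], params: SimParams
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Short-read-assembler stand-in: one scaffold per gene, the middle
    (1 - scaffold_trunc_frac) of the full-length transcript, plus the
    scaffold -> locus map.  Truncation 0 gives the transcripts verbatim."""
    scaffolds, locus_map = [], {}
    for gene in genes:
        full = gene.transcript(gene.isoforms[0][1])
        cut = int(len(full) * params.scaffold_trunc_frac / 2)
        seq = full[cut : len(full) - cut] if cut else full
        sid = f"{gene.gene_id}.scaf"
        scaffolds.append(SequenceRecord(id=sid, seq=seq))
        locus_map[sid] = gene.gene_id
    return scaffolds, locus_map
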