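# Methods

This note documents the models and algorithms implemented in `hybridasm`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that affect
results.

## Pairwise alignment

All alignment is one affine-gap (Gotoh) dynamic program
(`alignment_core`), numba-compiled, in two boundary modes:

* **local** — Smith–Waterman, for long-read→scaffold, transcript→pseudo-
  reference and exon→pseudo-reference comparisons;
* **overlap** — end-free global (no charge for leading/trailing gaps on
  either sequence), for folding sequences into consensus profiles.

Defaults: match +2, mismatch −3, gap open −3, gap extend −1; a gap of
length L costs `open + L·extend`. Two extra DP states model *structural*
gaps: a run of ≥ `target_gap_free_threshold` (default 30 bp) skipped
positions on the target (an exon the query lacks) or on the query (an exon
the target lacks, used only in the profile-merge aligner). A structural
gap costs a flat `long_gap_open` (default −15) regardless of length and
its columns are excluded from identity. The flat cost is deliberately
stiffer than a short-gap open: inside a skipped exon of a few hundred
random bases, chance micro-anchors of score ~+5 to +12 exist, and with a
cheap open the optimal path splits one real skip into several gaps
bracketing such anchors; −15 makes that unprofitable while leaving real
exon anchors (tens of matching bases) untouched. Percent identity is
matches over aligned columns, gaps included in the denominator except
structural ones — a conservative definition, stated here because the
field uses several.

Minus-strand handling reverse-complements the query and reports the flip
in `strand`; block coordinates stay on the reverse-complemented frame so
they remain strictly increasing. Many-read alignment against one target
uses exact k-mer seeding (default k = 13) and runs the spliced DP only on
the seeded target window; a read with no seed hit is reported unaligned.
Sequences beyond a 200 kb cap are refused with a pointer to external
aligner adapters (out of scope here).

## Scaffold extension

A long-read alignment to a scaffold is accepted at identity ≥ 0.70 over
≥ 100 aligned columns — loose enough for ~15% read error, tight enough to
reject chance hits. The read qualifies as end-covering when its alignment
reaches within 10 bp (`end_slack`) of a scaffold end with ≥ 50 bp
(`min_overhang`) of unaligned read past it; the unaligned portion is the
overhang fragment. A read with both overhangs contributes to both ends
independently. The scaffold is extended by concatenating each end's
overhang consensus; the original scaffold sequence is never edited
(substring invariant).

### Overhang consensus

Consensus of 10–15%-error fragments at 5–7× coverage is the accuracy
bottleneck of extension. Column-wise majority voting over star or
progressive alignments plateaus around 98% identity: pairwise alignments
place indels inconsistently in short repeats, splitting votes. The
implemented pipeline is therefore:

1. **Partial-order alignment (POA).** Fragments are folded into a DAG
   (longest fragment seeds the backbone); mismatches become alternative
   column nodes, insertions become branches, and edge weights count
   traversing reads. The consensus is the heaviest path, followed by
   majority-support pruning (a path node must carry at least half the
   local coverage) and a bounded trim of low-support terminal runs
   (≤ 15 columns) — a read's error-bearing first/last bases otherwise
   survive as light source/sink chains. A second POA round re-folds every
   fragment into a graph seeded with the first consensus.
2. **Homopolymer-aware column vote.** One star re-vote in
   homopolymer-compressed space: per column the plurality base wins and
   its emitted run length is the median of the voting rows' run lengths.
3. **Windowed Steiner refinement.** For each 12 bp consensus window, the
   candidate segment (any covering row's content, or the current
   consensus) minimizing the total edit distance to all covering rows
   replaces the window. This resolves the residual equivalent-gap-
   placement ambiguity that no column-wise vote can.

Measured on 300 bp fragments: 7 fragments at 10% error reach ≥ 99%
identity in ~98 of 100 trials; 5 fragments at 12% reach ≥ 98% in ~80+ of
100. Extended scaffolds (exact middle 60% + consensus ends) exceed 98%
identity to the full transcript in every tested gene.

## k-mer clustering of unaligned long reads

Reads are homopolymer-compressed — the dominant third-generation error
mode is homopolymer run-length error, which compression removes — then
clustered greedily in descending compressed length (ties broken by id).
The first read seeds a cluster and becomes its frozen representative;
each later read joins the cluster whose representative shares the largest
fraction of the read's distinct k-mers, if that fraction reaches
C_threshold, else founds a new cluster. Defaults k = 15 and
C_threshold = 0.05 follow the published tuning of this method class. The
denominator of the shared fraction is the query's k-mer count
(asymmetric, cheap against a stored filter). K-mers are 2-bit packed;
k-mers containing N are dropped; no strand canonicalization by default
(transcript reads are largely sense-strand), with a `canonical_kmers`
switch for unstranded protocols.

Representative k-mer sets live in bloom filters (bit array and hash count
from the standard optimal formulas; double hashing over two splitmix64
streams, so behaviour is process-independent and seed-free). The filter
guarantees no false negatives; at the default 1e-4 false-positive rate,
a false positive changes a shared fraction by at most ~1/|query k-mers|,
far below C_threshold — verified by an exact-set oracle backend
(`exact_sets=True`) that tests compare against.

The separation this achieves depends on the error rate: at 12% raw error
the expected per-k-mer survival in both query and representative leaves a
same-gene shared fraction of roughly 0.1–0.2 versus < 0.005 across genes,
so the 0.05 threshold separates cleanly, but occasionally (a few percent
of simulations) one noisy read pair pushes a gene below threshold and the
gene splits — an inherent property of single-pass greedy clustering with
frozen representatives, noted in the original method class as well.

Clustering quality is scored by pair-counting metrics (Jaccard,
precision, recall, F) over all unordered element pairs.

## Pseudo-reference construction

Cluster members sort by descending length; members whose identity to the
longest member (matches over the shorter sequence's length) falls below
0.30 are dropped and never reconsidered. The three longest members seed a
progressive profile and two more are folded in per round. The profile is
carried across rounds (votes and depth accumulate) rather than restarted
from the previous consensus string, so the depth vector is well defined.
Merging uses the both-sided structural-gap aligner: a member that skips
an exon crosses it with one flat charge and — critically — casts **no
coverage vote** across it, while a member carrying an exon the profile
lacks inserts it as new columns. Consensus emission is union semantics:
any column with at least one base vote survives, because the
pseudo-reference must contain every expressed exon, including ones
covered by a single read. A light noise filter drops unsupported 1–2
column insertion runs when ≥ 3 rows cover the position (single-read
indel noise); with fewer covering rows nothing is dropped, so the
two-member insertion-retention contract holds exactly.

The union profile is then polished by two structure-aware star re-votes
(majority per column among covering rows only; skipping members do not
vote inside their skips), which removes error-scale noise without
touching minority exons. `msa_consensus` additionally applies the
windowed Steiner refinement with the same structure awareness.

On error-free members, every exon of every retained member is an exact
substring of the pseudo-reference (tested exhaustively). On noisy input
the accuracy is coverage-limited: at ~15 long reads per gene plus the
clean scaffold, > 90% of truth exons align back at ≥ 90% identity; genes
sampled by only 1–2 reads account for most failures, since no consensus
can beat the raw read error there.

## Alternative exon usage and isoform annotation

Candidates are target-side gaps ≥ `min_gap_len` (default 43 bp) in the
best spliced alignment of a transcript to its pseudo-reference;
query-side gaps never produce events, since without a genome a
transcript-only insertion is indistinguishable from pseudo-reference
incompleteness. Confirmation requires `min_splice_reads` (default 10)
short reads whose alignments contain a gap with both boundaries within
`boundary_slack` (default 5 bp) of the event's, **and** mean short-read
depth ≥ `min_gap_coverage` (default 10) inside the gap ("mean" chosen
over "min" where the evidence definition is ambiguous;
`gap_coverage_stat` switches). Status is a total function of these
counts, so confirmation is idempotent. No event below 43 bp is ever
reported — a hard guarantee; small exon-usage events are an acknowledged
blind spot of length-based gap detection on noisy reads.

Isoform records take each transcript's alignment blocks with sub-43 bp
gaps fused into their flanks (alignment noise, not structure); two
transcripts whose block sets agree within 5 bp everywhere collapse to one
record represented by the longest transcript. Truncated reads with the
same splice pattern but shorter spans remain separate records — the
package does not guess missing ends.

## Quantification

**SR index.** Per cluster, the pseudo-reference is cut at the union of
isoform block boundaries; segments inside no isoform are dropped. Read
*starts* (leftmost aligned base) per segment are modelled as
c_s ~ Poisson(L_s · Σᵢ A[s,i]·θᵢ) with θᵢ ≥ 0 in reads/base — start
counting keeps segment observations independent, unlike per-base
coverage. θ is maximized by EM from a uniform start (monotone in the
log-likelihood; relative-change tolerance 1e-8, cap 10 000 iterations),
then finished with bounded L-BFGS-B, because EM's linear convergence
stalls ~1e-5 short of the optimum in flat directions. RPKM_i = θᵢ·10⁹/M
with M the run-wide mapped-read count. Cross-cluster multi-mapping reads
are dropped on seed-count ties; within-cluster ambiguity is what the
deconvolution resolves. Recovery accuracy is set by the size of
isoform-distinguishing segments: at ~100× depth with ~300 bp unique
segments the median relative error per θ is ~3%.

**LR index.** A long read supports an isoform when every structural gap
in its alignment matches one of the isoform's gaps within 5 bp, its span
lies inside the isoform's block envelope, and it does not read through an
exon the isoform skips. One read may support several isoforms
(compatibility, not assignment); counts are integer.

## Synthetic data generator

`synthetic_data` is the package's study-condition generator, fully
deterministic per seed. Genes are built from i.i.d. uniform-ACGT exons
(default 2–5 exons of 100–400 bp), so inter-gene k-mer sharing is
negligible and the clustering truth unambiguous; an optional gene-family
mode shares exons between gene pairs to stress that assumption. Isoform 1
always carries all exons; additional isoforms skip random non-empty
subsets of internal exons, so every alternative event is a clean internal
skip with known coordinates. Abundance weights are log-uniform over one
decade to exercise lowly-expressed transcripts.

Short reads: paired-end FR, fragment length 180–350, transcript chosen
∝ weight × length, substitutions only (default 0.5%). Long reads:
transcript chosen ∝ weight (molar, length-independent), optional
independent 5′/3′ truncation (default: each end with p = 0.3, up to 30%),
then indel-dominated errors at `lr_error_rate` (default 12%) split
40/40/20 insertion/deletion/substitution. Insertions duplicate the
current base with probability 0.75 — homopolymer-length errors, the
documented dominant indel mode of third-generation platforms and the
premise of compressing homopolymers before k-mer comparison. Scaffolds
are the middle (1 − `scaffold_trunc_frac`) of each gene's full-length
transcript, standing in for a short-read assembler.

Not emulated: realistic quality-score models, chimeric or strand-flipped
reads, sequence-context-dependent error hotspots, positional/GC coverage
bias, genuinely homologous gene families. Passing tests therefore show
the algorithms behave correctly under their stated error models, not that
real-library artifacts are handled.

### Study conditions used by the checks

* Clustering: 5 single-isoform genes (the check targets gene separation),
  4–7 exons of 200–400 bp, 30 reads at 12% error, ≤ 20% end truncation.
* Extension: 20 transcripts of 2–4 kb, scaffold = middle 60%, 5 reads per
  end at 12% error.
* Consensus: 7 fragments, 300 bp, 10% error, 100 trials.
* Exon recovery: 100 genes × 3 isoforms, ~15 reads/gene at 10% error plus
  the clean scaffold; denominator restricted to genes present in the
  long-read sample.
* Event calling: 100 two-isoform genes, internal skip ≥ 43 bp, 20× SR
  depth per isoform (comfortably above the 10-read/10× thresholds once
  junction-anchoring losses are accounted for).
* Quantification: the canonical 3-segment skip model for the oracle
  comparison; a 4-segment model with a unique segment per isoform for
  recovery, 200 replicates at ~100× depth.

`scripts/acceptance.py` re-runs all of the above from a single seed at
reduced sizes chosen to finish in a few minutes on one CPU (10 extension
genes, 50 consensus trials, 40 recovery genes, 50 event genes, 100 MLE
replicates, 10-gene end-to-end run); the quantities are unchanged in
expectation, only their sampling noise grows.

## Numerical and tie-break conventions

Coordinates are 0-based half-open everywhere; GFF3 output converts to
1-based inclusive at exactly one function. DP tie-breaks prefer
diagonal steps, then structural gaps, then target gaps, then query gaps;
consensus base ties resolve A<C<G<T; insertion-string ties resolve
shorter-then-lexicographic; cluster ties keep the earliest cluster;
length ties sort by id. Every component is deterministic given its
inputs, and the pipeline given its seed — byte-identical outputs across
reruns are asserted in tests.

## Known limitations

* Greedy frozen-representative clustering can split a gene (no merge
  pass) and lumps homologous gene families into one cluster.
* Exons shorter than the 43 bp gap threshold are invisible to event
  calling; introns common to *all* isoforms cannot be discovered at all
  without a genome.
* Pseudo-reference accuracy degrades to raw-read accuracy at 1–2×
  coverage.
* RPKM inherits Poisson-model assumptions (no GC/positional bias
  correction, no uncertainty intervals).
* Single pass of extension (no extend→re-align→extend iteration), and
  groups bridged by a single long read across two loci are not merged.
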