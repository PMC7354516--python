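# Methods

This note documents the models and procedures behind each stage, the
parameters that matter, what the simulator does and does not emulate, and the
design decisions taken where the underlying workflow left details open.

## Read quality filtering

Trimming follows the sliding-window convention (as in Trimmomatic's
SLIDINGWINDOW): scan windows of `window` bases (default 4); at the first
window whose mean Phred score falls below `min_q` (default 20), cut at the
window start, then retain consecutive bases that individually meet `min_q`.
A read shorter than `min_len` (default 50) after trimming is dropped, and a
pair survives only if both mates do. The retain-trailing-bases step makes the
rule idempotent and keeps high-quality bases that merely sit next to a bad
window. All three knobs are exposed in the pipeline config.

## Host-read subtraction

Alignment is replaced by canonical k-mer membership: the host chromosome and
any plasmids are indexed as canonical k-mers (lexicographic minimum of a
k-mer and its reverse complement, packed 2 bits/base; k odd so no k-mer is
its own reverse complement), and a mate's host fraction is (matching
windows)/(len − k + 1). A pair is host-derived when **either** mate reaches
`threshold` (default 0.5 at k = 25) — conservative against host contamination
of the assembly pool. Reads shorter than k can never be host-like; they are
flagged and routed to the non-host pool rather than silently lost. On
error-free reads this classification is exactly equivalent to substring
search against the host; at 0.5% error a host mate retains ≥ 50% matching
windows unless it carries ≥ 3 errors, which is why leakage stays ≪ 1%.

## Assembly

The non-host pool from all samples is pooled (the genome is reconstructed
once, from everything that transcribed) and counted into canonical 31-mers;
nodes with count < `min_count` (default 2) are discarded. Adjacency is
implied by exact (k−1)-mer overlap between retained nodes rather than
recorded per read: at k = 31 on these data a chance overlap between
non-adjacent k-mers is vanishingly rare, and the implied graph is what the
unitig walk traverses anyway.

Cleaning handles two error regimes. Tips — short dead-end paths with lower
coverage than a sibling branch — are classical read-end errors. But once
pooled coverage reaches hundreds-fold, the same substitution at the same
genome position recurs in independent reads, passes any fixed `min_count`,
and branches off the true path in tangles that are neither clean tips nor
simple two-arm bubbles; left in place they shatter contigs to below the
decontamination length floor. The default cleaner therefore also removes any
short unitig (≤ 5k bases) whose mean coverage is ≤ `bubble_ratio` (default
0.25) of its strongest neighbouring unitig. True low-coverage regions are
safe because genuine coverage varies continuously along the genome, whereas
an error branch sits next to a path carrying the full depth. Exact two-arm
bubble popping is also available separately. Setting `pop_bubbles: false`
reduces cleaning to tip removal only.

Contigs are maximal non-branching paths, emitted in canonical orientation
(lexicographic min of sequence and reverse complement) with a 2k minimum
length to suppress residual k-mer noise. Scaffolding anchors each mate by its
unique k-mers (≥ 5 consistent hits), links contig ends through
forward–reverse pair geometry, requires ≥ `min_links` (default 3) supporting
pairs, and refuses to join a contig pair whose best and second-best
end-combinations tie (contradictory orientation evidence). Estimated gaps are
`max(1, round(insert_mean − overhangs))` Ns. Scaffolds are renumbered by
descending length, so `scaffold_1` is always the longest. Linking saturates
quickly, so the pipeline anchors a deterministic stride-subsample of at most
~30,000 pairs.

Assembly statistics report per-scaffold length and GC (over non-N bases),
total bp, length-weighted GC%, and N50; displayed GC rounds half-up to one
decimal, matching the convention of the published scaffold table this
summary mirrors.

## Decontamination

The published workflow excluded contigs with high identity to host-genus
sequences in a public database; a desk-reproducible equivalent screens
against the supplied host reference only. Identity is the fraction of a
scaffold's N-free canonical k-mers found in the host index; scaffolds with
identity ≥ `identity_max` (default 0.9) or length < `min_len` (default
1 kb) are excluded, each with its fate and identity in the report. Screening
against the host reference rather than a database narrows the test to
"host-derived", which is the property the downstream analysis needs; it
cannot flag contamination from other organisms.

## Gene annotation

For every stop codon in all six frames the maximal ORF is called: the
furthest upstream in-frame start codon (ATG/GTG/TTG) with no intervening
stop, stop codon included, minimum 30 codons. This resolves nested
same-stop ORFs to the longest automatically. Each candidate is scored for a
ribosome-binding site: the longest contiguous substring of the
Shine–Dalgarno consensus `AGGAGGT` found within −20..−4 of the start codon
on the coding strand (window truncated at scaffold edges), with the spacer
reported; score ≥ 4 marks high confidence. The "suitable RBS" rule is an
explicit, tunable stand-in for what the original study confirmed manually.
Functional annotation by homology and tRNA detection are out of scope; genes
are emitted as hypothetical proteins in GFF3 (1-based inclusive), gene FASTA
and protein FASTA (translation table 11). ORFs spanning scaffold N-gaps are
possible and translate with X residues; they fall out as low-confidence calls.

## Quantification

Reads are re-assigned to annotated genes (phage) and the supplied host gene
models with the same k-mer machinery: each gene's canonical 25-mers form an
ownership map, k-mers shared between genes are marked shared and vote for
nobody, and a pair is assigned to the gene with the strict majority of
matching k-mers across both mates, requiring ≥ `min_hits` (default 10); a
tie is ambiguous, mirroring union-mode counting. Counting is unstranded —
canonical k-mers erase strand, matching the original analysis, which did not
exploit library strandedness. Per-sample tallies satisfy
assigned + ambiguous + unassigned = input pairs by construction.

## Temporal classification

Counts are scaled to CPM with the sample's total pair count as library size,
replicates at the same timepoint averaged (CPM is the minimal
library-size-correct unit; the source analysis did not state its unit).
Window means are taken over early (5, 15 min), middle (33, 45 min) and late
(63, 75, 92 min) observations, and the class is the argmax, ties broken to
the earlier window. The 0- and 30-min (and 60-min) samples fall in no
window; they are displayed in profiles but excluded from classification by
default, because the class windows skip them. Genes whose CPM never reaches
`min_cpm` (default 1) are flagged artifacts — the analogue of predicted
genes with minimal, flat expression that turn out to be annotation
artifacts. For heatmap display each gene is scaled to its own maximum, so
color encodes timing rather than level.

## Host differential expression

Normalization factors are the per-sample column totals of the analyzed
matrix rescaled to geometric mean 1 (so "library size" is defined relative
to the genes under test). A common dispersion φ is estimated by method of
moments on normalized counts — per gene and replicated group,
(s² − μ)/μ², averaged over cells with μ > 5 and floored at 0 — and each
timepoint is tested against the 0-min group with a conditional NB exact
test: given the pooled count s, the group-A total is distributed as the
ratio of NB totals with effective sizes equal to the summed normalization
factors, and the two-sided p-value sums the probability of every split at
most as probable as the observed one. With φ = 0 this is exactly the
conditional binomial split test. log₂ fold changes use a prior count of 0.5
so zero counts stay finite. Significance defaults to p < 0.001 — the rule
stated with the published host-response table — with an FDR-threshold mode
available; BH adjustment is computed per contrast. Tagwise dispersion
shrinkage is deliberately omitted: the common-dispersion exact test is the
documented, testable core, and the suite cross-checks it against an
independent implementation of the same test (edgeR's exactTest at fixed
dispersion; agreement is within a few percent, the residual coming from
edgeR's quantile adjustment for unequal library sizes).

## Growth curves

The 0-min untreated titer defines the number of infected cells and both
series are normalized to it. Threshold rules make the readout explicit where
the original procedure read values off a plot: the eclipse period ends at
the first sampled time the chloroform-released (intracellular) series
exceeds `rise_threshold` (default 2× baseline), the latent period at the
first untreated crossing; the burst size is the mean of the longest terminal
run whose relative spread is ≤ `plateau_tol` (default 10%), and the rise
period runs from latency to the plateau start. Flat curves report
`no_rise`; a curve without a plateau reports crossings but no burst. The
bundled reference curve is synthetic, constructed so that these rules
reproduce the reported kinetics (eclipse 30 min, latent 40 min, rise
20 min, burst 138 PFU per infected cell).

## The simulator

The simulator generates the statistical structure the pipeline assumes, with
two constructions that turn likely truths into exact ones:

* **Subtraction truth.** Host and phage genomes share no 31-mer; any
  colliding window is resampled. Every read pair carries an origin label
  (host / phage / junk).
* **Annotation truth.** Phage genes are real ORFs: a start codon, non-stop
  codons at AT-rich composition, and a stop. Every 8 random codons a 4-codon
  "stop-seed" block (`TTA GTT AAT CAA`) is inserted — it contains stop
  codons in all five non-coding frames and none in the coding frame — so no
  spurious ORF of ≥ 30 codons can survive inside a gene on any other frame
  or strand. Intergenic gaps carry a 12-mer with stops in all six frames
  (`TTAATTAGTTAA`), so no ORF crosses a gap, and each gene has an in-frame
  stop immediately upstream of its start codon, so the maximal-ORF rule
  recovers exactly the true start. An `AGGAGG` box sits 8 nt upstream of
  every start. Genome GC is pulled onto the configured value (default 0.323)
  by flipping bases only within the free random gap stretches.

Phage "transcripts" are the gene ± 100 bp, clamped at the genome ends;
consecutive transcripts therefore overlap by more than a read length,
emulating the overlapping polycistronic transcription that makes a whole
phage genome recoverable from RNA — the premise of the subtractive-assembly
approach. Expression follows a per-class piecewise-linear profile (rise to
the peak window, decay after, floor at 4% of peak) times a per-gene
lognormal amplitude (σ = 0.5); classes are assigned in contiguous blocks
along the genome (early → middle → late), as in real phage genome
organization. Host genes get lognormal base abundances (σ = 1); planted DE
genes shift by 2^logFC from their onset timepoint. Each sample's reads are a
multinomial draw over transcripts with the host share fixed by a
time-decaying schedule (0.98 at 0 min → 0.40 at 92 min; unstated in the
source study, chosen once as a plausible infection trajectory) plus 1% junk;
fragments are normal inserts (220 ± 30 bp), 150-nt mates, iid substitution
errors (default 0.5%), constant Q37 qualities with an optional degraded-tail
mode for exercising QC. Fragment and error randomness run on separate
substreams of one seed, so the same seed produces identical fragments at any
error rate. The full default design mirrors the emulated study: duplicates
at 0/5/15/30 min (MOI 50), singletons at 33/45/63/75/92 min (MOI 10),
triplicates at 0/15/30/60 min (MOI 50), 12,000 pairs per sample.

**What the simulator does not emulate** — rRNA carryover and depletion,
platform-specific error and quality profiles, coverage biases (GC, fragment
ends), operonic co-transcription beyond pairwise transcript overlap, genome
modification chemistry, and strand-specific library artifacts. Passing tests
therefore demonstrate the pipeline's logic under its stated assumptions, not
its performance on any particular instrument's data.

## Numerical and evaluation choices

* Rank-correlation checks between counted and expected gene abundances are
  computed where ranks are informative: within a sample's peaking class and
  over genes pooled across samples. Off-window genes share one baseline
  abundance by construction, so their per-sample ranks are multinomial noise
  and a blanket per-sample correlation bound would measure the tie structure,
  not the counting.
* DE recovery on the simulation is scored among truth genes with baseline
  mean ≥ 10 counts: below that, a 2–4-fold shift is undetectable at
  p < 0.001 with triplicates for any method.
* Genome recovery is measured through exact 31-mers (a position counts when
  a kept-scaffold k-mer occurring in the true genome covers it), and gene
  recovery through exact coding-sequence identity — assembled scaffolds have
  no shared coordinate system with the truth, sequences do.
* Display rounding is half-up to one decimal (Python's `Decimal`), matching
  the published tables' convention; all internal arithmetic is double
  precision.
* Determinism: all randomness flows from one seed through fixed
  `SeedSequence` spawns (genomes, expression, then one substream per
  sample); the pipeline itself is RNG-free, so identical inputs give
  byte-identical outputs.

## Problem sizes

Defaults are desk-scale by design: a 50 kb phage (the published 143,296 bp
YerA41 scale is supported and tested for exact length), 200 kb host, 25 samples × 12,000
pairs. At these sizes the full pipeline runs in ~2 minutes and the complete
test suite in ~7 minutes on one CPU.

## Known limitations

* The assembler has no repeat resolution beyond unitig boundaries and no gap
  filling; exact repeats longer than k fragment the assembly (by design, and
  exercised in tests).
* The identity screen cannot detect non-host contamination.
* The NB test uses one common dispersion; strongly gene-dependent
  overdispersion will inflate or deflate per-gene significance relative to a
  tagwise-shrinkage analysis.
* k-mer quantification discards pairs that match two genes equally; for
  genes with long exact duplications most reads become ambiguous.
* The RBS score is a motif-substring length, not a free-energy model.
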