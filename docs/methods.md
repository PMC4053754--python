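# Methods

This note documents the models, conventions and numerical choices behind
`txdominance`, and what the synthetic benchmarks do and do not demonstrate.

## Annotation model and derived structure

The annotation is held as genes → transcripts → exons/CDS with per-record
biotypes. Internal coordinates are 0-based half-open on both strands; GTF
input/output converts the on-disk 1-based inclusive convention exactly at
the boundary, and a write/parse round trip preserves every interval. Both
the GENCODE (`gene_type`/`transcript_type`) and Ensembl
(`gene_biotype`/`transcript_biotype`) attribute dialects are accepted.

Derived structure:

- **Study set** — protein-coding genes, minus any gene with an annotated
  transcript shorter than 300 nt (such transcripts are lost to the size
  selection step of standard library preparation, so their genes cannot be
  quantified faithfully). The rule is strict (`< 300`); a gene whose
  shortest transcript is exactly 300 nt stays.
- **Introns** — maximal regions inside the gene span (min exon start to max
  exon end over all transcripts) overlapped by no exon of any transcript.
  The gene span, rather than a per-transcript span, anchors the definition;
  introns and the exon union therefore tile the span exactly, which the
  test suite asserts on random generator output.
- **TSS groups** — transcripts grouped by the strand-aware 5'-most
  transcribed base, with exact coordinate equality (no fuzz window). Only
  multi-transcript groups enter TSS-level dominance analysis, which asks
  whether dominance persists when transcription start is held fixed and
  differences are attributable to splicing.
- **Unique junctions** — junction identity is (chrom, donor, acceptor,
  strand) with donor = upstream exon end and acceptor = downstream exon
  start in half-open coordinates. A junction is unique when exactly one
  transcript of the gene contains it; a gene is *fully identifiable* when
  every transcript has at least one unique junction. Single-exon
  transcripts are never identifiable.
- **Length flags** — "longest transcript" and "longest CDS" are strict
  maxima over the gene; ties flag every maximum rather than choosing
  arbitrarily.
- **Mitochondrial genes** — recognized by chromosome name
  ({MT, chrM, M}, configurable) and excluded from all mRNA-pool mass
  calculations, because their per-cell copy number would otherwise dominate
  the denominator.

## Expression conventions

FPKM = count × 10⁹ / (feature length in nt × library size). The conversion
is linear in counts and exact; no prior or shrinkage is applied.

Gene expression is the mean FPKM over the gene's *expressed* exons, where
"expressed" means FPKM strictly greater than a threshold (default 0). This
exon-based track is deliberately independent of the transcript quantifier,
so the gene-level expression gate does not inherit the quantifier's
deconvolution errors; a consequence is that the expressed
transcripts-to-genes ratio can fall below 1.

A gene enters major-transcript calling in a sample only when its gene FPKM
strictly exceeds the expression gate (default 1 FPKM, the conventional
minimum for downstream protein detectability). Given an expressed gene, its
transcripts are considered detected regardless of their own level.

## Dominance

The **major** transcript is the highest-FPKM transcript of an expressed
gene in a sample; ties are broken toward the lexicographically smallest
transcript id and flagged explicitly. The **fold ratio** is major FPKM over
runner-up FPKM (+∞ when there is no runner-up or its FPKM is 0 — a single
expressed isoform is maximally dominant). The major is **x-fold dominant**
when the fold ratio is ≥ x; since a tie gives ratio 1, tied majors are
never dominant.

Pool fractions divide the summed FPKM of a transcript class (majors,
two-fold dominant majors, five-fold dominant majors, non-coding majors) by
the summed FPKM of *all* study-set transcripts in the sample, mitochondrial
genes excluded on both sides. Threshold sweeps report, per sample and gate
(1/5/10 FPKM by default), the expressed-gene count as a percentage of the
full study-set size and the dominant counts as percentages of the expressed
genes of that same sample and gate — exact per-sample ratios, not averaged
percentages.

## Switch events

Gene G undergoes an x-fold switch between transcripts I_k and I_l in
samples S_i and S_j when G passes the expression gate in both samples and
expression(I_k)/expression(I_l) is ≥ x in S_i and ≤ 1/x in S_j. Candidate
pairs are the two samples' major transcripts (a switch requires different
majors); an exhaustive all-pairs scan is available behind a flag. A ratio
with zero denominator is treated as +∞, which passes the ≥ x condition and
fails ≤ 1/x; 0/0 yields no event.

A switch is **strong** when I_k in S_i and I_l in S_j are ≥ 5 FPKM while
I_k in S_j and I_l in S_i are strictly < 1 FPKM — the boundary conventions
(≥ 5, < 1) are applied exactly as stated. A switch is **expression
dependent** when the gene's |FPKM difference| between the two samples
exceeds the mean of that quantity over all genes expressed in both samples
of the pair; the per-pair all-genes mean is a documented design choice, as
the referent of "the mean" is genuinely open. Switch expression profiles
use log base 2, with a NaN sentinel when either transcript is at 0.

The protein-level subset keeps strong switches whose transcripts both have
annotated CDS with *different* genomic CDS interval sets — a conservative
proxy for a protein change; no translation is performed, so identical CDS
with different UTRs are excluded.

Pairwise scans cover all n(n−1)/2 unordered sample pairs and tally events
separately for replicate pairs (same condition label) and condition pairs,
so replicated designs expose how many events survive technical/biological
replication.

## Biotype accounting

A major is non-coding when its transcript has no annotated CDS. Counts and
mass fractions are tracked for the classes protein_coding, retained_intron,
processed_transcript, nonsense_mediated_decay and other; class mass
fractions share the pool denominator and recompose the overall major
fraction (asserted to 1e-9). Compartment aggregation uses unweighted means
over the samples of each compartment.

The **retained region** of a retained-intron major is its exonic sequence
covered by no *other* transcript of the gene. (The gene-level intron
complement is empty by construction once the retaining transcript's own
exon is included, so this other-transcripts definition is the one under
which the analysis is non-vacuous.) When several regions exist the most 3'
one is summarized. Its position is the strand-aware relative location of
the region midpoint within the gene span (0 = transcriptional start, 1 =
end), so mirroring a gene maps p → 1 − p.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes; its
defaults are the package's study conditions.

- **Gene structure.** Each gene has K transcripts (default 4) on a shared
  scaffold of K + 2 skippable-plus-flanking exons plus 6 constitutive extra
  exons; exon lengths are uniform on 100–300 nt and intron lengths on
  200–500 nt, giving transcripts well above the 300 nt study-set floor.
  Transcript k skips one distinct internal exon, so with unique-junction
  probability 1 every transcript owns a private skip junction and the gene
  is fully identifiable; lowering the probability makes transcripts collide
  on the same skip and lose identifiability. Coding transcripts carry their
  internal exons as CDS, so different skips imply different CDS sets.
- **Non-coding majors.** A configurable fraction of genes replaces its
  designated major with a retained-intron variant (the intron whose
  strand-aware midpoint lies nearest a target position, default 0.8, merged
  into the exon chain; no CDS) or a processed-transcript variant (same
  chain, no CDS). The extra constitutive exons exist precisely so the
  intron grid is fine enough (≈ 0.09 spacing) for the planted positions to
  land near the target.
- **Abundances.** The *dominant* scenario gives the designated major a
  fixed fraction p (default 0.8) and splits the rest evenly — the true fold
  ratio at K = 4 is 0.8/0.0667 = 12. The *uniform* scenario draws symmetric
  Dirichlet(α = 10) fractions per gene and sample. Gene totals are
  log-normal with natural-log mean 3 and sd 1 (median ≈ 20 FPKM) and a mild
  per-sample factor (sd 0.25), values chosen once as representative of
  moderately expressed protein-coding genes.
- **Counts.** Feature-level Poisson at a configurable depth (default 5M
  reads): the expected count of an exonic bin (disjoint bins from all exon
  boundary points), junction (effective length = 75 nt read span) or
  transcript is the covering transcripts' summed FPKM × length × depth /
  10⁹. Intron counts model splicing leakage (1 % of gene expression,
  doubled in nuclear samples). This is a deliberate simplification of
  read-level simulation — no fragment-length, positional or mappability
  bias — but it is sufficient for every statistic the pipeline computes,
  and in noiseless mode counts equal expectations exactly, making FPKM
  conversion an exact inverse.
- **Planted switches.** A planted event pins a gene's total to 20 FPKM in
  all samples, gives the pair (designated major, another coding transcript)
  fractions (0.8, 0.02) in one sample and (0.02, 0.8) in the other, and
  leaves the remaining samples in the dominant pattern. The construction
  satisfies the strong-switch conditions (16 ≥ 5, 0.4 < 1) in the planted
  pair while keeping untouched-sample minors at ≥ 1 FPKM, so no strong
  event exists outside the registry; the generator refuses configurations
  (very large K or low totals) where that guarantee would fail.

All randomness flows from one seed; identical scenarios produce
byte-identical outputs, which the suite asserts.

**What the benchmarks do and do not show.** Synthetic recovery (100 %
major-call accuracy noiseless, ≥ 95 % two-fold dominance under Poisson
noise, oracle-matching Dirichlet dominance rates, perfect planted-switch
recall, 100 % junction concordance) demonstrates that the *pipeline logic*
is correct and noise-robust under the generative model. It does not
demonstrate accuracy on real data, where the dominant error source is the
transcript quantifier's deconvolution of shared exons — here transcript
FPKMs are observed (noisily) per transcript, so quantifier identifiability
error is absent by design. Real-data percentages therefore depend on the
chosen quantifier and annotation version in ways these benchmarks cannot
capture.

## Numerical and reporting choices

- Ties: major ties → lexicographic winner + flag; junction-support ties →
  no call (conservative for junction-vs-quantifier agreement).
- Published-table checks: expressed-gene percentages reproduce from the
  printed counts divided by the printed study-set size (18,450) to two
  decimals; the dominance percentage cells of that table do not reproduce
  as exact row ratios (for example 8,179/10,410 = 78.57 % vs a printed
  78.51 %), suggesting they were averaged differently, so the package
  reports exact per-sample ratios and makes no attempt to match those
  cells.
- Outputs are written with fixed float formatting (6 significant digits)
  and stable row ordering, so fixed-seed reruns are byte-identical.
- Degenerate inputs: silent gene-samples yield NaN relative abundances
  (flagged), expressed genes with all-zero transcript FPKMs yield no major
  call (logged), empty GTFs yield empty models with a warning, and
  zero-length features are hard errors naming the feature.

## Known limitations

- No read-level simulation (fragment bias, positional bias, mappability),
  no BAM/FASTQ handling, and no re-implementation of transcript
  quantification: the pipeline consumes a transcript FPKM matrix.
- The protein-change proxy compares CDS genomic intervals; it does not
  translate sequence and cannot detect synonymous-interval frame changes.
- Expression-dependence of switches uses the per-pair mean |gene FPKM
  difference|; other referents (global mean, per-gene variance) are
  plausible and would shift the dependent/independent split.
- TSS grouping uses exact coordinate equality; annotations with jittered
  start sites would need a tolerance window.
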