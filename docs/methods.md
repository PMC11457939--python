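# Methods

## Tail calling model

A sequencing read of a 3′-modified RNA is the concatenation of a
*templated body* — a subsequence of the genome (possibly on the minus
strand) — and a *nontemplated tail* added enzymatically. The caller
recovers this boundary with a maximal-prefix convention: the body is the
longest read prefix that matches the genome exactly on either strand at
a unique location (seed length = minimum body = 15 nt, greedy base-wise
extension), and the remaining suffix is the tail, reported 5′→3′ in the
RNA alphabet. Consequences of this convention:

* a tail whose first base coincides with the genomic continuation is
  absorbed into the body, so reported tails are maximally short. This is
  the same bias aligner soft-clipping produces, and it systematically
  undercounts tails that start with a templated-looking base (~1/4 of
  single-nucleotide tails on random sequence). It is a property of the
  method, not a defect of this implementation;
* reads whose longest prefix matches more than one location are
  discarded as multimappers — conservative and deterministic; they are
  neither assigned at random nor fractionally counted;
* matching is exact (no body mismatches). For real, error-containing
  data the SAM/BAM ingestion path (`call_tails_sam`) takes aligner
  soft-clipped 3′ suffixes as tail candidates and applies the same
  greedy absorption, giving identical calls on identical alignments.

Retention precedes mapping: 3′ bases under Q20 are trimmed and the read
kept only if 15–26 nt remain. Tail typing collapses homopolymeric tails
of any length to their base (A/C/G/U); mixed tails (e.g. UG) are
"other"; an empty suffix is "none". The last templated nucleotide is the
final body base in read orientation.

Species assignment: a body lying sense within a miRNA or piRNA locus is
that class; a body antisense to a protein-coding gene with ≥90% of its
length covered by the gene's CDS exons is an siRNA of that gene (all
antisense reads of one gene form one species). The 0.9 coverage fraction
is a declared choice — the definition "antisense to CDS" carries no
threshold — and is configurable. When several definitions apply the
precedence is miRNA > piRNA > siRNA; within-class conflicts (overlapping
genes) are resolved to the lexicographically first gene and logged.

## Quantification

U-tail frequency of a species in a genotype is pooled across replicates:
Σ U-tailed reads / Σ total reads, on raw counts (not CPM) — a
depth-weighted mean, deliberately not the mean of per-replicate
frequencies. A genotype with zero reads for a species yields a missing
value, never zero. log₂FC of uridylation is log₂(mutant/wild type), with
±∞ sentinels when one side is zero. CPM uses retained, uniquely mapped,
species-assigned reads as the library size; whether the original
workflow's denominator counted all mapped reads is not stated anywhere
we could find, so the choice is declared here and carried in output
metadata.

## Selection filters

* Abundance: keep species with ≥50 CPM in at least k samples, k = the
  smallest group size (the filterByExpr heuristic restated explicitly and
  made configurable).
* Overlap filter: per mutant, compare the [min, max] range of the three
  wild-type replicate frequencies with the mutant range; strictly
  disjoint ranges ⇒ "up" or "down" by direction, touching endpoints ⇒
  overlap ("did not overlap" read literally; the opposite convention is a
  one-flag change). Under exchangeability the probability of a false
  "altered" call is 2·3!·3!/6! = 0.10 for continuous values (0.05 per
  direction); discreteness (ties) only lowers it. Species with an
  undefined frequency in any replicate of a comparison are excluded from
  that comparison rather than guessed.
* High-confidence targets: union over mutants of "altered" species, with
  UpSet-style counts per direction pattern.

## mRNA tail classification

mRNA-end reads are aligned as suffixes of their transcript (seed 20 nt,
exact match); the nontemplated remainder is parsed as a maximal A-run
followed by a maximal U-run. Classes: strict poly(A) (A-run ≥ min_a = 3,
no qualifying U-run), strict poly(U) (U-run ≥3 with *no* leading
A-run), A+U (A-run ≥3 then U-run ≥3), none otherwise. U-runs shorter
than 3 nt are ignored and suffixes that are not A-then-U shaped are
unclassifiable — both mirror the stated resolution floor of signal-space
tail calling on nanopore data, so strict-U and A+U counts are
undercounts by design. min_a has no published counterpart; 3 was chosen
for symmetry with the U floor and is configurable. Length means/modes
use only tail-length groups with ≥50 reads; class fractions are the mean
over replicates of per-replicate read fractions (the pooled-vs-averaged
alternative differs only at unequal depths and both are exposed).

## Synthetic data

The generator emulates the wild-type and *pup*-mutant tailing profiles
of the *C. elegans* adult hermaphrodite and is the package's test bed:

* class U-tail frequencies 14% / 6% / 4% (siRNA/miRNA/piRNA) in wild
  type; U-tail length mixtures 64/20/10/4/2% (U₁…U₅) for siRNAs, 94% and
  96% U₁ for miRNAs and piRNAs; *pup-1* null collapses all classes to 3%
  with 93% U₁; the *pup-3* null mRNA profile has 78% strict A, 1.5%
  strict U, 0.58% A+U versus 72/3.4/0.93% in wild type;
* the tail-type mixture beyond U is not individually quantified in the
  source data; it is fixed at U 0.8 / A 0.1 / C 0.03 / G 0.03 / other
  0.04, and each class's overall tailing probability p_tail is set so
  p_tail × P(U) reproduces the class U-frequency. "Other" tails are 2-nt
  heterogeneous pairs;
* mRNA strict-A lengths: spikes at the modal lengths 30 and 33 nt over a
  uniform 15–94 nt background, mean ≈51 nt. Strict-U lengths: an explicit
  distribution on 3–12 nt with mode 3 and mean ≈5.1. A bounded support
  was preferred over a geometric tail because the ≥50-reads/length-group
  profiling rule would otherwise truncate the long tail at desk scale and
  the profiled mean would mostly measure that truncation;
* siRNA bodies are reverse complements of CDS-exon windows, miRNA/piRNA
  bodies sense windows of their loci, 18–24 nt, capped at 26 − tail
  length so every simulated read survives retention (otherwise
  long-tailed reads would be preferentially rejected and the configured
  mixtures distorted). Body and expression-level distributions of real
  sRNA species are unknown; bodies are uniform and species abundances
  log-uniform over two decades — both arbitrary and declared;
* the boundary between body and tail is made unambiguous by re-drawing
  the *body window* (not the tail) until the genomic continuation base
  differs from the tail's first base. Re-sampling the tail instead would
  condition the tail-type mixture on genomic context and bias the very
  frequencies the recovery tests measure;
* mRNA-end reads are 40–80 nt transcript suffixes that always reach the
  transcript 3′ end, so appended tails are nontemplated by construction.

What passing tests on these fixtures do **not** show: robustness to
sequencing error, PCR duplication, adapters, multimapping-rich repeat
content, annotation errors, or signal-space tail length noise — none of
which the generator models.

## Downstream statistics

Differential abundance is a declared simplification of a
negative-binomial workflow: two-sided two-sample t-test on
log₂(CPM + 0.5), BH correction, significance at |log₂FC| > 1 with
FDR < 0.05 (sRNA) or 0.01 (mRNA). The stage is pluggable so externally
computed results can be substituted as a table. Argonaute summaries
count an sRNA once per associated Argonaute ("not_enriched" otherwise).
The tissue specificity index is S_t = 1 − JSdist(p, e_t) (Jensen-Shannon
distance, log base 2); genes are assigned their argmax tissue, or
"ubiquitous" when max S_t < 0.6 — the threshold has no published value
for this use and is configurable. Category enrichment uses per-category
2×2 χ² tests with BH correction, switching to Yates' continuity
correction when any expected cell is below 5.

## Numerical and scale choices

Reference generation places features by bounded rejection sampling and
fails loudly when the chromosome is too small. Benchmarks default to a
400 kb genome, 200 siRNA / 80 miRNA / 80 piRNA species, 3×90,000 sRNA
reads per genotype and 3×40,000 mRNA-end reads — sizes at which every
recovered statistic has a standard error well under the differences of
interest while a full two-genotype run completes in well under a minute.
All randomness flows from a single integer seed per run; fixed seed ⇒
byte-identical FASTQ and truth tables.

## Known limitations

Exact-match mapping ignores SNVs/errors in the body (use the SAM path
with a mismatch-tolerant aligner for real data). Tails starting with the
templated continuation base are systematically absorbed (shared with
soft-clip approaches; quantified exactly on fixtures because the
generator avoids the ambiguity). The overlap filter's stringency grows
with replicate count; it is calibrated for the 3 vs 3 design. The
differential-abundance stand-in does not model count dispersion and is
conservative at low counts.
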