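# utailor

Nontemplated 3′ tail calling and uridylation analysis for small RNAs and
mRNA 3′ ends.

Terminal nucleotidyltransferases — in *C. elegans*, the poly(U)
polymerases PUP-1/-2/-3/-4 — add untemplated nucleotides, chiefly
uridines, to the 3′ ends of siRNAs, miRNAs, piRNAs and mRNAs.
Uridylation marks RNAs for turnover or retargeting, and its loss in
*pup* mutants reshapes the small RNAome. Measuring it from sequencing
data requires calling, for every read, which 3′ bases are templated by
the genome and which were added enzymatically — and then aggregating
those calls into per-species modification frequencies that can be
compared across genotypes.

`utailor` implements that pipeline end to end, together with a
ground-truth read simulator so that every stage can be validated exactly:

* **simulate** — toy genome/annotation plus sRNA and mRNA-end reads with
  known tails, parameterised by genotype profiles (wild type, *pup-1*
  null, *pup-3* null);
* **call-tails** — read retention (15–26 nt after 3′ Q20 trimming),
  exact maximal-prefix mapping to both genome strands, tail extraction,
  and species classification (siRNA = reads antisense to one gene's CDS
  exons; miRNA/piRNA = sense reads within annotated loci). A SAM/BAM
  ingestion path applies the same rules to aligner soft-clips;
* **quantify** — per-species U-tail frequency, pooled across replicates
  as Σ U-tailed / Σ total reads on raw counts; CPM; log₂ fold change of
  uridylation; tail-length spectra; last-templated-nucleotide profiles;
* **filter** — the 50-CPM abundance cutoff and the replicate-range
  overlap filter: a species' uridylation is *meaningfully altered* in a
  mutant only when the [min, max] range of its per-replicate frequencies
  is strictly disjoint from the wild-type range. Species altered in ≥1
  mutant are the high-confidence uridylation targets;
* **mrna-tails** — poly(U)-aware mRNA tail classification: the
  nontemplated suffix is parsed as an A-run then U-run and called strict
  poly(A), strict poly(U) (≥3 U), A+U, or unclassifiable, with length
  statistics over groups of ≥50 reads;
* **report** — a simplified differential-abundance stand-in (t-test on
  log₂ CPM + BH), Argonaute-association summaries, and a tissue
  specificity index `S_t = 1 − JSdist(p, e_t)` with per-category χ²
  enrichment tests.

## Worked example

```python
from utailor import (make_reference, wild_type_profile,
                     build_species_table, uridylation_frequencies)
from utailor.benchmarks import run_srna_pipeline
from utailor.quant import tail_length_counts, tail_length_spectrum

ref = make_reference(n_genes=60, n_mirna=15, n_pirna=15,
                     chrom_len=200_000, seed=0)
profile = wild_type_profile(
    n_species_per_class={"siRNA": 40, "miRNA": 15, "piRNA": 15},
    reads_per_replicate=30_000, n_replicates=3, seed=0)
calls, truth = run_srna_pipeline(ref, profile)          # simulate + call
table = build_species_table(calls)
freqs = uridylation_frequencies(
    table, {f"rep{i}": "wild_type" for i in (1, 2, 3)})
print(freqs.groupby("species_class")["pooled_u_freq"].mean().round(3))
lc = tail_length_counts(calls).merge(
    calls[["species_id", "species_class"]].drop_duplicates(),
    on="species_id")
print(tail_length_spectrum(lc, species_class="siRNA").round(3).head(5))
```

prints

```
species_class
miRNA    0.065
piRNA    0.042
siRNA    0.137
Name: pooled_u_freq, dtype: float64
tail_len
1    0.636
2    0.205
3    0.101
4    0.037
5    0.021
Name: count, dtype: float64
```

i.e. the pipeline recovers the wild-type profile it simulated: mean
per-species U-tail frequencies of ~14% (siRNA), ~6% (miRNA), ~4%
(piRNA), with single uridines making up ~64% of siRNA U-tails, ~20%
(U)₂ and ~10% (U)₃. The same stages are available from the shell
(`utailor simulate | call-tails | quantify | filter | mrna-tails |
report`); see `utailor --help`.

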