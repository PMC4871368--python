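# Methods

## The question and the design

A hybrid species formed from two divergent parental lineages carries both
parental allele sets in one genome. Where one parental taxon is available
for sequencing and the other is unknown or extinct, the hybrid hypothesis
can still be tested from expressed sequence alone by comparing allelic
diversity *within* each taxon and *between* them. `hybridtest` operationalizes
this as a reciprocal-mapping design over four read-source × transcript-source
combinations (hybrid/parent reads × hybrid/parent transcript assemblies),
with each curated transcript assembly treated as an independent locus.

## Generative model (synthetic data)

The generator emulates the study system — a diploid parent and a triploid
hybrid sequenced as single-end 100 b cDNA reads — with known ground truth:

- **Locus lengths** are lognormal (default mean 600 b, SD 300 b, floor
  200 b), matching the length scale and right skew of de novo transcript
  assemblies; the floor also guarantees every locus fits a full read.
- **Parent**: two haplotypes per locus; each site is heterozygous
  independently with probability *h* (default 0.002, a low-diversity
  outbred diploid), the alternative base drawn uniformly from the other
  three. Expected minor-read fraction at a het site: 1/2.
- **Maternal lineage**: one haplotype derived from the first paternal
  haplotype by per-site substitution at rate *d* (default 0.02, a few
  percent cross-species divergence); substitutions never restore the
  original base.
- **Hybrid**: copy set per `hybrid_composition = (n_pat, n_mat)` (default
  (1, 2), a triploid with a doubled maternal subgenome). Paternal copies
  cycle over the parent's two haplotypes so that composition (3, 0) is the
  autopolyploid control whose only variable sites are the parent's
  heterozygous ones. Truth tables record, per variable site, the minor base,
  the copies carrying it and its expected read fraction
  (carriers / ploidy) — e.g. 1/3 for a (1, 2) difference site.
- **Consensus transcripts** take the per-site majority base over copies
  (ties to the first-listed, paternal copy), reproducing the way de novo
  assembly collapses allelic variation into one sequence: a (1, 2)
  difference site is written with the *maternal* base.
- **Redundant contigs** mimic a k-mer-sweep assembly, whose contigs for one
  transcript are near-identical and vary at the ends: fragments are the
  consensus under random end trims (up to ~L/6 per end). The first fragment
  keeps the 5' end, the second the 3' end (guaranteeing locus coverage and
  one overlapping-but-not-contained pair); the third is strictly contained
  in the first. Ground-truth containment relations are recorded by
  brute-force substring tests on both strands.
- **Reads**: per-locus read counts are Poisson with mean
  coverage · L / read_length; the source copy is uniform over genome copies
  (expression proportional to dosage, the assumption that links dosage to
  read fraction), start positions uniform, strand random, per-base errors
  at `error_rate` (default 0.002) substituting a uniform other base.
  Quality strings are constant at the phred encoding of the error rate.

Everything is driven by `numpy.random.Generator` streams seeded from the
config (per-stage `SeedSequence` keys), so a config is byte-reproducible.

What the generator does **not** emulate: expression heterogeneity across
loci, splice variants, indels, RNA degradation, within-individual mosaicism
of the hybrid composition, position-dependent quality, and paralogy.
Passing tests therefore demonstrate the pipeline's correctness under
SNP-only divergence with uniform dosage-proportional expression — not
robustness to paralog collapse or splice artifacts, which the study design
addresses by manual curation.

## Curation

1. **Length floor** — contigs under 200 b are dropped (the CLI default; the
   synthetic pipeline lowers the floor beneath its fragment lengths).
2. **Containment removal** — a contig that is an exact substring of a
   longer retained contig on either strand is removed; overlapping but
   non-contained contigs are all retained. Near-containment with mismatches
   is deliberately not removed. The operation is idempotent.
3. **Clustering** — single-linkage components over the graph joining
   contigs that share ≥ 50% of the smaller contig's canonical 21-mers.
   This is a deterministic, desk-scale stand-in filling the same role as
   orthology-based clustering of transcripts into loci: near-identical
   end-trimmed contigs of one transcript share most of their k-mers, while
   unrelated transcripts share almost none.
4. **Consensus** — cluster members are laid out by best ungapped overlap
   (match counts for all offsets computed by per-base correlation; minimum
   overlap 15, minimum identity 0.8), members whose first/last 5 bases
   disagree with the column majority have those 5 bases deleted (end
   miscalls concentrate where contig coverage drops), and the per-column
   majority is taken. Disconnected layouts yield several super-contigs; the
   longest is selected and the cluster flagged `multi_supercontig`. All
   tie-breaks are lexicographic on sequence, then identifier.

## Mapping

Reads are quality-trimmed to the longest contiguous segment whose per-base
error probability meets the threshold (ties leftmost; `TrimConfig` default
0.001, the most stringent of the 0.01 / 0.003 / 0.001 settings). Because
simulated qualities are constant, trimming there is all-or-nothing, and the
synthetic pipeline uses the 0.01 threshold so that default-error (Q27)
reads pass; the stricter settings are exercised with variable-quality reads
in the tests.

All transcripts are indexed simultaneously (exact 16-mer seeds, both
strands) and each read receives at most one placement: candidates from seed
diagonals are extended without gaps across the read, placements with fewer
than `min_mapped_length` aligned bases (default 12) or mismatch rate above
10% are rejected, and the single highest-scoring placement
(score = matches − mismatches; ties to lowest transcript id, then start,
then forward strand) is kept. Mapped length counts aligned bases (matches
plus mismatches). Gapped alignment is unsupported — the generator emits no
indels and the analysis is substitution-only. Reverse-strand bases are
complemented into transcript orientation before pileup; cDNA is treated as
unstranded.

## Variant calling and per-locus rates

Pileups accumulate per-position base counts (strand-split, for
diagnostics — no strand-bias filter is applied). A SNP is called where

- coverage ≥ `min_coverage` (default 8),
- variant reads ≥ `min_variant_reads` (default 2),
- variant frequency ≥ `min_variant_frequency` (default 0.10),

with `primary` the reference (transcript) base and `variant` the most
frequent non-reference base; only that one alternative allele is reported
per position. Defining the frequency against the reference rather than as
"second most frequent base" matters for cross-mapping: at a site where the
reference carries the other taxon's allele, nearly all reads disagree with
it and the variant frequency approaches 1 — such sites are SNPs (evidence
of divergence), and self-mapping is unaffected because there the reference
is the consensus of the very reads being piled up. The 10% threshold is the
conservative evidence level for two alleles being present; the coverage and
variant-read floors are the customary defaults of pileup-based variant
detectors. Base qualities are not used in calling (the threshold is on read
counts).

Per locus, `n_snps / length` gives the SNP rate per nucleotide and
`n_snps = 0` marks the locus SNP-free. All transcripts count in SNP-free
denominators, with a `low_coverage` flag (median coverage below
`min_coverage`) carried for reporting, since excluding unmappable loci
would bias the proportions the hypothesis test compares.

## Coding subset

ORFs are stop-to-stop (no start codon required — assembled transcripts are
5'/3'-truncated), measured in nucleotides over all six frames. GC content
is (G+C)/(A+C+G+T) with ambiguity codes excluded. Transcripts at GC ≥ 0.48
form the predominantly protein-coding subset on which the hypothesis
statistics can be re-run as a robustness check; the threshold is adopted as
a constant.

## Hypothesis evaluation

For each combination, the SNP-free count/proportion and the per-locus rate
distribution are computed; the density-plot view excludes SNP-free loci,
and the heat-map view is the 2D histogram of per-locus rates for two read
sources on a shared transcript set.

- **Prediction 1** (excess diversity): supported when the hybrid's
  self-mapping SNP-free proportion is below the parent's with Pearson
  chi-squared (2×2, 1 df, no continuity correction) p < α (default 10⁻⁴,
  the significance convention used throughout the reporting).
- **Prediction 2** (allelic nesting) is a verbal prediction made testable
  as three conditions, all required:
  (a) per-locus SNP rates of parent reads on hybrid transcripts sit
  significantly below a **no-shared-ancestry null** — the same pipeline run
  with an independent lineage at divergence 2·d in place of the hybrid
  (one-sided Mann–Whitney, p < α). Rates are used rather than SNP-free
  proportions because at percent-scale divergence essentially no locus is
  SNP-free in either arm, and a saturated proportion carries no signal;
  (b) **heat-map symmetry**: medians of the within-hybrid and
  parent-on-hybrid rate distributions (SNP-free loci excluded) differ by at
  most 20% of their mean — within-hybrid allelic divergence equals
  parent-to-hybrid divergence when the parent really is a parent;
  (c) hybrid reads on parent transcripts show significantly fewer SNP-free
  loci than the parent's self-mapping — the divergent (maternal) allele
  class is actually present in the hybrid. Condition (c) is what rejects an
  autopolyploid: its cross-mapping is indistinguishable from the parent's
  self-mapping, while (a) and (b) alone it would pass trivially.
- **Dosage signature**: variant frequencies of calls at coverage ≥ 8 are
  binned at width 0.05 (bin centers on round frequencies); the modal bin
  center, folded onto (0, 0.5], classifies the taxon as triploid-like
  (nearer 1/3), diploid-like (nearer 1/2) or ambiguous (within 0.04 of the
  midpoint 5/12). The classification is reported, not used in the verdict;
  at shallow coverage the binomial spread of frequencies makes the modal
  bin noisy, which is why the signature is best read at deep coverage.

## Problem sizes and numerical choices

The default scenario is 200 loci per taxon at 20× coverage (~2.4 Mb of
reads per taxon); a full two-taxon run including curation, four mapping
combinations and the null simulation completes in well under a minute on
one CPU. The deep-coverage dosage measurement uses one 2,500 b locus at
600×. Degenerate inputs are handled explicitly: empty contig sets warn and
return empty; clusters must be non-empty; chi-squared tables with an
uninformative margin return statistic 0, p = 1; an empty call set yields an
ambiguous signature with an empty histogram. Positions are 1-based in all
reports and VCF output, 0-based half-open internally.

## Known limitations

- The clustering stand-in is k-mer-identity-based and will not group
  transcripts that diverged beyond seed-k-mer identity, nor separate
  recently duplicated paralogs — mirroring the fundamental
  paralog-vs-allele caveat of the design, which is resolvable only when
  between-subgenome divergence exceeds within-parent diversity.
- The mapper is exact-seed ungapped: indels, long reads and spliced
  alignment are out of scope.
- The no-shared-ancestry null fixes the unrelated-lineage divergence at
  2·d; a field application would calibrate this against an outgroup.
- SNP-free proportions are sensitive to coverage through calling
  sensitivity; comparisons across combinations are valid because coverage
  is matched by design, as in the underlying two-taxon sequencing layout.
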