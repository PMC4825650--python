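# Methods

This note records the models, conventions and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
problem sizes the test suite and acceptance script run at.

## Call filtering and the three-list comparison

Calls are kept when all four evidence thresholds hold *inclusively*:
Phred quality ≥ 30, alternate-allele frequency ≥ 5%, depth ≥ 5, and
probability-not-reference ≥ 0.90 (a caller-reported percent divided by
100). Filtering is a pure predicate, hence idempotent.

Hemi-SNPs — reads from a homeologous locus of the other subgenome mapping
to the wrong copy and producing an apparently heterozygous call in a fully
inbred line — are excluded by an allele-frequency band: a call with
frequency strictly inside (0.2, 0.8) is flagged. The band is an operational
choice (the phenomenon is defined by heterozygous appearance, not by a
published numeric band) and is configurable; the open interval keeps calls
at exactly 20% or 80% frequency.

Variant identity is the triple (chromosome, position, alt allele), so two
parents carrying different alternates at one site contribute two records to
the polymorphic set. The three lists are: shared-vs-reference (key in both
parents), parent1-only and parent2-only; the parent-vs-parent polymorphic
set is the union of the two parent-only lists. A site present in both
parents with conflicting *reference* alleles raises an error rather than
being silently resolved.

Manual-review accuracy is a single genome-wide proportion
confirmed/reviewed (e.g. 414/500 = 82.8%) applied multiplicatively to raw
counts; no per-chromosome or per-list rate is modelled because one
genome-wide review is the intended design.

## Effect classification and densities

Gene models are single-transcript (one CDS chain per gene, possibly
multi-exon, either strand); coordinates are 0-based half-open internally
and 1-based in GFF3/VCF on disk. A SNP outside every CDS is noncoding;
inside a CDS the affected codon is substituted in transcript orientation
(minus-strand alleles complemented) and translated with the standard code —
identical amino acid ⇒ synonymous. A SNP inside several overlapping models
counts as nonsynonymous if it changes any protein, and is counted once in
density totals.

Densities are percentages of SNP count over *callable length* (bases at
≥ 5× coverage; in synthetic runs, the generated mask). All four categories
(noncoding, synonymous, nonsynonymous, total) are divided by the same
callable length, which is why noncoding density nearly equals total
density on mostly noncoding chromosomes. Genome-level summaries report
mean and SD across chromosomes; the A-vs-C comparison uses an unpaired
Welch t-test on per-chromosome densities (no homeolog pairing is assumed).
The equal-divergence test is a two-category chi-square goodness of fit
with expectation (c₁+c₂)/2 and 1 df.

## dN/dS

A counting estimator in the Nei–Gojobori (1986) style replaces ML codon
models: at the within-cultivar divergences this pipeline targets (≲ 0.3%
coding), proportion-based counting and ML pairwise estimates coincide to
well within their sampling noise, and counting is exactly testable against
a brute-force pathway oracle.

Conventions:

- Expected synonymous sites per codon position are the fraction of the
  three possible changes that preserve the amino acid; changes *to* a stop
  codon count as nonsynonymous, so sites sum to exactly 3 per codon.
  Site totals average the reference and mutant sequences.
- A codon carrying several substitutions is scored by averaging the step
  classifications over all orderings of the changed positions; orderings
  that pass through a stop codon are dropped unless all do.
- A variant codon that *is* a stop (premature stop gain) is flagged and the
  codon excluded from both substitution and site totals.
- dN = nd/n and dS = sd/s are proportions; a Jukes–Cantor correction is
  available behind a flag but off by default since p ≪ 0.75 here.

The genome-wide aggregate is the **ratio of means**, mean(dN)/mean(dS)
over genes with defined rates — not the mean of per-gene ratios, which is
undefined whenever a gene has dS = 0 (the dominant case at these
densities). The paired bootstrap resamples gene-level (dN, dS) pairs
jointly, preserving their coupling, recomputes the ratio of means per
replicate (replicates with resampled mean dS = 0 are redrawn and counted)
and reports a percentile interval; 10,000 replicates is the default.

## GO enrichment

The per-term statistic is total nonsynonymous SNPs per codon over the
term's genes. The null distribution shuffles the per-gene
(ns count, codon count) **pairs** across gene identities while the
gene-to-term annotation stays fixed; shuffling the pair preserves the
gene-length/SNP-count coupling that makes the density statistic
meaningful. (Shuffling the two arrays independently is available behind a
flag for sensitivity analysis.) P-values use the upper tail (permuted ≥
observed, compared by integer cross-multiplication so ties are exact) with
the (r+1)/(n+1) estimator, so finite runs never report zero. Raw P < 0.01
is the reporting threshold, matching single-test practice for this
statistic; a Benjamini–Hochberg q-value column is emitted alongside for
users who want FDR control. No GO-graph ancestor propagation is performed.

## Multi-mapping profiler

A hit is a distinct start position on the reference where the read or its
reverse complement aligns within the edit budget; the union over strands
avoids double-counting palindromic reads, and a read sampled from the
genome always counts its origin locus. Hamming distance (substitutions
only) is the default — on 100 bp reads a budget of 5 equals a 95% identity
threshold — with a gapped Levenshtein mode backed by edlib. Counts are
capped at 500 per read, mirroring secondary-alignment reporting caps, and
the cap is reported alongside the histogram. The implementation
accumulates mismatch counts incrementally across read offsets and is meant
for toy genomes (≤ ~10 Mbp); it is a desk-scale reimplementation, not a
production aligner.

## DH QTL scanning

DH genotypes are coded {0, 1}. The Kosambi map function
d = 25 ln((1+2r)/(1−2r)) cM links map distance and recombination fraction
(round-trip exact to 1e-10). At a scan position the probability of the
parent-1 allele conditions on the flanking typed markers through the
two-state enumeration of the query genotype; at a typed marker it is 0
or 1, and lines with missing flanks fall back to the nearest typed markers.
Haley–Knott regression fits the phenotype on this expected genotype at
1 cM grid steps; LOD = (n/2) log₁₀(RSS₀/RSS₁), with degenerate
(monomorphic) grid points forced to LOD 0 and logged. The support interval
is the contiguous grid region within 1.5 LOD of the peak, read off the
grid by nearest-point crossing. Genome-wide thresholds take the (1−α)
quantile of the maximum LOD over 1000 phenotype permutations. Map
construction and stepwise multi-QTL selection are out of scope; positions
are taken as given, with a kbp/cM utility (physical length over map
length) for recombination-rate summaries.

In the generator, a single planted QTL with allele-substitution effect *a*
and heritability h² satisfies a/σ_P = 2√h², so an "0.5 SD" effect
corresponds to h² = 1/16; noise is Gaussian with variance scaled to the
realised genetic variance.

## What the synthetic generator emulates — and what it does not

The generator reproduces the *design* downstream of alignment: a reference
with valid single-transcript gene models (ATG start, terminal stop, no
internal stops, CDS divisible by 3), two inbred parents diverged from it
at controlled rates, hemi-SNP artifacts, callable masks, GO tables with
one planted enriched term, a focal insertion in a flowering-annotated
gene, and DH populations on a Kosambi map. Defaults mirror the study
conditions at desk scale: per-parent divergence of a few per mille with
the two parents asymmetric (0.006 vs 0.004), ~30% of each parent's
variants drawn from a shared ancestral pool so the shared-vs-reference
list is populated, coding rate at half the noncoding rate, nonsynonymous
plantings thinned to half (a purifying regime), the C subgenome at 0.7×
the A rate, ts/tv 2.0, 10% hemi-SNP calls with allele frequencies uniform
on [0.25, 0.75] inside a duplicated donor segment, 82% callable fraction,
and a 5× nonsynonymous enrichment on one GO term.

Not emulated: read-level errors and coverage fluctuations (call metadata
are drawn from simple distributions that pass the filters), alignment
artifacts other than hemi-SNPs, indel calling (the focal insertion enters
as a truth record and a genotyped marker, not as called variants),
isoforms, and linked selection. Passing tests therefore demonstrate the
*statistical machinery* — filters, set algebra, codon arithmetic,
permutation and bootstrap calibration, scan localization — on data whose
generative process is known; they do not validate caller behaviour on real
reads.

## Numerical and scale choices

- Integer cross-multiplication for permutation tail comparisons (no float
  ties); seeded `numpy.random.default_rng` everywhere; identical seeds give
  byte-identical outputs.
- Degenerate inputs raise typed errors (zero phenotype variance, empty
  margins, zero callable length with calls present, mean dS = 0) rather
  than returning sentinels; singular regressions inside a scan are the one
  logged-and-continued case.
- Test and acceptance problem sizes are desk scale, chosen so the full
  suite runs in well under a minute per calibration block: trios of 2–4
  chromosomes × 60–600 kb, 200-replicate calibrations (GO type-I, scan
  type-I, QTL recovery), 500-replicate bootstrap coverage, 199–1000
  permutations, 1000-read profiler runs on 10–20 kb genomes. The
  chi-square/accuracy arithmetic uses the study's printed inputs directly
  (500/414 reviewed; 355,048 and 789,793 SNPs), as does the kbp/cM
  arithmetic (3.05 Mbp and 5.13 Mbp over 10 cM).

## Known limitations

- The hemi-SNP band is a heuristic; real hemi-SNP frequencies depend on
  homeolog copy number and coverage balance and can leak outside any fixed
  band.
- The counting dN/dS has no codon-frequency or ts/tv weighting (unweighted
  Nei–Gojobori); at higher divergences or biased mutation spectra a
  weighted or ML estimator would differ.
- The profiler's Hamming default ignores indels; the Levenshtein mode
  counts start positions reported by edlib's infix search, which can merge
  alignments sharing a start.
- Single-QTL scans only; closely linked QTL will produce one merged peak.
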