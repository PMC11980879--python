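# Methods

## Scope and data model

The package operates downstream of variant calling: its input is a
variants-only VCF of diploid genotypes, a sample→population map, and
optionally a GFF3 of gene models and a genome FASTA. Genotypes are held as
alt-allele dosages (0/1/2, missing = −1) in a samples × sites matrix;
phasing is ignored everywhere, and half-missing genotypes (`0/.`) are treated
as missing. Only single-base ref/alt records enter the matrix; indels are
dropped with a logged count. Coordinates are 1-based inclusive at every file
boundary (VCF/GFF3 convention) and converted to 0-based half-open only inside
interval arithmetic.

## Site filtering

Five steps in fixed order, each only removing sites, never altering calls:

1. **Biallelic** — at most one alt allele.
2. **Mean depth** — mean per-sample depth over *all* samples ≥ 4; missing
   genotypes contribute their recorded depth (0 when absent). The boundary is
   kept ("less than 4" removed).
3. **MAF** — minor allele frequency on non-missing alleles ≥ 0.05; exactly
   0.05 is kept. Sites with every call missing are removed and counted
   separately.
4. **Call rate** — genotyped fraction ≥ 0.70; exactly 0.70 is kept.
5. **LD pruning** — sliding windows of 50 SNPs advanced by 5; within a
   window, for any pair with dosage r² > 0.2 (squared Pearson correlation on
   pairwise-complete observations) the later SNP in position order is
   removed greedily. Zero-variance vectors make r² undefined; such pairs are
   skipped and both SNPs kept, avoiding spurious removals. The window/step/r²
   defaults are common pruning practice and fully configurable — results
   should always be read as conditional on these thresholds.

The filter report telescopes (output of step k = input of step k+1) and the
whole chain is idempotent.

## Diversity statistics

All per-site statistics use non-missing alleles only. Nucleotide diversity is
the missing-data-aware form: at a site with `a` alt and `r` ref allele copies
called, the pairwise-difference count is `a·r` and the comparison count is
`C(a+r, 2)`; site π is their ratio, and any multi-site (window) π is the
ratio of summed numerators to summed denominators, never a mean of ratios.
For complete data this per-site π coincides with the unbiased expected
heterozygosity uHe = 2n/(2n−1)·2pq. Reported π is averaged over *variant
sites only* — the input VCF carries no invariant sites — so it is a
per-variant-site quantity, not per-bp diversity; comparisons across datasets
with different site densities are not meaningful.

PIC uses Botstein's biallelic closed form 1 − (p²+q²) − 2p²q²; the Shannon
index is −Σ pᵢ ln pᵢ over the two allele frequencies. PIC ≤ He ≤ uHe holds
per site by construction. No ordering of Ho versus He is asserted anywhere:
founder-effect populations routinely show Ho > He.

## FST

Between-population differentiation is the Weir & Cockerham (1984)
variance-components estimator, computed per site from the per-population
sample sizes, allele frequencies and observed heterozygote frequencies, and
combined across sites as Σa / Σ(a+b+c) (ratio of sums). Sites where either
population has no called genotype, or the mean sample size is ≤ 1, carry
undefined components and are excluded from both observed and permuted sums
symmetrically. The raw multi-site value may be negative; reporting and the
qualitative bins clamp it at 0 while the raw value is preserved in output
tables. The bin boundary at 0.25 is resolved deterministically to "high".
The estimator choice matters: alternatives (Hudson, Nei) differ at small
sample sizes, and the test suite pins this implementation to an independent
scalar transcription of the published component formulas at 10⁻¹⁰.

PCA mean-imputes missing dosages per site, centres (optionally scales) and
takes the leading components of the sample covariance.

## The genome scan and sweep screen

Chromosomes are tiled into windows (default 10 kb window and step,
non-overlapping; any window ≤ step ≤ window geometry is accepted and the
last partial window is kept and flagged). Per window the scan reports the
ratio-of-sums F<sub>ST</sub>, pooled π for each population, and
log₂(π_ref/π_focal); windows without usable sites are undefined and excluded
from every quantile.

The significance baseline is a permutation null: sample labels of the two
populations are reshuffled (group sizes preserved), the windowed
F<sub>ST</sub> recomputed identically, and all permuted window values pooled
into a single genome-wide distribution (1,000 permutations by default) whose
95th percentile is the no-differentiation baseline. Pooling across windows
mixes windows of different site counts, so low-count windows are slightly
over-represented above the pooled percentile; the calibration test bounds
the resulting exceedance of observed windows in (0.02, 0.09) around the
nominal 5%.

A window is a sweep candidate iff its F<sub>ST</sub> is at/above the
top-5% threshold of defined window F<sub>ST</sub>s *and* its log₂ ratio is
at/above the top-5% threshold of finite ratios; windows where the focal π is
0 and the reference π positive count as above the ratio threshold, and
windows with both π zero are excluded. Quantiles use linear interpolation
between order statistics throughout. Candidates that touch or overlap merge
into regions; genes overlap-associate by ≥ 1 bp. Detection is invariant to
window order and to sample order.

## Annotation

Within a gene, category precedence is CDS > intron > upstream_1kb >
downstream_1kb; upstream/downstream are measured strand-aware from the
TSS/TES (positions −1…−1000 and +1…+1000, exclusive of the gene body); a
variant overlapping several genes yields one record per gene, and effect
summaries report both per-context counts and a deduplicated variant total.
Coding effects splice the CDS in transcription order, substitute the alt
base (complemented on minus-strand genes) and translate with the standard
code; stop gain/loss and start loss fall into `exon_other`. Gene-body
positions outside annotated CDS are reported as `intron` (UTRs are not
distinguished).

Promoters are the 2,000 bp immediately 5′ of the strand-aware TSS, returned
in transcription orientation and clipped at chromosome edges (zero-length
promoters warn rather than fail). Motif matching is exact IUPAC consensus
matching on both strands, all overlapping occurrences reported; an N in the
scanned sequence never matches. The bundled motif table carries the
cis-elements named in the plant stress-response literature; entries whose
consensus was curated rather than taken from a primary source are marked in
the table's `source` column and the file is user-replaceable. Motif
gain/loss under a promoter variant is the set difference of hits keyed by
(motif, start, strand), with mutated-sequence positions shifted back to the
reference frame past insertion points; the diff is antisymmetric under
swapping ref and alt.

## Phenotype statistics

The 2×2 survival test is the Yates-corrected χ², in the clamped form
Σ max(|O−E|−0.5, 0)²/E with one degree of freedom — the clamp makes equal
proportions give exactly χ² = 0, where unclamped implementations report a
small positive value. Survivor counts for rate-only tables are reconstructed
as round(rate × n). The t-test is the classic pooled-variance two-sample
test (df = nₐ+n_b−2) because that is what "Student's t-test" denotes; Welch
is available behind `equal_var=False`. Degenerate zero-variance inputs
return p = 1 for equal means and a flagged sub-denormal p for different
means.

## Synthetic data

The generator is a Balding–Nichols model: ancestral frequencies p₀ ~
Uniform(0.05, 0.95) by default (a Beta option exists), per-population
frequencies Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) with drift parameter F, and
genotypes Binomial(2, p_pop). This gives direct, closed-form control of the
expected F<sub>ST</sub> — the large-sample limit of the Weir–Cockerham
estimand is Σs²/Σ(p̄(1−p̄)+s²/2) over the true frequencies, which the test
suite uses as the simulation truth — at the cost of realism: sites are
unlinked (an optional block-copy mode creates LD for exercising the pruner),
there is no mutation model, no recombination map and no genealogy.
Consequently, passing tests demonstrate the statistics and the screen's
operating characteristics under drift-plus-selection allele-frequency
structure, not robustness to LD, mapping artefacts or complex demography in
real resequencing data.

A planted sweep multiplies the focal population's frequency toward the
nearer boundary of {0,1} by strength s (ties at 0.5 pulled toward 0),
reducing heterozygosity in the interval; s = 1 fixes the site. Missingness
is independent per call; depth is Poisson (mean 12 by default, matching a
low-coverage resequencing design of 10 diploids per population), with
missing calls at depth 0. All randomness flows from one seed through
`numpy.random.SeedSequence.spawn` with a fixed stream order, so equal
configs produce byte-identical fixture bundles. Bundle genomes are patched
so every SNP's REF matches the FASTA base; gene fixtures guarantee
ATG-initiated, internally stop-free CDS on both strands, with one gene
deliberately placed within 2 kb of a chromosome edge to exercise promoter
clipping.

## Problem sizes and numerical conventions

The calibration and power suites run at deliberately desk-scale sizes chosen
to keep Monte-Carlo error small relative to the asserted bands: 20
replicates of 5,000 SNPs with 200 permutations for null calibration, and 20
replicates of 20,000 SNPs for sweep recovery (s = 0.9, F = 0.05, 50 kb sweep,
10 kb windows). Quantiles are linear-interpolated everywhere; undefined
values are excluded before any quantile; FST clamping happens only at the
reporting/classification layer. Oracle comparisons use exact rational
arithmetic where feasible (small-sample π) and 10⁻¹⁰–10⁻¹² absolute
tolerance otherwise.

## Known limitations

* π over variant sites only — not comparable to per-bp π from all-sites
  VCFs.
* The permutation null pools across windows; per-window nulls are not
  implemented.
* LD pruning is greedy and threshold-dependent; with few samples, chance
  correlations prune aggressively at r² > 0.2.
* Haplotype statistics (iHS, XP-EHH), admixture inference, enrichment
  analysis and genotype-likelihood handling are out of scope.
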