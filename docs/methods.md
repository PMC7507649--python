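# Methods

This note documents the models, conventions and numerical choices behind
`popnovel`, and what the synthetic-data generator does and does not
emulate.

## Data model and normalization

Sites are held as `SiteRecord`s: chromosome, 1-based position, REF, a
list of ALT alleles, the seven site metrics used for quality control
(QD, MQ, MQRankSum, ReadPosRankSum, FS, SOR, DP) and per-sample GT, AD,
DP, GQ, RGQ.  VCF I/O goes through pysam; QUAL and Float INFO values are
normalized to the shortest decimal representation of their 32-bit float
storage so that parse → write → parse is a fixed point.

Allele comparison across call sets uses the atomic `NormalizedAllele`
`(chrom, pos, ref, alt)` obtained by multiallelic splitting followed by
left alignment.  Splitting recodes genotypes relative to the kept
allele; a genotype carrying a *different* alternative allele is marked
as "other non-reference" and contributes zero copies to the focal
allele's count — the only reading consistent with per-allele copy
counting.  Left alignment implements full minimal representation: shared
trailing bases are trimmed (extending left with reference bases when one
allele would become empty), then shared leading bases, keeping at least
one base per side.  The operation is idempotent and position-minimal,
which the tests verify against an oracle that enumerates every
equivalent spelling by exhaustive shifting.  Coordinates are 1-based
inclusive in VCF-facing code and 0-based half-open for BED/mask
interval arithmetic.

## Quality control

Pre-exclusion drops sites with no QD, zero DP in every sample, zero
alternative AD everywhere, or a non-autosomal chromosome; quality
control and all downstream analysis use SNVs only.

Truth labelling: a site is *true* iff any of its normalized alleles is
present in any truth panel (union semantics).  Filters are evaluated by
true-site retention and the discrimination factor DF = true retention /
other retention.  The packaged default cascade is

1. `-2.5 < MQRankSum < 1 and QD > 7 or QD > 0.5 and -0.01 < MQRankSum < 0.01`
2. `MQ > 50 or FS = 0 and MQ > 40`
3. mixture score > −0.5

The compound rules are parsed with `and` binding tighter than `or`, i.e.
as two alternative clauses `(A and B) or (C and D)`; chained comparisons
expand to conjunctions.  Records missing a referenced metric fail the
rule (conservative), except that an absent FS compared for equality with
zero is treated as zero, since callers omit FS at some sites where the
statistic is degenerate; both behaviours are switches.  Equality on FS
uses exact comparison of the parsed decimal value: a printed 0 means the
annotation was exactly zero.

The score model fits a full-covariance Gaussian mixture by EM (k = 2,
tolerance 1e−6 on mean log-likelihood, at most 500 iterations, diagonal
covariance regularization 1e−6, seeded initialisation from k random
training rows) to the standardized metrics DP, SOR, ReadPosRankSum and
FS of truth-matching sites.  The negative model is fitted to the lowest
5 % of training sites by positive-model density (the fraction is
configurable; the reference implementation's exact negative-set
construction is deliberately out of scope).  The score is the log-density
difference, and sites without all model metrics score −∞ by default.
EM enforces a non-decreasing mean log-likelihood; a singular covariance
aborts with advice to raise the regularization.  An independent
cross-check against scikit-learn's GaussianMixture on a shared fixture
guards the EM implementation.

Stage retentions are measured on each stage's input, so the overall
ratio increase telescopes into the product of stage discrimination
factors — an exact identity used as a test invariant.  Two helpers
(`compose_stage_factors`, `implied_removed_fraction`) perform the
arithmetic that connects per-stage summaries (stage DFs, starting
true:other ratio, overall retention) to the overall ratio increase and
the fraction of sites removed: with ratio r, true retention t and ratio
increase g, other-site retention is t/(1+g) and the removed fraction is
1 − (t·r + t/(1+g))/(r+1).

## Novelty

Reference panels store normalized alleles with a pass/fail flag
(populated from the FILTER column when requested) and a set of excluded
chromosomes; query alleles on an excluded chromosome are *not assessed*
rather than novel, because the panel simply carries no calls there.
Matching is exact on `(chrom, pos, ref, alt)` — no position-only
matching; "known position, different allele" is derived as a site-level
statistic afterwards.  Failed panel entries are excluded from the
comparison by default (`treat_fail_as="novel"`), which reduces the
chance that a reported novel allele is a false positive shared with the
panel.  Panels are stored as hash maps; exact membership at the
10^8-allele conceptual scale is a memory, not correctness, concern and
tests run at ≤10^5.

## Annotation

Transcript models are ingested from a 12-column refFlat-like TSV
(0-based starts, half-open ends, comma-joined exon lists, biotype
column).  Each SNV allele is annotated against every transcript whose
span ± flank (default 1000 bp, configurable) contains it: exon positions
resolve to exonic/UTR5/UTR3 (strand-aware) for coding transcripts or
ncRNA_exonic otherwise; intron positions within the first or last two
bases of the intron are splicing (ncRNA_splicing for non-coding), else
intronic; flank positions are upstream/downstream by strand; intergenic
when no transcript qualifies.

Multiple annotations collapse by fixed precedence: exonic, splicing,
ncRNA_exonic, ncRNA_splicing, UTR5, UTR3, intronic, ncRNA_intronic,
upstream, downstream, intergenic.  Exonic and splicing conceptually
share the top tier; exonic ranks above splicing so every allele receives
exactly one class.  Coding effects use the standard genetic code with
strand-aware complementing on the codon containing the allele:
stop_gain, stop_loss, nonsynonymous, synonymous, unknown (codon
truncated at a CDS edge), with the same high-to-low precedence across
transcripts.  Effects are verified against a full-CDS retranslation
oracle.  Selenocysteine and non-nuclear codes are not supported.

## Spectra and densities

The allele-count spectrum counts, per normalized allele, the copies
carried across all N samples (1..2N); any site with a missing genotype
in any sample is excluded and tallied separately.  Multiallelic sites
contribute each allele separately to spectra but one site to densities.
Density binning uses half-closed blocks so that 1-based position
`i·B` falls in block `i−1` (position 10,000,000 is in block 0 for 10 Mb
blocks); the final partial block is kept.

## Ancestry

Reference-side site selection applies, in order: MAF > 0.05 (strict;
sites at exactly 5 % are excluded), proximity (≤ 5 bp, inclusive, to any
other variant in the catalogue, indels included), accessibility mask,
and the Hardy–Weinberg exact test at P ≥ 1e−6.  The HWE test is the
standard conditional enumeration of heterozygote counts given allele
counts, two-sided by summing configurations no more probable than the
observed one (no mid-p); computed with log-gamma arithmetic and verified
against an exact-fraction enumeration oracle for all tables with ≤ 30
individuals.

Query-side rules: sites uncalled in the query are dropped; sites whose
alternative allele differs from the panel's are dropped; sites within
5 bp of another query variant are dropped; all-homozygous-reference
sites require QUAL ≥ 30 and DP ≥ 10, RGQ ≥ 20 in every sample; variant
sites require DP ≥ 10 and GQ ≥ 20 in every sample.  Query-side
exclusions shrink the site list *before* the PCA fit, so model and
query always share one site list.

LD pruning follows PLINK `--indep 50 5 2` semantics: windows of 50
retained sites advancing by 5; within a window the site with the highest
VIF (1/(1−R²) from regressing its genotypes on the other retained sites
in the window, equal to the diagonal of the inverse correlation matrix)
is removed, ties broken towards the lower genomic position, until all
VIFs are ≤ 2.  Passes repeat until a full pass removes nothing, which
makes pruning idempotent and guarantees the VIF bound in every final
window; the exact retained set of the original implementation is not
reproduced, only the bound (verified by direct per-site regression
audits).  Missing reference genotypes (synthetic data only) are
mean-imputed before pruning and PCA.

PCA centres each 0/1/2 column by its mean and scales by its sample
standard deviation (n−1 denominator); loadings are the top-k right
singular vectors, with a deterministic sign convention (largest-magnitude
loading entry positive) for reproducible outputs.  k defaults to 2.
Projection applies the stored means, scales and loadings to the query
rows; projecting the training matrix reproduces the stored scores to
1e−8.

## Synthetic data

The generator emulates the *shape* of a small WGS study: a three-sample
cohort of 10,000 sites (default) whose metrics are drawn from
class-conditional distributions — Gaussians for the rank-sum statistics,
zero-truncated Gaussians for QD, MQ, FS, SOR and DP, which also gives FS
the exact point mass at 0 that real caller output has.  The default
separations (e.g. true MQ ~ N(60, 3) vs other MQ ~ N(48, 8)) are chosen
so the packaged rules retain nearly all true sites with DF > 1, mirroring
the design point of threshold filtering.  60 % of sites are true-labelled
by default; a configurable minority are indels (3 %) and multiallelic
(5 %).  Optional deficiency knobs (missing QD, zero DP, zero AD,
non-autosomal placement, missing genotypes) default to zero and exist to
exercise the pre-exclusion rules.

Panels: the truth panel contains exactly the alleles of true-labelled
sites; each reference panel contains 93 % of the assessable cohort SNV
alleles (so the planted novel fraction is 7 %) plus 20 % extra
panel-only alleles; fail flags are planted at a configurable fraction;
the gnomAD-like panel omits chrY and writes one line per allele with a
FILTER column, while the 1000G-like panel merges shared positions into
multiallelic lines — exercising both panel-parsing paths.

Populations follow the Balding–Nichols model: ancestral frequencies
uniform on [0.05, 0.95], population frequencies Beta(p(1−F)/F,
(1−p)(1−F)/F) with F = 0.1, genotypes Binomial(2, freq) for two
populations of 100 samples at 5,000 sites spaced 1 kb apart; admixed
queries draw from α·p₁ + (1−α)·p₂ for α ∈ {0, 0.25, 0.5, 0.75, 1}.

The toy genome (300 kb) carries non-overlapping three-exon transcripts,
alternating coding/non-coding and strand; planted alleles cover every
annotation class, and two strata of exonic SNVs carry nonsense changes
at 1 % and 4 × 1 % to emulate nonsense enrichment in a novel stratum.

All generators are deterministic under the seed (independent named
streams per generator).  What the generator does **not** emulate:
read-level error processes, realistic genome-wide LD (only window-local
correlation planted for pruning tests), realistic allele-frequency
spectra, and overlap structure between QC class and panel membership
(membership is drawn uniformly).  Passing tests therefore demonstrate
correctness of the computations and exact recovery of planted structure,
not calibration against real sequencing error.

## Problem sizes and runtime

The packaged study scale — 10,000 cohort sites, 5,000 PCA sites,
100 + 100 reference samples — keeps a full pipeline run under ten
seconds and the whole test suite under a minute on one CPU, while being
large enough for the binomial recovery checks to be sharp.  Oracle
comparisons run at 500 alignments, 200 HWE tables, 1,000 precedence
multisets and 500 codon effects.

## Known limitations

- The mixture score is an analogue, not a reimplementation, of the
  reference recalibration tool; scores are comparable in construction
  (log-odds of positive vs negative model) but not numerically.
- Per-site (not per-allele) filtering in the QC cascade.
- Annotation handles SNVs only; indel and frameshift effects are out of
  scope, as are GFF3 gene models.
- The pipeline's end-to-end ancestry stage consumes simulated genotype
  matrices; the query-record filter path is exercised with synthetic
  records carrying passing metrics.
- No BCF, structural variants, or phased-genotype semantics beyond
  allele counting.
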