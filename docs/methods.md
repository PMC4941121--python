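# Methods

This note documents the statistical models, parameter choices, numerical
decisions and simulation designs behind `regprior`.  It states nothing the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

All genomic coordinates are 0-based half-open (BED convention), including
SNP positions, which are treated as width-1 intervals.  Intervals sharing
only a boundary never overlap; a SNP at position `end` is outside the
peak.  Even-length intervals take the lower-middle base as their center,
`floor((start + end) / 2)`, matching common peak-summit tooling.
Chromosome dialects (`1` vs `chr1`) are normalized to the `chr`-prefixed
form on load.  Peaks are unstranded; strand enters only in motif
scanning.  Interval intersection reports each query interval at most once
regardless of how many subject intervals it touches, and merging fuses
bookended intervals at `gap_bp = 0` with the merged score equal to the
mean of the member scores.

## LD expansion and marker selection

Linkage disequilibrium is consumed as an input table of pairwise (r², |D′|)
values — as exported by 1000 Genomes browsers — never computed from
genotypes.  The candidate set is leads ∪ {proxies with r² ≥ 0.8}, with an
inclusive threshold.  Records violating r² ≤ D′² are tolerated and logged,
since published tables are not always internally consistent.  Transcribed
marker SNPs for allelic assays require D′ > 0.90 (MAF > 0.15), falling
back to D′ > 0.75 when no strict-cutoff marker exists; if neither tier
yields a marker, the regulatory SNP itself can be measured in intronic
pre-mRNA as a transcription surrogate — a data-preparation convention, not
an algorithmic branch.  Ties break by higher MAF, then lexicographic rsid.

## Enrichment statistics

**DHS-background contingency.** Each interval of the DHS background
universe is classified by (overlaps the feature set by ≥ 1 bp) × (contains
≥ 1 panel SNP); the 2×2 counts always total the universe size.  A feature
interval overlapping several background intervals marks each of them; a
background interval that both overlaps the feature and contains a SNP is
counted once in the joint cell.  The test is one-sided (greater) Fisher's
exact.

**Fisher's exact test.** The one-sided p-value is the hypergeometric upper
tail at fixed margins; the two-sided p-value sums all outcome
probabilities not exceeding the observed one (standard software
convention), with a 1e-7 relative guard against log-space rounding of
equal-probability outcomes.  Tails are computed through log-gamma
(`scipy.stats.hypergeom`), so tables with 10⁵-scale cells neither overflow
nor lose extreme p-values.  The reported odds ratio is the sample
(a·d)/(b·c), with a 0.5 continuity correction applied to every cell when
any cell is zero; its 95% CI is the Woolf log-normal interval.  Tables
with an empty margin return p = 1 with the odds ratio flagged undefined.

**Cumulative binomial enrichment.** P(X ≥ x) for X ~ Binomial(n, p) with
n the panel size, x the open-chromatin overlap count, and p the fraction
of the uniquely mappable genome (2,630,301,437 bp for hg19) covered by the
assessed open-chromatin regions.  Fold enrichment is reported as
x / (n·p); this is a declared definition for the significance-vs-fold
scatter, since no formula is attached to that axis upstream.

**Density profiles.** Point features (SNPs, motif-hit centers) are counted
in 100-bp bins over ±1 kb around peak midpoints.  Each feature is assigned
to its nearest center (ties to the leftmost) so that overlapping windows
do not double-count.  "Global" normalization divides by the total number
of reference centers; a per-bp density variant is available behind a flag
but off by default.

## Motif scanning

Scores are log2 odds against the background base composition with a
pseudocount folded in as (p + c)/(1 + 4c), c = 0.01 by default, which
keeps each position summing to one; JASPAR count matrices are normalized
per column first.  Ambiguous bases score −∞ and can never seed a hit.

The hit threshold for a target p-value (0.001 in the pipeline) is derived
by exact dynamic programming over the per-position score distributions,
discretized at 10⁻³ bits.  The DP is exact up to that granularity;
equivalence with exhaustive W-mer enumeration is asserted in tests for
W ≤ 6 at tolerance W·10⁻³ bits.  When the requested tail is unreachable
(fewer than 1/p distinct outcomes), the maximal score is returned with a
warning.  Both strands are scanned — the reverse strand by scoring the
reverse-complement matrix on the forward sequence — and reverse-strand
hits carry forward coordinates.  Opposite-strand hits at one locus count
separately.

The proximity null is the column-permuted matrix: permuting motif
positions preserves the matrix's base composition exactly, so
compositional bias cannot produce spurious proximity enrichment.  The
permutation is drawn uniformly from non-identity permutations (rejection
sampling, seeded); a matrix whose positions are all identical is its own
permutation.  SNP-to-hit distance is measured from the SNP position to
the hit center (the anchor is otherwise unspecified upstream).  The near
band is ±100 bp; the far band is 900–1,000 bp on *both* flanks, noted as
a sensitivity choice.  A hit is counted once per band membership even
when the windows of nearby SNPs overlap.  The proximity table's Fisher
test defaults to two-sided (the R `fisher.test` default used for this
table upstream); the DHS peak-overlap test is the one explicitly one-sided
upstream.

## Super-enhancers

Signal-bearing peaks are stitched when gaps are ≤ 12,500 bp (inclusive —
the boundary is undocumented in the original tooling, so the inclusive
reading is declared).  Regions are ranked by summed member signal; rank
fraction and signal are min-max scaled to [0, 1], and the tangent point
where the curve's slope passes 1 is located as the *last* rank minimizing
(signal fraction − rank fraction).  Everything strictly beyond it is
called.  Taking the last minimizer makes the degenerate linear ramp
(slope ≡ 1) call nothing, and calls are always a suffix of the
signal-sorted list; adding a constant to all signals changes nothing.
All-equal signals call nothing by contract.  Background-signal
subtraction belongs to upstream peak processing; peaks simply carry their
(already subtracted, if desired) score.

## Allelic quantification

The standard curve is ordinary least squares of the measured log2
intensity ratio on log2 of the known mixing ratio over the 8:1 … 1:8
series (log2 design points −3 … +3).  All logs are base 2 — the upstream
description mixes "Log" and "Log2", and base 2 is the consistent reading.
Sample measurements are inverted through the curve; gDNA normalization is
a subtraction on the log2 scale (equivalent to dividing linear ratios),
so a value of 1.0 means balanced output.  Replicates are averaged on the
log2 scale per sample before inversion.  A near-zero slope makes the
curve non-invertible and is an error.

Imbalance across heterozygotes is a two-tailed one-sample t-test against
1.0.  Constant input exactly at 1.0 returns (t = 0, p = 1) by contract;
constant input elsewhere has no defined statistic and is an error.
haploChIP antibody groups are compared against the control
(input/IgG) group with Welch's unequal-variance t-test on log2 ratios;
groups whose mean assay signal is at or below a floor (a blank IgG
pulldown) are flagged and excluded from ratio estimation.

Note one deliberate property of testing *ratios* against 1.0: the
inverted ratio is lognormal under Gaussian measurement noise, so its mean
slightly exceeds 1 under a balanced truth.  At the design noise level
(0.1 log2 units per channel) this inflates the nominal 5% type-I rate by
well under two percentage points at n = 23, which the null-calibration
band in the acceptance checks accommodates; at materially larger noise a
log-scale test would be preferable.

## cis-eQTL analysis

The marginal association is OLS of log2-scale expression on allele dosage
{0, 1, 2} with a t-test on the slope (closed form; cross-checked against
statsmodels in tests).  The conditional association P(SNP₁ | SNP₂)
residualizes expression on SNP₂ and tests SNP₁ against the residuals.
The upstream description of the conditioning direction is ambiguous, but
with a single conditioning predictor the slope t-statistic is symmetric
in the two variables, so both readings give the same p-value — asserted
in tests.  Perfect collinearity (r² = 1, e.g. self-conditioning) returns
a flagged null result.  The cis window is a query-time filter defaulting
to 2 Mb centered on the SNP, and reported associations are capped at
p ≤ 0.05 by default.  Covariate columns are accepted by the cohort
container but default to none.

## Synthetic data design

The generators are pure functions of (config, seed); per-generator
substreams are derived with `default_rng([seed, stream])` so pieces can be
regenerated independently.  Defaults describe the desk-scale study
conditions: 1-Mb single-chromosome genome at GC 0.41, 200 planted motif
instances, 100 case + 100 control SNPs with half the case SNPs within
100 bp of a motif, a 23-heterozygote allelic cohort with true ratio 1.3
and 0.1 log2-unit channel noise, and an n = 500 eQTL cohort with effect
size 0.4 per allele on a unit-variance expression scale.

**Genome and motifs.** Bases are i.i.d. at the requested GC; motif
instances are sampled from the matrix (consensus planting available for
sharper recovery tests) at non-overlapping positions kept clear of the
chromosome ends.  The bundled AP-1-like matrix is synthetic: eleven
positions around the canonical TGA(C/G)TCA core with the degenerate
middle position carrying C/G equally (making the core self-reverse-
complementary, like the real element) and moderately informative flanks.
Its information content was chosen so that matrix-sampled instances
exceed the 0.001 background threshold with ~97% probability — a design
requirement for sharp planted-truth recovery, set from the score
distribution, not fitted to data.

**SNP panels and LD.** A configured fraction of case SNPs is placed
within the near distance of distinct planted motifs; the rest, and all
controls, are uniform.  Each case lead receives an LD block whose first
proxy sits at r² = D′ = 1 and whose remaining proxies draw r² at random
with D′ ≥ √r² enforced, so generated tables are internally consistent
even though the reader tolerates violations.

**Peaks and the DHS universe.** The background universe is laid out as
non-overlapping fixed-width slots (400 bp, 1,500 slots by default): every
slot containing a planted motif, topped up with random slots.  Each
feature set (ATAC, H3K27ac, TF) samples slots — a configurable share from
motif slots — and draws one jittered peak inside each chosen slot.  Two
consequences are deliberate: every feature set is a subset of the
universe (so pre-filtering feature peaks to DHS overlap is the identity,
as the contingency construction assumes), and under a zero motif share
the per-slot feature/SNP classification is exchangeable with essentially
constant interval widths, so the Fisher null calibration measured on this
design reflects the test, not hidden length confounding.  Real DHS
catalogs have variable-width, clustered intervals; length heterogeneity
correlated with SNP density would make the real-data test anti-
conservative, which is a caveat of the method itself, not of the
implementation.

**Allelic and eQTL cohorts.** The allelic forward model maps the true
log2 allele ratio through the assay line (slope 0.95, intercept 0.1 —
a realistic mildly compressive assay) plus Gaussian channel noise;
heterozygote gDNA is balanced by construction.  The eQTL cohort draws
Hardy-Weinberg genotypes at the configured MAF; a second SNP at target r²
is generated on phased haplotypes with D = r·p·q at equal allele
frequencies.

What the generators do *not* emulate: mappability and GC structure of
real genomes, clustered/variable-width DHS intervals, haplotype-block LD
beyond pairwise tables, read-level noise, covariate structure and
population stratification in expression cohorts.  Passing tests therefore
demonstrate correctness of the statistics under the stated generative
assumptions, not robustness to those real-data features.

## Problem sizes and seeds in the checks

The acceptance checks run: the motif-proximity experiment on 20 seeded
1-Mb genomes with 250 case + 250 control SNPs and 250 planted motifs —
the panel size was set by an a-priori power analysis (at the 100-SNP
desk-scale default the expected near/far Fisher p is only ~0.02–0.03;
250 SNPs put the expected p near 10⁻⁴ or below, while the original
analysis used a 5,240-SNP panel at genome scale); DHS-background null
calibration over 1,000 simulations with 1,000 uniform SNPs per simulation
(large enough cell counts that the discrete exact test's size sits near
the nominal 5%, and enough simulations that the Monte-Carlo error of the
rate estimate is small relative to the 3–7% acceptance band);
allelic-imbalance type-I error over 2,000 null cohorts of n = 23 and
power over 200 cohorts at ratio 1.3; eQTL null uniformity over 1,000
cohorts, CI coverage over 500, and LD-proxy conditional nullification
(r² = 0.5) over 20.  All per-simulation seeds are child seeds derived
from one base seed via `default_rng([base, salt])`.  Everything completes
in about two minutes on one CPU.

## Known limitations

* The DHS contingency treats background intervals as exchangeable units;
  per-SNP versus per-interval accounting of the published odds ratios is
  ambiguous upstream, and the per-interval reading is implemented.
* The far band of the proximity test is taken on both flanks; a one-flank
  reading would halve the far counts and slightly change odds ratios.
* The super-enhancer tangent rule is implemented on the 1-rank-step
  normalized curve; promoter-proximal exclusion before stitching is not
  performed.
* Real-data headline counts from the original study (5,240 candidate
  SNPs; 323/462/193 single-set overlaps; 87 combined; 64 filtered; 653
  super-enhancers; cohort eQTL p-values) require the external GEO / 1000
  Genomes / STARNET data and are treated as documented reference values,
  not reproduction targets.
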