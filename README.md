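# regprior

Prioritization of GWAS regulatory variants with cell-type epigenomic data,
built for the coronary-artery-disease / vascular smooth-muscle setting but
generic over any disease panel and peak collection.

Most trait-associated SNPs are non-coding, and the association signal at a
locus is shared by every variant in linkage disequilibrium with the lead
SNP.  `regprior` implements the analysis chain that narrows such a panel to
candidate *regulatory* variants and then tests their function:

1. **LD expansion** — leads plus all proxies with r² ≥ 0.8 form the
   candidate set; transcribed marker SNPs for allelic assays are chosen at
   D′ > 0.90 (fallback D′ > 0.75) with MAF > 0.15.
2. **Peak-overlap enrichment** — candidates are intersected with open
   chromatin (ATAC-seq), active enhancers (H3K27ac) and TF binding peaks.
   Enrichment over a DNaseI-hypersensitivity (DHS) background universe is
   tested per background interval with a one-sided Fisher's exact test,
   and open-chromatin enrichment per phenotype with the cumulative
   binomial b(x; n, p), where n is the panel size, x the overlap count and
   p the fraction of the uniquely mappable genome (2,630,301,437 bp for
   hg19) covered by the assessed open-chromatin regions.
3. **Motif proximity with a randomized-matrix null** — a position weight
   matrix (e.g. AP-1/JUN::FOS) is scanned genome-wide on both strands at a
   p-value threshold of 0.001 (score cutoff derived by exact dynamic
   programming over the background score distribution).  The null model is
   the same matrix with its columns permuted, which preserves base
   composition exactly.  Hits within ±100 bp of the SNPs versus hits
   900–1,000 bp away, for real versus permuted matrix, form a 2×2 table
   tested with Fisher's exact test.
4. **Super-enhancers** — signal-bearing enhancer peaks are stitched within
   12,500 bp and regions beyond the tangent point of the normalized
   rank/signal curve are called.
5. **Allele-specific quantification** — two-color allelic qPCR intensities
   are linearized through a standard curve fitted on a genomic-DNA mixing
   series (8:1 … 1:8); cDNA ratios are normalized by matched gDNA ratios,
   and imbalance across heterozygotes is tested against the expected ratio
   of 1.0 with a one-sample t-test (haploChIP groups use Welch's t-test
   against the control immunoprecipitation).
6. **cis-eQTL validation** — ordinary least squares of expression on
   allele dosage within a 2-Mb cis window, plus conditional analysis
   P(SNP₁ | SNP₂) by residualizing expression on the conditioning SNP.

Every stage can be driven end-to-end on synthetic data with planted ground
truth (`regprior.synthetic`), so the statistics are testable without any
external download.

## Worked example

```python
from regprior import ContingencyTable, fisher_exact

# near/far motif-proximity counts: (real near, permuted near,
#                                   real far,  permuted far)
table = ContingencyTable(173_761, 63_176, 165_206, 65_423)
res = fisher_exact(table, alternative="greater")
print(f"OR = {res.odds_ratio:.3f}  95% CI [{res.ci_low:.3f}, "
      f"{res.ci_high:.3f}]  p = {res.p_value:.3g}")
```

```
OR = 1.089  95% CI [1.075, 1.103]  p = 3.68e-39
```

Real-matrix hits are 1.09-fold enriched near the SNPs relative to the
permuted-matrix control, and the enrichment is decisive (p far below
2.2e-16) because the cell counts are in the 10⁵ range.

The same test on a fully synthetic experiment — a 1-Mb genome with AP-1-like
motifs planted within 100 bp of half of 250 "case" SNPs:

```python
from regprior.synthetic import (SimulationConfig, ap1_like_pwm,
                                generate_genome, generate_snp_panel)
from regprior.motif import (scan_sequences, randomize_pwm,
                            snp_motif_contingency)

cfg = SimulationConfig(seed=7, n_case_snps=250, n_control_snps=250,
                       n_planted_motifs=250)
pwm = ap1_like_pwm()
genome, planted = generate_genome(cfg, pwm)
panel = generate_snp_panel(cfg, planted)
hits_real = scan_sequences(genome, pwm, pvalue=0.001)
hits_null = scan_sequences(genome, randomize_pwm(pwm, seed=8), pvalue=0.001)

t, r = snp_motif_contingency(panel.case, hits_real, hits_null)
print(f"near/far table = ({t.a}, {t.b}, {t.c}, {t.d})  "
      f"OR = {r.odds_ratio:.2f}  p = {r.p_value:.2e}")
t2, r2 = snp_motif_contingency(panel.control, hits_real, hits_null)
print(f"control table  = ({t2.a}, {t2.b}, {t2.c}, {t2.d})  p = {r2.p_value:.3f}")
```

```
near/far table = (341, 98, 140, 98)  OR = 2.44  p = 3.72e-07
control table  = (128, 101, 131, 118)  p = 0.520
```

Real-matrix hits pile up near the case SNPs (341 near vs 140 far, against
a flat permuted-matrix baseline), while the uniformly placed control SNPs
show no enrichment — the qualitative signature the analysis is designed to
detect.

## Command line

A thin CLI mirrors the library:

```sh
regprior simulate --seed 3 -o sim/           # synthetic dataset + truth.json
regprior intervals merge sim/atac.bed --gap 0 -o merged.bed
regprior enrich fisher --cells 173761,63176,165206,65423
regprior motif scan --genome sim/genome.fa -o hits.bed
regprior superenhancer sim/h3k27ac.bed -o se.bed
regprior allelic calibrate sim/calibration.tsv
regprior eqtl scan --genotypes sim/genotypes.tsv \
    --expression sim/expression.tsv -o eqtl.tsv
```

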