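"""Enrichment statistics for GWAS variants in regulatory peak sets.

Three statistical devices:

* a 2x2 contingency table over a DNaseI-hypersensitivity (DHS) background
  universe, classifying each background interval by feature overlap and
  SNP content, tested with a one-sided Fisher's exact test;
* a cumulative-binomial open-chromatin enrichment, b(x; n, p), where n is
  the number of SNPs in a phenotype, x the number overlapping open
  chromatin, and p the fraction of the uniquely mappable genome covered by
  the assessed open-chromatin regions;
* binned density profiles of point features (SNPs, motif-hit centers)
  around centered reference peaks.

All hypergeometric/binomial tails are computed in log space (scipy), so
tables in the 1e5 range neither overflow nor lose the extreme p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .intervals import PeakSet, midpoints
from .ld import Variant

__all__ = [
    "MAPPABLE_HG19_BP",
    "ContingencyTable",
    "EnrichmentResult",
    "BinomialEnrichmentParams",
    "DensityProfile",
    "build_dhs_contingency",
    "fisher_exact",
    "binomial_enrichment",
    "density_profile",
]

#: uniquely mappable hg19 genome size in bp
MAPPABLE_HG19_BP = 2_630_301_437


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a=feat+/cond+, b=feat-/cond+, c=feat+/cond-, d=feat-/cond-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str  # "fisher" | "binomial"
    alternative: str  # "greater" | "two_sided"
    fold_enrichment: float = float("nan")
    degenerate: bool = False


@dataclass(frozen=True)
class BinomialEnrichmentParams:
    """Parameters of the cumulative-binomial open-chromatin enrichment.

    p may be given directly, or derived as open_chromatin_bp /
    mappable_genome_bp via :meth:`from_coverage`.
    """

    x: int
    n: int
    p: float
    mappable_genome_bp: int = MAPPABLE_HG19_BP

    def __post_init__(self):
        if self.x < 0 or self.n <= 0 or self.x > self.n:
            raise ValueError(f"require 0 <= x <= n, got x={self.x}, n={self.n}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must lie in (0, 1), got {self.p}")

    @classmethod
    def from_coverage(cls, x: int, n: int, open_chromatin_bp: int,
                      mappable_genome_bp: int = MAPPABLE_HG19_BP):
        return cls(x=x, n=n, p=open_chromatin_bp / mappable_genome_bp,
                   mappable_genome_bp=mappable_genome_bp)


@dataclass(frozen=True)
class DensityProfile:
    """Per-bin counts of point features by signed offset to peak centers."""

    bin_offsets: np.ndarray  # bin centers relative to feature center, bp
    counts: np.ndarray
    normalized: np.ndarray
    window_bp: int
    bin_bp: int

    @property
    def n_bins(self) -> int:
        return len(self.counts)


def fisher_exact(t: ContingencyTable,
                 alternative: str = "greater") -> EnrichmentResult:
    """Fisher's exact test on a 2x2 table.

    The odds ratio is the sample (a*d)/(b*c) with a 0.5 continuity
    correction applied to every cell when any cell is zero; its 95% CI is
    the Woolf log-normal interval.  The two-sided p-value sums all
    hypergeometric outcomes at the fixed margins whose probability does not
    exceed the observed one (standard software convention).
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a, b, c, d = t.a, t.b, t.c, t.d
    N = t.total
    K = a + c  # feature-positive margin
    n_draw = a + b  # condition-positive margin

    degenerate = (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0)
    if degenerate:
        return EnrichmentResult(
            odds_ratio=float("nan"), ci_low=float("nan"),
            ci_high=float("nan"), p_value=1.0, method="fisher",
            alternative=alternative, degenerate=True,
        )

    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    odds_ratio = (aa * dd) / (bb * cc)
    se_log = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = float(odds_ratio * np.exp(-1.959963984540054 * se_log))
    ci_high = float(odds_ratio * np.exp(1.959963984540054 * se_log))

    dist = stats.hypergeom(N, K, n_draw)
    if alternative == "greater":
        p = float(dist.sf(a - 1))
    else:
        support = np.arange(max(0, n_draw - (N - K)), min(n_draw, K) + 1)
        logpmf = dist.logpmf(support)
        obs = dist.logpmf(a)
        # relative tolerance guards against log-space rounding of equal-prob outcomes
        p = float(np.exp(logpmf[logpmf <= obs + 1e-7]).sum())
    p = min(1.0, p)
    return EnrichmentResult(
        odds_ratio=float(odds_ratio), ci_low=ci_low, ci_high=ci_high,
        p_value=p, method="fisher", alternative=alternative,
    )


def binomial_enrichment(params: BinomialEnrichmentParams) -> EnrichmentResult:
    """Cumulative binomial enrichment: P(X >= x), X ~ Binomial(n, p).

    Also reports the fold enrichment x / (n * p).
    """
    p_value = float(stats.binom.sf(params.x - 1, params.n, params.p))
    fold = params.x / (params.n * params.p)
    return EnrichmentResult(
        odds_ratio=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
        p_value=min(1.0, p_value), method="binomial", alternative="greater",
        fold_enrichment=float(fold),
    )


def build_dhs_contingency(feature: PeakSet, snp_set: list[Variant],
                          dhs_universe: PeakSet) -> ContingencyTable:
    """Classify each DHS background interval by feature overlap x SNP content.

    a = DHS intervals overlapping the feature (>=1 bp) and containing >= 1
    SNP; b = SNP-containing DHS devoid of the feature; c = feature-marked
    DHS without SNPs; d = DHS devoid of both.  Cell totals always sum to
    the size of the universe.  The feature is expected to be pre-filtered
    to DHS-overlapping intervals.
    """
    if len(dhs_universe) == 0:
        raise ValueError("DHS background universe is empty")
    trees = feature.trees()
    snp_pos: dict[str, np.ndarray] = {}
    for v in snp_set:
        snp_pos.setdefault(v.chrom, []).append(v.pos)  # type: ignore[arg-type]
    snp_pos = {ch: np.sort(np.asarray(ps)) for ch, ps in snp_pos.items()}

    a = b = c = d = 0
    for iv in dhs_universe:
        tree = trees.get(iv.chrom)
        overlaps = bool(tree is not None and tree.overlap(iv.start, iv.end))
        ps = snp_pos.get(iv.chrom)
        has_snp = False
        if ps is not None:
            lo = np.searchsorted(ps, iv.start, side="left")
            hi = np.searchsorted(ps, iv.end, side="left")
            has_snp = hi > lo
        if overlaps and has_snp:
            a += 1
        elif not overlaps and has_snp:
            b += 1
        elif overlaps:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def density_profile(features: PeakSet, centers: PeakSet,
                    window_bp: int = 1000, bin_bp: int = 100,
                    normalization: str = "global") -> DensityProfile:
    """Count point features in bins of signed offset around peak centers.

    Centers are reduced to midpoints; each feature point is assigned to its
    nearest center (ties to the leftmost center) and counted if the signed
    offset lies in [-window_bp, window_bp).  "global" normalization divides
    counts by the total number of reference centers; "per_bin" additionally
    divides by the bin width, giving a per-bp density.
    """
    if window_bp % bin_bp != 0:
        raise ValueError("window_bp must be divisible by bin_bp")
    if normalization not in ("global", "per_bin"):
        raise ValueError(f"unknown normalization {normalization!r}")
    centers = midpoints(centers)
    center_pos = {
        ch: np.array([iv.start for iv in ivs])
        for ch, ivs in centers.by_chrom().items()
    }
    n_bins = 2 * window_bp // bin_bp
    counts = np.zeros(n_bins, dtype=np.int64)
    for iv in features:
        pos = iv.midpoint
        cs = center_pos.get(iv.chrom)
        if cs is None or len(cs) == 0:
            continue
        i = np.searchsorted(cs, pos)
        # nearest center; tie -> leftmost (strict < when comparing right cand.)
        best = None
        if i > 0:
            best = cs[i - 1]
        if i < len(cs):
            cand = cs[i]
            if best is None or abs(cand - pos) < abs(pos - best):
                best = cand
        offset = pos - int(best)
        if -window_bp <= offset < window_bp:
            counts[(offset + window_bp) // bin_bp] += 1
    n_ref = max(1, len(centers))
    normalized = counts / n_ref
    if normalization == "per_bin":
        normalized = normalized / bin_bp
    bin_offsets = np.arange(n_bins) * bin_bp - window_bp + bin_bp / 2.0
    return DensityProfile(
        bin_offsets=bin_offsets, counts=counts, normalized=normalized,
        window_bp=window_bp, bin_bp=bin_bp,
    )
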