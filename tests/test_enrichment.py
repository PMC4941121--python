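"""Fisher/binomial enrichment statistics against independent oracles."""

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np
import pytest
import scipy.stats

from regprior.enrichment import (
    BinomialEnrichmentParams, ContingencyTable, build_dhs_contingency,
    binomial_enrichment, density_profile, fisher_exact,
)
from regprior.intervals import GenomicInterval, PeakSet
from regprior.ld import Variant

from conftest import random_peakset


# -------------------------------------------------------- enumeration oracle

@lru_cache(maxsize=None)
def _hypergeom_pmf_exact(N, K, n):
    """Exact rational hypergeometric pmf over the support at fixed margins."""
    lo, hi = max(0, n - (N - K)), min(n, K)
    denom = math.comb(N, n)
    return {
        k: Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom)
        for k in range(lo, hi + 1)
    }


def fisher_oracle(a, b, c, d, alternative):
    """Exhaustive-outcome Fisher p-value with exact rational arithmetic."""
    N, K, n = a + b + c + d, a + c, a + b
    pmf = _hypergeom_pmf_exact(N, K, n)
    if alternative == "greater":
        return float(sum(p for k, p in pmf.items() if k >= a))
    obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= obs))


def all_tables(max_total):
    for total in range(1, max_total + 1):
        for a in range(total + 1):
            for b in range(total - a + 1):
                for c in range(total - a - b + 1):
                    yield a, b, c, total - a - b - c


class TestFisherExact:
    def test_symmetric_table(self):
        res = fisher_exact(ContingencyTable(5, 5, 5, 5),
                           alternative="two_sided")
        assert res.odds_ratio == 1.0
        assert res.p_value == pytest.approx(1.0)

    def test_example_against_enumeration(self):
        t = ContingencyTable(8, 2, 1, 5)
        for alt in ("greater", "two_sided"):
            res = fisher_exact(t, alternative=alt)
            assert res.p_value == pytest.approx(
                fisher_oracle(8, 2, 1, 5, alt), rel=1e-9)

    def test_exhaustive_small_tables(self):
        """Exact agreement with outcome enumeration on every table, total<=16.

        (The acceptance suite pushes this to total 30; here a faster sweep
        guards the same property.)
        """
        for a, b, c, d in all_tables(16):
            t = ContingencyTable(a, b, c, d)
            res_g = fisher_exact(t, "greater")
            res_t = fisher_exact(t, "two_sided")
            if res_g.degenerate:
                assert res_g.p_value == 1.0
                continue
            assert res_g.p_value == pytest.approx(
                fisher_oracle(a, b, c, d, "greater"), rel=1e-9, abs=1e-12)
            assert res_t.p_value == pytest.approx(
                fisher_oracle(a, b, c, d, "two_sided"), rel=1e-7, abs=1e-12)

    def test_agrees_with_scipy(self, rng):
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0
                    or a + b + c + d == 0):
                continue
            t = ContingencyTable(a, b, c, d)
            sp_g = scipy.stats.fisher_exact([[a, b], [c, d]],
                                            alternative="greater")[1]
            sp_t = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert fisher_exact(t, "greater").p_value == pytest.approx(
                sp_g, rel=1e-7)
            assert fisher_exact(t, "two_sided").p_value == pytest.approx(
                sp_t, rel=1e-6)

    def test_greater_p_monotone_in_a_at_fixed_margins(self):
        ps = []
        for k in range(5):
            t = ContingencyTable(5 + k, 10 - k, 10 - k, 5 + k)
            ps.append(fisher_exact(t, "greater").p_value)
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_degenerate_margin(self):
        res = fisher_exact(ContingencyTable(0, 0, 3, 4))
        assert res.degenerate and res.p_value == 1.0
        assert math.isnan(res.odds_ratio)

    def test_zero_cell_continuity_correction(self):
        res = fisher_exact(ContingencyTable(5, 0, 2, 3))
        assert res.odds_ratio == pytest.approx((5.5 * 3.5) / (0.5 * 2.5))
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_large_table_no_overflow(self):
        res = fisher_exact(ContingencyTable(173_761, 63_176, 165_206, 65_423))
        assert res.p_value < 2.2e-16
        assert res.odds_ratio == pytest.approx(
            173_761 * 65_423 / (63_176 * 165_206))
        assert res.ci_low <= res.odds_ratio <= res.ci_high


class TestBinomialEnrichment:
    def test_x_zero_gives_one(self):
        res = binomial_enrichment(BinomialEnrichmentParams(x=0, n=10, p=0.1))
        assert res.p_value == 1.0

    def test_small_example_against_direct_summation(self):
        # sum of the Binomial(10, 0.1) mass over k = 3..10
        expected = sum(
            math.comb(10, k) * 0.1**k * 0.9 ** (10 - k) for k in range(3, 11))
        res = binomial_enrichment(BinomialEnrichmentParams(x=3, n=10, p=0.1))
        assert res.p_value == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0702, abs=5e-5)

    def test_lgamma_summation_oracle_large_n(self):
        def oracle(x, n, p):
            out = 0.0
            for k in range(x, n + 1):
                out += math.exp(
                    math.lgamma(n + 1) - math.lgamma(k + 1)
                    - math.lgamma(n - k + 1)
                    + k * math.log(p) + (n - k) * math.log1p(-p))
            return out

        for x, n, p in [(3, 10, 0.1), (30, 1000, 0.02), (120, 10_000, 0.01),
                        (5, 10_000, 0.0001)]:
            res = binomial_enrichment(BinomialEnrichmentParams(x=x, n=n, p=p))
            assert res.p_value == pytest.approx(oracle(x, n, p), rel=1e-10)

    def test_mappable_genome_coverage_fraction(self):
        params = BinomialEnrichmentParams.from_coverage(
            x=1, n=10, open_chromatin_bp=26_303_014)
        assert params.p == pytest.approx(0.01, rel=1e-6)
        assert params.mappable_genome_bp == 2_630_301_437

    def test_fold_enrichment(self):
        res = binomial_enrichment(BinomialEnrichmentParams(x=4, n=100, p=0.01))
        assert res.fold_enrichment == pytest.approx(4.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            BinomialEnrichmentParams(x=5, n=4, p=0.1)
        with pytest.raises(ValueError):
            BinomialEnrichmentParams(x=1, n=4, p=1.5)


class TestDhsContingency:
    def test_direct_classification(self):
        dhs = PeakSet("dhs", [GenomicInterval("chr1", s, s + 100)
                              for s in (0, 200, 400, 600)])
        feature = PeakSet("f", [GenomicInterval("chr1", 50, 60),
                                GenomicInterval("chr1", 250, 260)])
        snps = [Variant("s1", "chr1", 10), Variant("s2", "chr1", 450)]
        t = build_dhs_contingency(feature, snps, dhs)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_empty_snp_set(self):
        dhs = PeakSet("dhs", [GenomicInterval("chr1", 0, 100)])
        feature = PeakSet("f", [GenomicInterval("chr1", 10, 20)])
        t = build_dhs_contingency(feature, [], dhs)
        assert (t.a, t.b) == (0, 0) and t.c == 1

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            build_dhs_contingency(PeakSet("f"), [], PeakSet("dhs"))

    def test_matches_brute_force(self, rng):
        dhs = PeakSet("dhs", [GenomicInterval("chr1", i * 200, i * 200 + 150)
                              for i in range(50)])
        feature = random_peakset(rng, 30, "f", chroms=("chr1",))
        snps = [Variant(f"s{i}", "chr1", int(rng.integers(0, 10_000)))
                for i in range(40)]
        t = build_dhs_contingency(feature, snps, dhs)
        a = b = c = d = 0
        for iv in dhs:
            ov = any(iv.overlap_bp(f) >= 1 for f in feature)
            sn = any(iv.start <= s.pos < iv.end for s in snps)
            a += ov and sn
            b += (not ov) and sn
            c += ov and not sn
            d += (not ov) and not sn
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
        assert t.total == len(dhs)


class TestDensityProfile:
    def test_stated_binning_gives_20_bins(self):
        centers = PeakSet("c", [GenomicInterval("chr1", 5_000, 5_200)])
        prof = density_profile(PeakSet("f"), centers,
                               window_bp=1000, bin_bp=100)
        assert prof.n_bins == 20

    def test_features_at_centers_fill_central_bin(self):
        centers = PeakSet("c", [GenomicInterval("chr1", 1_000, 1_200),
                                GenomicInterval("chr1", 9_000, 9_100)])
        feats = PeakSet("f", [GenomicInterval("chr1", 1_100, 1_101),
                              GenomicInterval("chr1", 9_050, 9_051)])
        prof = density_profile(feats, centers)
        assert prof.counts.sum() == 2
        # offset 0 falls in the first bin right of the center
        assert prof.counts[10] == 2
        assert prof.normalized[10] == pytest.approx(1.0)

    def test_counts_conserved_for_in_window_features(self, rng):
        centers = PeakSet("c", [GenomicInterval("chr1", 50_000, 50_001)])
        pos = rng.integers(49_000, 51_000, size=200)
        feats = PeakSet("f", [GenomicInterval("chr1", int(p), int(p) + 1)
                              for p in pos])
        prof = density_profile(feats, centers)
        in_window = ((pos >= 49_000) & (pos < 51_000)).sum()
        assert prof.counts.sum() == in_window

    def test_uniform_features_give_flat_profile(self, rng):
        centers = PeakSet("c", [GenomicInterval("chr1", c, c + 1)
                                for c in range(10_000, 200_000, 10_000)])
        pos = rng.integers(0, 200_000, size=20_000)
        feats = PeakSet("f", [GenomicInterval("chr1", int(p), int(p) + 1)
                              for p in pos])
        prof = density_profile(feats, centers)
        expected = prof.counts.mean()
        assert prof.counts.std() < 0.15 * expected + 10

    def test_nearest_center_tie_goes_left(self):
        centers = PeakSet("c", [GenomicInterval("chr1", 1_000, 1_001),
                                GenomicInterval("chr1", 1_200, 1_201)])
        feats = PeakSet("f", [GenomicInterval("chr1", 1_100, 1_101)])
        prof = density_profile(feats, centers)
        # equidistant: assigned to the left center -> offset +100
        assert prof.counts[11] == 1

    def test_window_bin_divisibility(self):
        with pytest.raises(ValueError):
            density_profile(PeakSet("f"), PeakSet("c"),
                            window_bp=1000, bin_bp=300)
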