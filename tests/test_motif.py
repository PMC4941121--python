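"""PWM scoring, threshold DP, strand symmetry, and the permutation null."""

import itertools

import numpy as np
import pytest
import scipy.stats

from regprior.enrichment import ContingencyTable
from regprior.ld import Variant
from regprior.motif import (
    GRANULARITY, PWM, MotifHit, randomize_pwm, read_jaspar, scan_sequences,
    score_pwm, snp_motif_contingency, threshold_from_pvalue, write_hits_bed,
)
from regprior.synthetic import ap1_like_pwm


def random_pwm(rng, width, name="rand"):
    m = rng.dirichlet(np.ones(4), size=width)
    return PWM(name, m)


def enumeration_threshold(pwm, pvalue):
    """Oracle: exhaustive W-mer enumeration of the score distribution."""
    scores = []
    for word in itertools.product(range(4), repeat=pwm.width):
        s = sum(pwm.log_odds[j, b] for j, b in enumerate(word))
        p = np.prod([pwm.background[b] for b in word])
        scores.append((s, p))
    scores.sort(reverse=True)
    tail = 0.0
    threshold = scores[0][0]
    for s, p in scores:
        if tail + p > pvalue + 1e-12:
            break
        tail += p
        threshold = s
    return threshold


class TestScorePwm:
    def test_uniform_matrix_scores_zero(self):
        pwm = PWM("u", np.full((5, 4), 0.25))
        assert score_pwm("ACGTA", pwm) == pytest.approx(0.0)

    def test_single_column_one_bit(self):
        pwm = PWM("one", [[0.5, 0.5 / 3, 0.5 / 3, 0.5 / 3]], pseudocount=0.0)
        assert score_pwm("A", pwm) == pytest.approx(1.0)

    def test_consensus_maximal_over_all_words(self, rng):
        pwm = random_pwm(rng, 4)
        best = score_pwm(pwm.consensus, pwm)
        for word in itertools.product("ACGT", repeat=4):
            assert score_pwm("".join(word), pwm) <= best + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_pwm("ACG", PWM("u", np.full((5, 4), 0.25)))

    def test_ambiguous_base_scores_neg_inf(self):
        pwm = PWM("u", np.full((4, 4), 0.25))
        assert score_pwm("ACNT", pwm) == float("-inf")


class TestThresholdFromPvalue:
    def test_pvalue_one_gives_minimum(self, rng):
        pwm = random_pwm(rng, 4)
        scores, _ = pwm.score_distribution()
        assert threshold_from_pvalue(pwm, 1.0) == pytest.approx(
            scores[0], abs=GRANULARITY)

    @pytest.mark.parametrize("width", [2, 3, 4, 5, 6])
    def test_matches_exhaustive_enumeration(self, rng, width):
        for pvalue in (0.5, 0.1, 0.01, 0.001):
            pwm = random_pwm(rng, width)
            dp = threshold_from_pvalue(pwm, pvalue)
            enum = enumeration_threshold(pwm, pvalue)
            assert dp == pytest.approx(enum,
                                       abs=width * GRANULARITY + 1e-9)

    def test_unreachable_pvalue_warns_and_returns_max(self):
        pwm = PWM("flat", np.full((4, 4), 0.25))
        with pytest.warns(UserWarning, match="unreachable"):
            thr = threshold_from_pvalue(pwm, 1e-6)
        scores, _ = pwm.score_distribution()
        assert thr == pytest.approx(scores[-1])

    def test_hit_count_monotone_in_pvalue(self, rng):
        pwm = ap1_like_pwm()
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        counts = [len(scan_sequences({"chr1": seq}, pwm, pvalue=p))
                  for p in (0.05, 0.01, 0.001)]
        assert counts == sorted(counts, reverse=True)


class TestScanSequences:
    def test_planted_consensus_recovered(self, rng):
        pwm = ap1_like_pwm()
        seq = list(rng.choice(list("ACGT"), size=1_000))
        seq[500:500 + pwm.width] = list(pwm.consensus)
        hits = scan_sequences({"chr1": "".join(seq)}, pwm, pvalue=0.001)
        assert any(h.start == 500 and h.strand == "+" for h in hits)

    def test_palindromic_pwm_pairs_strands(self, rng):
        # fully reverse-complement-symmetric matrix: TGASTCA-like core only
        strong = {b: [0.97 if x == b else 0.01 for x in "ACGT"]
                  for b in "ACGT"}
        rows = [strong["T"], strong["G"], strong["A"],
                [0.01, 0.485, 0.485, 0.01],
                strong["T"], strong["C"], strong["A"]]
        pwm = PWM("pal", rows)
        assert np.allclose(pwm.matrix, pwm.reverse_complement().matrix)
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        hits = scan_sequences({"chr1": seq}, pwm, pvalue=0.001)
        fwd = {(h.chrom, h.start) for h in hits if h.strand == "+"}
        rev = {(h.chrom, h.start) for h in hits if h.strand == "-"}
        assert fwd == rev

    def test_reverse_complement_genome_mirrors_hits(self, rng):
        pwm = ap1_like_pwm()
        seq = "".join(rng.choice(list("ACGT"), size=30_000))
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        hits = scan_sequences({"chr1": seq}, pwm, pvalue=0.001)
        hits_rc = scan_sequences({"chr1": rc}, pwm, pvalue=0.001)
        L, W = len(seq), pwm.width
        mirrored = {(L - h.end, "+-"["+-".index(h.strand) ^ 1])
                    for h in hits_rc}
        assert {(h.start, h.strand) for h in hits} == mirrored

    def test_empty_genome(self):
        assert scan_sequences({}, ap1_like_pwm(), pvalue=0.01) == []

    def test_deterministic_ordering(self, rng):
        pwm = ap1_like_pwm()
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        hits = scan_sequences({"chr1": seq}, pwm, pvalue=0.01)
        assert hits == sorted(hits, key=lambda h: (h.chrom, h.start, h.strand))

    def test_hits_written_as_bed6(self, rng, tmp_path):
        hits = [MotifHit("chr1", 10, 21, "+", 8.5),
                MotifHit("chr1", 50, 61, "-", 7.25)]
        path = write_hits_bed(hits, tmp_path / "hits.bed")
        lines = path.read_text().strip().split("\n")
        assert lines[0].split("\t") == ["chr1", "10", "21", ".", "8.5000", "+"]


class TestRandomizePwm:
    def test_identical_columns_fixed_point(self):
        pwm = PWM("deg", np.tile([0.4, 0.3, 0.2, 0.1], (4, 1)))
        rand = randomize_pwm(pwm, seed=3)
        assert np.allclose(rand.matrix, pwm.matrix)

    def test_column_multiset_preserved(self, rng):
        pwm = random_pwm(rng, 6)
        rand = randomize_pwm(pwm, seed=11)
        got = sorted(map(tuple, np.round(rand.matrix, 12)))
        want = sorted(map(tuple, np.round(pwm.matrix, 12)))
        assert got == want
        # total base composition of the matrix is exactly preserved
        assert np.allclose(rand.matrix.sum(axis=0), pwm.matrix.sum(axis=0))

    def test_never_identity_for_distinct_columns(self, rng):
        pwm = random_pwm(rng, 5)
        for seed in range(30):
            rand = randomize_pwm(pwm, seed)
            assert not np.allclose(rand.matrix, pwm.matrix)

    def test_seeded_reproducibility(self, rng):
        pwm = random_pwm(rng, 8)
        a, b = randomize_pwm(pwm, 42), randomize_pwm(pwm, 42)
        assert np.array_equal(a.matrix, b.matrix)

    def test_uniform_over_non_identity_permutations(self, rng):
        """W=3: the 5 non-identity permutations appear uniformly."""
        pwm = random_pwm(rng, 3)
        perms = list(itertools.permutations(range(3)))
        counts = dict.fromkeys(perms, 0)
        for seed in range(10_000):
            rand = randomize_pwm(pwm, seed)
            for perm in perms:
                if np.allclose(rand.matrix, pwm.matrix[list(perm)]):
                    counts[perm] += 1
                    break
        assert counts[(0, 1, 2)] == 0
        observed = [c for p, c in counts.items() if p != (0, 1, 2)]
        assert sum(observed) == 10_000
        chi2 = scipy.stats.chisquare(observed)
        assert chi2.pvalue > 1e-3


class TestSnpMotifContingency:
    def test_distance_bookkeeping(self):
        snps = [Variant("s", "chr1", 500)]
        # hit centers at 550 (near band) and 1450 (950 bp away: far band)
        real = [MotifHit("chr1", 545, 556, "+", 9.0),
                MotifHit("chr1", 1445, 1456, "+", 9.0)]
        rand = [MotifHit("chr1", 560, 571, "+", 9.0),
                MotifHit("chr1", 1425, 1436, "+", 9.0)]
        table, _ = snp_motif_contingency(snps, real, rand)
        assert (table.a, table.c) == (1, 1)
        assert (table.b, table.d) == (1, 1)

    def test_band_boundaries_inclusive(self):
        snps = [Variant("s", "chr1", 5_000)]
        mk = lambda c: MotifHit("chr1", c - 5, c + 6, "+", 9.0)
        # centers exactly at 100, 900 and 1000 bp; 101 bp misses the near band
        real = [mk(5_100), mk(5_900), mk(6_000), mk(5_101), mk(6_001)]
        rand = [mk(4_000)]
        table, _ = snp_motif_contingency(snps, real, rand)
        assert table.a == 1
        assert table.c == 2

    def test_printed_matrix_significance(self):
        table = ContingencyTable(173_761, 63_176, 165_206, 65_423)
        from regprior.enrichment import fisher_exact
        assert fisher_exact(table, "two_sided").p_value < 2.2e-16

    def test_hit_counted_once_per_band(self):
        # two SNPs 50 bp apart: one hit inside both near windows counts once
        snps = [Variant("s1", "chr1", 500), Variant("s2", "chr1", 550)]
        real = [MotifHit("chr1", 520, 531, "+", 9.0)]
        rand = [MotifHit("chr1", 5_000, 5_011, "+", 9.0),
                MotifHit("chr1", 1_450, 1_461, "+", 9.0)]
        table, _ = snp_motif_contingency(snps, real, rand)
        assert table.a == 1


class TestJasparIO:
    def test_jaspar_bracket_dialect(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text(
            ">MA0000.1 TEST\n"
            "A  [ 10  0  5 ]\n"
            "C  [  0 20  5 ]\n"
            "G  [  5  0  5 ]\n"
            "T  [  5  0  5 ]\n"
        )
        pwm = read_jaspar(p)
        assert pwm.width == 3
        assert pwm.matrix[1] == pytest.approx([0, 1, 0, 0])
        assert pwm.matrix[0] == pytest.approx([0.5, 0, 0.25, 0.25])
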