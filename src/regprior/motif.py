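"""Position-weight-matrix scanning and the randomized-matrix proximity test.

The scanner scores log2 odds against a background base composition, derives
its hit threshold from a target p-value by exact dynamic programming over
the discretized column score distributions, and scans both strands of a
genome.  The null model for motif-proximity testing is a column-permuted
copy of the matrix: permuting motif positions preserves base composition
exactly, so compositional bias cannot masquerade as proximity enrichment.

SNP-to-hit distances are measured from the SNP position to the hit center.
Hits within +/- near_bp of any SNP versus hits 900-1,000 bp away (both
flanks) for the real and the permuted matrix form a 2x2 table tested with
Fisher's exact test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .enrichment import ContingencyTable, EnrichmentResult, fisher_exact
from .ld import Variant

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "MotifHit",
    "read_jaspar",
    "score_pwm",
    "threshold_from_pvalue",
    "scan_sequences",
    "randomize_pwm",
    "snp_motif_contingency",
    "write_hits_bed",
]

_BASES = "ACGT"
#: score discretization granularity for the threshold DP, in bits
GRANULARITY = 1e-3


class PWM:
    """A position weight matrix over A, C, G, T.

    ``matrix`` rows are motif positions; each row holds the four base
    probabilities (count rows are normalized per position).  A pseudocount
    is folded in at log-odds time as (p + c) / (1 + 4c), which keeps each
    position summing to one.
    """

    def __init__(self, name: str, matrix, background=None,
                 pseudocount: float = 0.01):
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("matrix must have shape (W, 4) over A,C,G,T")
        if m.shape[0] < 1:
            raise ValueError("matrix must have at least one position")
        if np.any(m < 0):
            raise ValueError("matrix entries must be non-negative")
        row_sums = m.sum(axis=1)
        if np.any(row_sums <= 0):
            raise ValueError("every matrix position needs positive total mass")
        self.matrix = m / row_sums[:, None]
        self.name = name
        bg = np.full(4, 0.25) if background is None else np.asarray(background,
                                                                    dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 frequencies summing to 1")
        self.background = bg
        if pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        self.pseudocount = pseudocount
        self._dist_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(W, 4) log2-odds scores with the pseudocount folded in."""
        c = self.pseudocount
        p = (self.matrix + c) / (1.0 + 4.0 * c)
        with np.errstate(divide="ignore"):
            return np.log2(p / self.background)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        # reversing the ACGT axis maps A<->T, C<->G
        return PWM(f"{self.name}_rc", self.matrix[::-1, ::-1],
                   self.background[::-1], self.pseudocount)

    def score_distribution(self, granularity: float = GRANULARITY):
        """Exact distribution of the score of a random background W-mer.

        Returns (scores, survival): ascending achievable scores on the
        granularity grid and P(score >= s) for each.  Computed by dynamic
        programming over discretized per-position score distributions.
        """
        if granularity in self._dist_cache:
            return self._dist_cache[granularity]
        lom = self.log_odds
        if not np.all(np.isfinite(lom)):
            raise ValueError(
                "score distribution undefined with -inf log-odds entries; "
                "use a positive pseudocount"
            )
        bins = np.round(lom / granularity).astype(np.int64)  # (W, 4)
        lo = hi = 0
        probs = np.array([1.0])
        for j in range(self.width):
            row = bins[j]
            jlo, jhi = int(row.min()), int(row.max())
            new = np.zeros(hi - lo + jhi - jlo + 1)
            for b in range(4):
                off = int(row[b]) - jlo
                new[off:off + len(probs)] += probs * self.background[b]
            probs, lo, hi = new, lo + jlo, hi + jhi
        scores = np.arange(lo, hi + 1) * granularity
        survival = np.cumsum(probs[::-1])[::-1]
        mask = probs > 0
        result = (scores[mask], survival[mask])
        self._dist_cache[granularity] = result
        return result


@dataclass(frozen=True)
class MotifHit:
    """One scored match; reverse-strand hits carry forward coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float | None = None

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def read_jaspar(path: str | Path, pseudocount: float = 0.01,
                background=None) -> PWM:
    """Read a JASPAR-style pfm file (either the 'A [..]' or 4-row dialect)."""
    from Bio import motifs as bio_motifs

    path = Path(path)
    for fmt in ("jaspar", "pfm"):
        try:
            with open(path) as fh:
                m = bio_motifs.read(fh, fmt)
            counts = np.array([[m.counts[b][i] for b in _BASES]
                               for i in range(m.length)])
            name = getattr(m, "matrix_id", None) or m.name or path.stem
            return PWM(name, counts, background=background,
                       pseudocount=pseudocount)
        except Exception:
            continue
    raise ValueError(f"could not parse {path} as a JASPAR pfm matrix")


def score_pwm(seq: str, pwm: PWM) -> float:
    """Log2-odds score of one W-mer; ambiguous bases score -inf."""
    if len(seq) != pwm.width:
        raise ValueError(
            f"sequence length {len(seq)} != matrix width {pwm.width}"
        )
    lom = pwm.log_odds
    total = 0.0
    for j, base in enumerate(seq.upper()):
        idx = _BASES.find(base)
        if idx < 0:
            return float("-inf")
        total += lom[j, idx]
    return float(total)


def threshold_from_pvalue(pwm: PWM, pvalue: float = 0.001,
                          granularity: float = GRANULARITY) -> float:
    """Minimal score s with P(score of a background W-mer >= s) <= pvalue.

    Exact up to the score discretization granularity.  If even the maximal
    score is more probable than the requested p-value, that maximum is
    returned with a warning.
    """
    if not 0.0 < pvalue <= 1.0:
        raise ValueError("pvalue must lie in (0, 1]")
    scores, survival = pwm.score_distribution(granularity)
    idx = np.nonzero(survival <= pvalue + 1e-15)[0]
    if len(idx) == 0:
        warnings.warn(
            f"p-value {pvalue} unreachable for {pwm.name} "
            f"(min tail {survival[-1]:.3g}); using the maximal score",
            stacklevel=2,
        )
        return float(scores[-1])
    return float(scores[idx[0]])


_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_one_strand(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Vector of window scores; windows containing N score -1e9."""
    W = lom.shape[0]
    L = len(codes)
    if L < W:
        return np.empty(0)
    lom5 = np.hstack([lom, np.full((W, 1), -1e9)])
    scores = np.zeros(L - W + 1)
    for j in range(W):
        scores += lom5[j, codes[j:L - W + 1 + j]]
    return scores


def load_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def scan_sequences(genome: dict[str, str] | str | Path, pwm: PWM,
                   pvalue: float = 0.001, strands: str = "both",
                   threshold: float | None = None) -> list[MotifHit]:
    """Scan a genome for matrix matches on one or both strands.

    The threshold defaults to :func:`threshold_from_pvalue` at ``pvalue``.
    Reverse-strand matches are scored with the reverse-complement matrix so
    they can be reported in forward coordinates.  Hits are ordered by
    (chrom, start, strand); each hit carries the exact tail p-value of its
    score under the background model.
    """
    if strands not in ("both", "+", "-"):
        raise ValueError(f"unknown strands {strands!r}")
    if not isinstance(genome, dict):
        genome = load_fasta(genome)
    if threshold is None:
        threshold = threshold_from_pvalue(pwm, pvalue)
    scores_grid, survival = pwm.score_distribution()

    def tail_p(score: float) -> float:
        i = np.searchsorted(scores_grid, score - GRANULARITY / 2)
        return float(survival[min(i, len(survival) - 1)])

    strand_loms = []
    if strands in ("both", "+"):
        strand_loms.append(("+", pwm.log_odds))
    if strands in ("both", "-"):
        strand_loms.append(("-", pwm.reverse_complement().log_odds))

    hits = []
    W = pwm.width
    for chrom in sorted(genome):
        codes = _encode(genome[chrom])
        for strand, lom in strand_loms:
            scores = _scan_one_strand(codes, lom)
            for pos in np.nonzero(scores >= threshold - 1e-9)[0]:
                s = float(scores[pos])
                hits.append(MotifHit(chrom, int(pos), int(pos) + W, strand,
                                     s, tail_p(s)))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def randomize_pwm(pwm: PWM, seed: int) -> PWM:
    """Column-permuted copy of a matrix, preserving base composition.

    The permutation of motif positions is drawn uniformly from non-identity
    permutations (rejection sampling), except when all positions are
    identical, in which case any permutation reproduces the input.  Seeded
    and reproducible.
    """
    if pwm.width < 2:
        raise ValueError("randomization needs at least 2 matrix positions")
    rng = np.random.default_rng(seed)
    degenerate = bool(np.all(pwm.matrix == pwm.matrix[0]))
    identity = np.arange(pwm.width)
    while True:
        perm = rng.permutation(pwm.width)
        if degenerate or not np.array_equal(perm, identity):
            break
    return PWM(f"{pwm.name}_randomized", pwm.matrix[perm],
               pwm.background, pwm.pseudocount)


def _band_membership(hit_centers: dict[str, np.ndarray],
                     snp_pos: dict[str, np.ndarray],
                     lo: int, hi: int) -> int:
    """Number of hits whose distance to some SNP lies in [lo, hi]."""
    count = 0
    for chrom, centers in hit_centers.items():
        ps = snp_pos.get(chrom)
        if ps is None or len(ps) == 0:
            continue
        if lo == 0:
            in_band = (
                np.searchsorted(ps, centers + hi, side="right")
                > np.searchsorted(ps, centers - hi, side="left")
            )
        else:
            left = (
                np.searchsorted(ps, centers - lo, side="right")
                > np.searchsorted(ps, centers - hi, side="left")
            )
            right = (
                np.searchsorted(ps, centers + hi, side="right")
                > np.searchsorted(ps, centers + lo, side="left")
            )
            in_band = left | right
        count += int(in_band.sum())
    return count


def snp_motif_contingency(
    snps: list[Variant],
    hits_real: list[MotifHit],
    hits_random: list[MotifHit],
    near_bp: int = 100,
    far_lo_bp: int = 900,
    far_hi_bp: int = 1000,
    alternative: str = "two_sided",
) -> tuple[ContingencyTable, EnrichmentResult]:
    """Near-vs-far contingency of real and randomized matrix hits around SNPs.

    a = real hits within +/-near_bp of any SNP; b = randomized hits in the
    near band; c/d = the same in the far band [far_lo_bp, far_hi_bp] on
    either flank.  A hit is counted once per band membership even when near
    windows of close SNPs overlap.  Returns the table and its Fisher test.
    """
    snp_pos: dict[str, list[int]] = {}
    for v in snps:
        snp_pos.setdefault(v.chrom, []).append(v.pos)
    snp_arr = {ch: np.sort(np.asarray(ps)) for ch, ps in snp_pos.items()}

    def centers(hits: list[MotifHit]) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for h in hits:
            out.setdefault(h.chrom, []).append(h.center)
        return {ch: np.asarray(cs) for ch, cs in out.items()}

    real_c, rand_c = centers(hits_real), centers(hits_random)
    table = ContingencyTable(
        a=_band_membership(real_c, snp_arr, 0, near_bp),
        b=_band_membership(rand_c, snp_arr, 0, near_bp),
        c=_band_membership(real_c, snp_arr, far_lo_bp, far_hi_bp),
        d=_band_membership(rand_c, snp_arr, far_lo_bp, far_hi_bp),
    )
    return table, fisher_exact(table, alternative=alternative)


def write_hits_bed(hits: list[MotifHit], path: str | Path) -> Path:
    """Write hits as BED6 (name = score rank is omitted; score = log2 odds)."""
    path = Path(path)
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t.\t{h.score:.4f}\t{h.strand}\n"
            )
    return path
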