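"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of the real inputs — a
genome with planted TF-binding motifs, SNP panels whose "case" set sits
near motifs at a controlled rate, open-chromatin/enhancer/TF peak sets
enriched for motif positions inside a DHS background universe, allelic
qPCR intensities with a known imbalance and mixing-series calibration, and
Hardy-Weinberg eQTL cohorts with known effect sizes — so that every
downstream statistic can be checked against a recorded truth without any
external download.

Every generator is a pure function of (config, seed): the same
configuration reproduces byte-identical data.  Distinct deterministic
substreams are derived per generator so the pieces can be regenerated
independently.

The DHS universe is laid out as non-overlapping fixed-width slots with
feature peaks placed inside chosen slots.  This guarantees the universe is
a superset of every feature set, and makes the per-slot overlap-by-SNP
classification exchangeable when no enrichment is planted — so Fisher
null calibration on synthetic data is honest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .allelic import STANDARD_MIX_RATIOS, AllelicMeasurement, CalibrationPoint
from .eqtl import Cohort
from .intervals import GenomicInterval, PeakSet, write_bed
from .ld import LDRecord, Variant
from .motif import PWM

__all__ = [
    "SimulationConfig",
    "SnpPanel",
    "PeakCollection",
    "AllelicDataset",
    "ap1_like_pwm",
    "generate_genome",
    "generate_snp_panel",
    "generate_peaks",
    "generate_allelic_dataset",
    "generate_eqtl_cohort",
    "simulate_all",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Desk-scale simulation conditions.

    The defaults describe a 1-Mb single-chromosome genome with 200 planted
    motif instances, 100 case and 100 control SNPs (half the case SNPs
    within 100 bp of a motif), a DHS universe of 1,500 fixed 400-bp slots,
    an allelic-imbalance cohort of 23 heterozygotes with a true ratio of
    1.3, and an n=500 eQTL cohort with effect size 0.4 — all stages run in
    seconds to minutes.
    """

    seed: int = 0
    genome_length_bp: int = 1_000_000
    gc_fraction: float = 0.41
    n_planted_motifs: int = 200
    n_case_snps: int = 100
    n_control_snps: int = 100
    fraction_snps_near_motif: float = 0.5
    near_distance_bp: int = 100
    peak_width_mean_bp: int = 300
    true_allelic_ratio: float = 1.3
    allelic_noise_sd: float = 0.1
    eqtl_beta: float = 0.4
    eqtl_n: int = 500
    maf: float = 0.3
    # layout of the synthetic DHS universe and feature peak sets
    dhs_slot_bp: int = 400
    n_dhs: int = 1500
    n_peaks_per_set: int = 300
    peak_motif_fraction: float = 0.8
    # LD-block construction
    ld_block_size: int = 3
    # allelic assay forward model
    n_heterozygotes: int = 23
    calibration_slope: float = 0.95
    calibration_intercept: float = 0.1
    calibration_noise_sd: float = 0.02

    def __post_init__(self):
        for name in ("genome_length_bp", "n_planted_motifs", "n_case_snps",
                     "n_control_snps", "near_distance_bp", "peak_width_mean_bp",
                     "dhs_slot_bp", "n_dhs", "n_peaks_per_set",
                     "ld_block_size", "n_heterozygotes", "eqtl_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("gc_fraction", "fraction_snps_near_motif",
                     "peak_motif_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must lie strictly in (0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-generator substream."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class SnpPanel:
    case: list[Variant]
    control: list[Variant]
    ld_table: list[LDRecord]
    panel: dict[str, Variant]  # rsid -> coordinates, proxies included
    truth: dict


@dataclass
class PeakCollection:
    atac: PeakSet
    h3k27ac: PeakSet
    tf: PeakSet
    dhs: PeakSet
    truth: dict


@dataclass
class AllelicDataset:
    calibration_points: list[CalibrationPoint]
    measurements: list[AllelicMeasurement]
    truth: dict


def ap1_like_pwm(pseudocount: float = 0.01) -> PWM:
    """A synthetic AP-1-like matrix around the TGA(C/G)TCA consensus.

    Eleven positions: two moderately informative flanks on each side of
    the seven-position core, as in full-length AP-1 matrices.  The
    degenerate middle position carries C and G equally, which makes the
    core self-reverse-complementary like the real AP-1 element.  The
    information content is set high enough that instances sampled from
    the matrix score above the 0.001 background threshold with ~97%
    probability, so planted-truth recovery is sharp.  This is a synthetic
    stand-in with the canonical consensus, not a database matrix.
    """
    strong = {b: [0.98 if x == b else 0.02 / 3 for x in _BASES]
              for b in _BASES}
    flank = {b: [0.60 if x == b else 0.40 / 3 for x in _BASES]
             for b in _BASES}
    middle = [0.01, 0.49, 0.49, 0.01]
    rows = [
        flank["A"], flank["T"],
        strong["T"], strong["G"], strong["A"], middle,
        strong["T"], strong["C"], strong["A"],
        flank["A"], flank["C"],
    ]
    return PWM("AP1_synthetic", rows, pseudocount=pseudocount)


def _spaced_positions(rng: np.random.Generator, n: int, lo: int, hi: int,
                      sep: int) -> np.ndarray:
    """n sorted positions in [lo, hi) pairwise separated by >= sep."""
    span = hi - lo - (n - 1) * sep
    if n > 0 and span <= 0:
        raise ValueError(
            f"cannot place {n} features with separation {sep} in "
            f"[{lo}, {hi})"
        )
    base = np.sort(rng.integers(lo, lo + span, size=n))
    return base + np.arange(n) * sep


def generate_genome(config: SimulationConfig, pwm: PWM | None = None,
                    consensus_only: bool = False,
                    chrom: str = "chr1") -> tuple[dict[str, str], PeakSet]:
    """I.i.d. genome at the requested GC with planted motif instances.

    Instances are sampled from the matrix (or its consensus with
    ``consensus_only``) at non-overlapping recorded positions, kept clear
    of the chromosome ends so that +/-1 kb windows around them fit.
    Returns the genome and a BED-ready peak set of planted positions.
    """
    pwm = pwm or ap1_like_pwm()
    rng = config.rng(1)
    gc = config.gc_fraction
    base_probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=config.genome_length_bp, p=base_probs)
    margin = 1_100
    W = pwm.width
    positions = _spaced_positions(
        rng, config.n_planted_motifs, margin,
        config.genome_length_bp - margin - W, sep=W + 2 * config.near_distance_bp,
    )
    for pos in positions:
        if consensus_only:
            inst = [_BASES.index(b) for b in pwm.consensus]
        else:
            inst = [rng.choice(4, p=pwm.matrix[j]) for j in range(W)]
        codes[pos:pos + W] = inst
    seq = "".join(_BASES[c] for c in codes)
    planted = PeakSet(
        label="planted_motifs",
        intervals=[GenomicInterval(chrom, int(p), int(p) + W, name=f"m{i}")
                   for i, p in enumerate(positions)],
    )
    return {chrom: seq}, planted


def generate_snp_panel(config: SimulationConfig, planted: PeakSet,
                       chrom: str = "chr1") -> SnpPanel:
    """Case and control SNP sets with block LD structure and known truth.

    A configured fraction of case SNPs is placed within near_distance_bp
    of distinct planted motif centers; the remainder, and all controls,
    are uniform.  Each case lead receives an LD block of proxies, the
    first at r2 = D' = 1.0, the rest with r2 and a consistent D' >=
    sqrt(r2) drawn at random.
    """
    rng = config.rng(2)
    L = config.genome_length_bp
    motif_centers = np.array([iv.midpoint for iv in planted])
    n_near = int(round(config.fraction_snps_near_motif * config.n_case_snps))
    if n_near > len(motif_centers):
        raise ValueError("more near-motif SNPs requested than planted motifs")
    near_motifs = rng.choice(len(motif_centers), size=n_near, replace=False) \
        if n_near else np.empty(0, dtype=int)

    def mk(rsid: str, pos: int) -> Variant:
        return Variant(rsid=rsid, chrom=chrom, pos=int(np.clip(pos, 0, L - 1)),
                       ref_allele="A", alt_allele="G",
                       maf=float(np.round(rng.uniform(0.16, 0.5), 3)))

    case, near_ids = [], []
    for i in range(config.n_case_snps):
        if i < n_near:
            center = motif_centers[near_motifs[i]]
            pos = center + rng.integers(-config.near_distance_bp,
                                        config.near_distance_bp + 1)
            near_ids.append(f"case{i}")
        else:
            pos = rng.integers(0, L)
        case.append(mk(f"case{i}", pos))
    control = [mk(f"ctrl{i}", rng.integers(0, L))
               for i in range(config.n_control_snps)]

    panel = {v.rsid: v for v in case + control}
    ld_table: list[LDRecord] = []
    for lead in case:
        for j in range(config.ld_block_size - 1):
            rsid = f"{lead.rsid}_p{j}"
            proxy = mk(rsid, lead.pos + rng.integers(500, 5_000))
            panel[rsid] = proxy
            if j == 0:
                r2, dp = 1.0, 1.0
            else:
                r2 = float(np.round(rng.uniform(0.2, 0.95), 3))
                root = np.sqrt(r2)
                dp = float(np.round(root + rng.uniform(0, 1 - root), 3))
                # rounding must not break the r2 <= D'^2 consistency contract
                dp = max(dp, float(np.ceil(root * 1000) / 1000))
            ld_table.append(LDRecord(lead.rsid, rsid, r2=r2, dprime=dp))
    truth = {
        "near_motif_case_rsids": sorted(near_ids),
        "n_near": n_near,
        "case_rsids": [v.rsid for v in case],
        "control_rsids": [v.rsid for v in control],
    }
    return SnpPanel(case=case, control=control, ld_table=ld_table,
                    panel=panel, truth=truth)


def generate_peaks(config: SimulationConfig, planted: PeakSet,
                   motif_fraction: float | None = None,
                   chrom: str = "chr1") -> PeakCollection:
    """ATAC, H3K27ac, TF and DHS peak sets over a slotted background.

    The DHS universe is n_dhs non-overlapping slots of dhs_slot_bp: every
    slot containing a planted motif, topped up with random slots.  Each
    feature set samples n_peaks_per_set slots — a motif_fraction share
    from motif slots, the rest at random — and draws one jittered peak
    inside each chosen slot, so every feature set is a subset of the
    universe.  Peak scores emulate signal intensity (motif-anchored peaks
    run hotter).
    """
    if motif_fraction is None:
        motif_fraction = config.peak_motif_fraction
    rng = config.rng(3)
    slot = config.dhs_slot_bp
    n_slots_total = config.genome_length_bp // slot
    motif_slots = sorted({iv.midpoint // slot for iv in planted})
    if len(motif_slots) > config.n_dhs:
        raise ValueError("DHS universe too small to hold all motif slots")
    remaining = np.setdiff1d(np.arange(n_slots_total), motif_slots)
    random_slots = rng.choice(remaining, size=config.n_dhs - len(motif_slots),
                              replace=False)
    dhs_slots = np.sort(np.concatenate([motif_slots, random_slots]).astype(int))
    motif_set = set(motif_slots)
    nonmotif_dhs = np.array([s for s in dhs_slots if s not in motif_set])

    def one_feature(label: str) -> tuple[PeakSet, list[int]]:
        n_motif = min(int(round(motif_fraction * config.n_peaks_per_set)),
                      len(motif_slots))
        n_rand = config.n_peaks_per_set - n_motif
        chosen = []
        if n_motif:
            chosen.extend(rng.choice(motif_slots, size=n_motif, replace=False))
        if n_rand:
            chosen.extend(rng.choice(nonmotif_dhs, size=n_rand, replace=False))
        ivs = []
        for s in sorted(int(c) for c in chosen):
            width = int(np.clip(rng.normal(config.peak_width_mean_bp,
                                           config.peak_width_mean_bp / 6),
                                50, slot))
            off = int(rng.integers(0, slot - width + 1))
            start = s * slot + off
            hot = 1.0 if s in motif_set else 0.0
            score = float(np.round(
                max(1.0, rng.lognormal(2.0 + hot, 0.5)), 3))
            ivs.append(GenomicInterval(chrom, start, start + width, score))
        return PeakSet(label=label, intervals=ivs), sorted(
            int(c) for c in chosen)

    atac, atac_slots = one_feature("atac")
    k27, k27_slots = one_feature("h3k27ac")
    tf, tf_slots = one_feature("tf")
    dhs = PeakSet(label="dhs", intervals=[
        GenomicInterval(chrom, int(s) * slot, int(s) * slot + slot)
        for s in dhs_slots
    ])
    truth = {
        "motif_slots": [int(s) for s in motif_slots],
        "atac_slots": atac_slots, "h3k27ac_slots": k27_slots,
        "tf_slots": tf_slots, "dhs_slots": [int(s) for s in dhs_slots],
        "motif_fraction": motif_fraction,
    }
    return PeakCollection(atac=atac, h3k27ac=k27, tf=tf, dhs=dhs, truth=truth)


def generate_allelic_dataset(config: SimulationConfig,
                             rsid: str = "rs_sim") -> AllelicDataset:
    """Mixing-series calibration points and heterozygote measurements.

    The forward model maps a true log2 allele ratio through the assay
    line slope * log2(ratio) + intercept plus Gaussian measurement noise.
    Heterozygote cDNA carries the configured true allelic ratio; gDNA is
    balanced (1:1) by construction.
    """
    rng = config.rng(4)
    slope, icpt = config.calibration_slope, config.calibration_intercept
    points = [
        CalibrationPoint(
            mix_ratio=r,
            log2_intensity_ratio=float(
                slope * np.log2(r) + icpt
                + rng.normal(0, config.calibration_noise_sd)),
        )
        for r in STANDARD_MIX_RATIOS
    ]
    log2_true = np.log2(config.true_allelic_ratio)
    measurements = [
        AllelicMeasurement(
            sample_id=f"S{i}", rsid=rsid,
            cdna_log2_ratio=float(slope * log2_true + icpt
                                  + rng.normal(0, config.allelic_noise_sd)),
            gdna_log2_ratio=float(icpt
                                  + rng.normal(0, config.allelic_noise_sd)),
        )
        for i in range(config.n_heterozygotes)
    ]
    truth = {"slope": slope, "intercept": icpt,
             "true_allelic_ratio": config.true_allelic_ratio}
    return AllelicDataset(calibration_points=points, measurements=measurements,
                          truth=truth)


def generate_eqtl_cohort(config: SimulationConfig,
                         second_snp_r2: float | None = None,
                         effect_snp: str = "snp1") -> tuple[Cohort, dict]:
    """Hardy-Weinberg cohort with expression = beta * dosage + noise.

    With ``second_snp_r2`` a second SNP is generated on phased haplotypes
    at the requested r2 to the first (same allele frequency); the causal
    effect is attached to ``effect_snp``.
    """
    import pandas as pd

    if not 0.0 < config.maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    rng = config.rng(5)
    n = config.eqtl_n
    p = config.maf
    if second_snp_r2 is None:
        geno = {"snp1": rng.binomial(2, p, size=n)}
    else:
        if not 0.0 <= second_snp_r2 <= 1.0:
            raise ValueError("second_snp_r2 must lie in [0, 1]")
        r = np.sqrt(second_snp_r2)
        q = 1 - p
        D = r * p * q  # equal-frequency loci
        hap_probs = np.array([q * q + D, p * q - D, q * p - D, p * p + D])
        haps = rng.choice(4, size=(n, 2), p=hap_probs)
        # haplotype code: bit 0 = allele at snp1, bit 1 = allele at snp2
        geno = {
            "snp1": (haps % 2).sum(axis=1),
            "snp2": (haps // 2).sum(axis=1),
        }
    dosage = geno[effect_snp]
    expr = config.eqtl_beta * dosage + rng.normal(0, 1, size=n)
    cohort = Cohort(
        genotypes=pd.DataFrame(geno),
        expression=pd.DataFrame({"gene1": expr}),
    )
    truth = {"beta": config.eqtl_beta, "effect_snp": effect_snp,
             "maf": p, "second_snp_r2": second_snp_r2}
    return cohort, truth


def simulate_all(config: SimulationConfig, outdir: str | Path) -> Path:
    """Write FASTA, BEDs, TSVs and a truth.json manifest for a full run."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, planted = generate_genome(config)
    with open(outdir / "genome.fa", "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_bed(planted, outdir / "planted_motifs.bed")
    snps = generate_snp_panel(config, planted)
    peaks = generate_peaks(config, planted)
    for name, ps in (("atac", peaks.atac), ("h3k27ac", peaks.h3k27ac),
                     ("tf", peaks.tf), ("dhs", peaks.dhs)):
        write_bed(ps, outdir / f"{name}.bed")
    pd.DataFrame(
        [(v.rsid, v.chrom, v.pos, v.ref_allele, v.alt_allele, v.maf, label)
         for label, vs in (("case", snps.case), ("control", snps.control))
         for v in vs],
        columns=["rsid", "chrom", "pos", "ref", "alt", "maf", "group"],
    ).to_csv(outdir / "snps.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(r.lead_rsid, r.proxy_rsid, r.r2, r.dprime, r.population)
         for r in snps.ld_table],
        columns=["lead", "proxy", "r2", "dprime", "pop"],
    ).to_csv(outdir / "ld.tsv", sep="\t", index=False)
    allelic = generate_allelic_dataset(config)
    pd.DataFrame(
        [(p.mix_ratio, p.log2_intensity_ratio)
         for p in allelic.calibration_points],
        columns=["mix_ratio", "log2_intensity_ratio"],
    ).to_csv(outdir / "calibration.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(m.sample_id, m.rsid, m.cdna_log2_ratio, m.gdna_log2_ratio)
         for m in allelic.measurements],
        columns=["sample", "rsid", "cdna_log2_ratio", "gdna_log2_ratio"],
    ).to_csv(outdir / "allelic.tsv", sep="\t", index=False)
    cohort, eqtl_truth = generate_eqtl_cohort(config)
    cohort.genotypes.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    truth = {
        "config": asdict(config),
        "snp_panel": snps.truth,
        "peaks": peaks.truth,
        "allelic": allelic.truth,
        "eqtl": eqtl_truth,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return outdir
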