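"""LD expansion of lead GWAS SNPs and transcribed-proxy marker selection.

LD is consumed as an input table (population-tagged pairwise r2 and |D'|),
as produced by 1000 Genomes browsers — it is never computed from genotypes
here.  Inconsistent records (r2 > D'^2) are tolerated and logged, since
published LD tables are not always internally consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .intervals import normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "LDRecord",
    "expand_ld",
    "select_transcribed_proxy",
    "read_variant_table",
    "read_ld_table",
]


@dataclass(frozen=True)
class Variant:
    """A bi-allelic SNP with 0-based position."""

    rsid: str
    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "G"
    risk_allele: str | None = None
    maf: float | None = None

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")
        if self.pos < 0:
            raise ValueError(f"{self.rsid}: negative position")
        if self.maf is not None and not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.rsid}: maf {self.maf} outside [0, 0.5]")


@dataclass(frozen=True)
class LDRecord:
    """Pairwise linkage between a lead SNP and a proxy: r2 and |D'|."""

    lead_rsid: str
    proxy_rsid: str
    r2: float
    dprime: float
    population: str = "EUR"

    def __post_init__(self):
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 {self.r2} outside [0, 1]")
        if not 0.0 <= self.dprime <= 1.0:
            raise ValueError(f"dprime {self.dprime} outside [0, 1]")
        # r2 <= D'^2 is expected but not enforced: log, keep the record
        if self.r2 > self.dprime**2 + 1e-9:
            logger.warning(
                "inconsistent LD record %s-%s: r2=%.3f > dprime^2=%.3f",
                self.lead_rsid, self.proxy_rsid, self.r2, self.dprime**2,
            )


def expand_ld(
    leads: list[Variant] | set[Variant],
    ld_table: list[LDRecord],
    panel: dict[str, Variant] | None = None,
    r2_min: float = 0.8,
) -> list[Variant]:
    """Expand lead SNPs to leads plus all proxies with r2 >= r2_min.

    The threshold is inclusive.  `panel` maps proxy rsids to Variant
    coordinate records; proxies absent from the panel are skipped with a
    logged warning count.  Leads are always retained.  The result is
    deduplicated by rsid and sorted by (chrom, pos, rsid).
    """
    panel = panel or {}
    by_rsid: dict[str, Variant] = {v.rsid: v for v in leads}
    lead_ids = set(by_rsid)
    n_skipped = 0
    for rec in ld_table:
        if rec.lead_rsid not in lead_ids or rec.r2 < r2_min:
            continue
        if rec.proxy_rsid in by_rsid:
            continue
        proxy = panel.get(rec.proxy_rsid)
        if proxy is None:
            n_skipped += 1
            continue
        by_rsid[rec.proxy_rsid] = proxy
    if n_skipped:
        logger.warning(
            "expand_ld: skipped %d proxies with no coordinate record", n_skipped
        )
    return sorted(by_rsid.values(), key=lambda v: (v.chrom, v.pos, v.rsid))


def select_transcribed_proxy(
    candidate: Variant,
    transcribed_snps: list[Variant] | set[Variant],
    ld_table: list[LDRecord],
    dprime_strict: float = 0.90,
    dprime_relaxed: float = 0.75,
    maf_min: float = 0.15,
) -> Variant | None:
    """Pick a transcribed marker SNP linked to a candidate regulatory SNP.

    Preference order: the transcribed SNP with maximal |D'| to the candidate
    with D' > dprime_strict and MAF > maf_min; failing that, the best under
    the relaxed D' > dprime_relaxed cutoff; failing that, None (the caller
    may then measure the candidate itself in pre-mRNA, the intronic
    surrogate strategy).  Ties break by higher MAF, then rsid.
    """
    transcribed = {v.rsid: v for v in transcribed_snps}
    linked: dict[str, float] = {}
    for rec in ld_table:
        other = None
        if rec.lead_rsid == candidate.rsid:
            other = rec.proxy_rsid
        elif rec.proxy_rsid == candidate.rsid:
            other = rec.lead_rsid
        if other is not None and other in transcribed:
            linked[other] = max(linked.get(other, 0.0), rec.dprime)

    def best(dprime_cut: float) -> Variant | None:
        pool = [
            (dp, transcribed[rsid].maf or 0.0, rsid)
            for rsid, dp in linked.items()
            if dp > dprime_cut
            and transcribed[rsid].maf is not None
            and transcribed[rsid].maf > maf_min
        ]
        if not pool:
            return None
        dp, _maf, rsid = max(pool, key=lambda t: (t[0], t[1], _rev(t[2])))
        return transcribed[rsid]

    return best(dprime_strict) or best(dprime_relaxed)


class _rev(str):
    """Reverse lexicographic comparison so max() picks the smaller rsid."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)


def read_variant_table(path: str | Path) -> list[Variant]:
    """Read a variant TSV with columns rsid, chrom, pos[, ref, alt, maf]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    variants = []
    for row in df.itertuples(index=False):
        variants.append(
            Variant(
                rsid=row.rsid,
                chrom=normalize_chrom(str(row.chrom)),
                pos=int(row.pos),
                ref_allele=getattr(row, "ref", "A"),
                alt_allele=getattr(row, "alt", "G"),
                maf=float(row.maf) if hasattr(row, "maf") else None,
            )
        )
    return variants


def read_ld_table(path: str | Path) -> list[LDRecord]:
    """Read an LD TSV with columns lead, proxy, r2, dprime[, pop]."""
    df = pd.read_csv(path, sep="\t")
    return [
        LDRecord(
            lead_rsid=row.lead,
            proxy_rsid=row.proxy,
            r2=float(row.r2),
            dprime=float(row.dprime),
            population=getattr(row, "pop", "EUR"),
        )
        for row in df.itertuples(index=False)
    ]
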