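"""The candidate-variant funnel: peak-overlap combination and annotation filters.

A GWAS-expanded variant panel is flagged for 1-bp containment in open
chromatin (ATAC), active enhancer (H3K27ac) and transcription-factor
binding peaks; the combined candidates carry all three flags.  Candidates
are then filtered on regulatory annotation categories (functional score
<= 4 on the 1-6 scale, lower = stronger evidence) and on in-vivo protein
binding (>= 1 trans-acting factor).  Annotation scores are consumed from
an input table, never queried live.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import PeakSet
from .ld import Variant

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateVariant",
    "overlap_combination",
    "functional_filter",
    "read_annotations",
    "candidates_to_frame",
]


@dataclass(frozen=True)
class CandidateVariant:
    """A variant with its per-dataset overlap flags and annotations."""

    variant: Variant
    in_open_chromatin: bool
    in_h3k27ac: bool
    in_tf_binding: bool
    functional_score: int | None = None
    n_bound_factors: int = 0
    locus_label: str | None = None
    tf_flags: tuple[tuple[str, bool], ...] = ()

    def __post_init__(self):
        if self.functional_score is not None and not 1 <= self.functional_score <= 6:
            raise ValueError("functional_score must be an integer in 1..6")
        if self.n_bound_factors < 0:
            raise ValueError("n_bound_factors must be >= 0")

    @property
    def combined(self) -> bool:
        """All three overlap flags at once — the combined candidate set."""
        return self.in_open_chromatin and self.in_h3k27ac and self.in_tf_binding


def _containment_flags(variants: list[Variant], peaks: PeakSet) -> list[bool]:
    pos_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in peaks:
        pos_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    starts_ends = {
        ch: (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
        for ch, ivs in (
            (ch, sorted(ivs)) for ch, ivs in pos_by_chrom.items()
        )
    }
    flags = []
    for v in variants:
        se = starts_ends.get(v.chrom)
        if se is None:
            flags.append(False)
            continue
        starts, ends = se
        # half-open containment: start <= pos < end; a SNP at pos == end is outside
        i = np.searchsorted(starts, v.pos, side="right")
        flags.append(bool((ends[:i] > v.pos).any()))
    return flags


def overlap_combination(
    variants: list[Variant],
    atac: PeakSet,
    h3k27ac: PeakSet,
    tf: PeakSet | list[PeakSet],
    annotations: dict[str, tuple[int, int]] | None = None,
    locus_labels: dict[str, str] | None = None,
) -> list[CandidateVariant]:
    """Flag every variant for containment in each peak set.

    ``tf`` may be a single peak set or a list of per-factor sets; the TF
    flag is the union over factors, with per-factor flags retained.
    Optional ``annotations`` maps rsid -> (functional_score, n_factors).
    """
    tf_sets = tf if isinstance(tf, list) else [tf]
    atac_flags = _containment_flags(variants, atac)
    k27_flags = _containment_flags(variants, h3k27ac)
    per_tf = [(ts.label, _containment_flags(variants, ts)) for ts in tf_sets]
    annotations = annotations or {}
    locus_labels = locus_labels or {}
    out = []
    for i, v in enumerate(variants):
        tf_flags = tuple((label, flags[i]) for label, flags in per_tf)
        score, n_factors = annotations.get(v.rsid, (None, 0))
        out.append(CandidateVariant(
            variant=v,
            in_open_chromatin=atac_flags[i],
            in_h3k27ac=k27_flags[i],
            in_tf_binding=any(f for _, f in tf_flags),
            functional_score=score,
            n_bound_factors=n_factors,
            locus_label=locus_labels.get(v.rsid),
            tf_flags=tf_flags,
        ))
    return out


def functional_filter(
    candidates: list[CandidateVariant],
    max_score: int = 4,
    min_factors: int = 1,
) -> tuple[list[CandidateVariant], int]:
    """Retain candidates with score <= max_score and >= min_factors bound.

    Candidates lacking a functional score are dropped; their count is
    returned alongside the retained list.
    """
    kept = []
    n_unscored = 0
    for c in candidates:
        if c.functional_score is None:
            n_unscored += 1
            continue
        if c.functional_score <= max_score and c.n_bound_factors >= min_factors:
            kept.append(c)
    if n_unscored:
        logger.info("functional_filter: dropped %d unscored candidates",
                    n_unscored)
    return kept, n_unscored


def read_annotations(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read an annotation TSV with columns rsid, score, n_factors."""
    df = pd.read_csv(path, sep="\t")
    return {
        row.rsid: (int(row.score), int(row.n_factors))
        for row in df.itertuples(index=False)
    }


def candidates_to_frame(candidates: list[CandidateVariant]) -> pd.DataFrame:
    """Flat candidate table for TSV export and auditing of the funnel."""
    rows = []
    for c in candidates:
        row = {
            "rsid": c.variant.rsid,
            "chrom": c.variant.chrom,
            "pos": c.variant.pos,
            "locus": c.locus_label,
            "in_open_chromatin": c.in_open_chromatin,
            "in_h3k27ac": c.in_h3k27ac,
            "in_tf_binding": c.in_tf_binding,
            "combined": c.combined,
            "functional_score": c.functional_score,
            "n_bound_factors": c.n_bound_factors,
        }
        for label, flag in c.tf_flags:
            row[f"tf_{label}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)
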