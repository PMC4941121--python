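"""Genomic-interval data model and arithmetic.

All coordinates are 0-based half-open (BED convention), including SNP
positions, which downstream modules store as width-1 intervals.  Intervals
sharing only a boundary coordinate do not overlap.  Strand is ignored:
peaks are unstranded; strand only matters inside motif scanning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "BedParseError",
    "GenomeMismatchError",
    "read_bed",
    "write_bed",
    "intersect",
    "merge",
    "midpoints",
    "filter_by_length",
    "normalize_chrom",
]


class BedParseError(ValueError):
    """A BED record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class GenomeMismatchError(ValueError):
    """Two peak sets on different assemblies were combined."""


def normalize_chrom(name: str) -> str:
    """Normalize chromosome dialects ('1' vs 'chr1') to the chr-prefixed form."""
    name = name.strip()
    return name if name.startswith("chr") else f"chr{name}"


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region [start, end) with optional score and name."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    name: str | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.score is not None and self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # even-length intervals take the lower-middle base
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class PeakSet:
    """An ordered collection of intervals from one dataset on one assembly.

    Intervals are sorted by (chrom, start, end) on construction.
    """

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    genome_id: str = "synthetic"

    def __post_init__(self):
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return (
            self.label == other.label
            and self.genome_id == other.genome_id
            and self.intervals == other.intervals
        )

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def covered_bp(self) -> int:
        """Total bases covered by the union of the intervals (>= 0)."""
        total = 0
        for iv in merge(self).intervals:
            total += iv.length
        return total

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees for overlap queries."""
        out: dict[str, IntervalTree] = {}
        for chrom, ivs in self.by_chrom().items():
            out[chrom] = IntervalTree.from_tuples(
                (iv.start, iv.end, i) for i, iv in enumerate(ivs)
            )
        return out

    def summary(self) -> dict:
        return {
            "label": self.label,
            "genome_id": self.genome_id,
            "n_intervals": len(self),
            "covered_bp": self.covered_bp(),
            "n_chroms": len(self.chroms),
        }


def read_bed(path: str | Path, label: str | None = None,
             genome_id: str = "synthetic") -> PeakSet:
    """Read a 3-6 column BED file into a PeakSet.

    Chromosome names are normalized to the chr-prefixed dialect.  Malformed
    records raise :class:`BedParseError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"BED file not found: {path}")
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"expected >= 3 tab-separated fields, got {len(fields)}",
                    lineno,
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"non-integer coordinate: {exc}", lineno)
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"non-numeric score: {exc}", lineno)
            try:
                intervals.append(
                    GenomicInterval(
                        normalize_chrom(fields[0]), start, end, score, name
                    )
                )
            except ValueError as exc:
                raise BedParseError(str(exc), lineno)
    return PeakSet(label=label or path.stem, intervals=intervals,
                   genome_id=genome_id)


def write_bed(peaks: PeakSet, path: str | Path) -> Path:
    """Write a PeakSet as BED (3, 5 or 6 columns depending on fields present)."""
    path = Path(path)
    has_name = any(iv.name is not None for iv in peaks)
    has_score = any(iv.score is not None for iv in peaks)
    with open(path, "w") as fh:
        for iv in peaks:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if has_name or has_score:
                fields.append(iv.name if iv.name is not None else ".")
            if has_score:
                fields.append(f"{iv.score:g}" if iv.score is not None else ".")
            fh.write("\t".join(fields) + "\n")
    return path


def _check_same_genome(a: PeakSet, b: PeakSet) -> None:
    if a.genome_id != b.genome_id:
        raise GenomeMismatchError(
            f"peak sets are on different assemblies: "
            f"{a.genome_id!r} vs {b.genome_id!r}"
        )


def intersect(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1) -> PeakSet:
    """Intervals of `a` having >= min_overlap_bp overlap with any interval of `b`.

    Each interval of `a` is reported at most once, regardless of how many
    intervals of `b` it touches.  Half-open adjacency is not overlap.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be a positive integer")
    _check_same_genome(a, b)
    trees = b.trees()
    kept = []
    for iv in a:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap_bp:
                kept.append(iv)
                break
    return PeakSet(label=f"{a.label}&{b.label}", intervals=kept,
                   genome_id=a.genome_id)


def merge(a: PeakSet, gap_bp: int = 0) -> PeakSet:
    """Merge into unique non-overlapping intervals with mean member scores.

    Intervals whose gap is <= gap_bp (bookended intervals at gap_bp=0
    included) are fused; the merged score is the mean of the member scores
    that are present.  Output intervals are pairwise separated by > gap_bp.
    """
    if gap_bp < 0:
        raise ValueError("gap_bp must be non-negative")
    merged: list[GenomicInterval] = []
    cur: dict | None = None
    for iv in a:  # already sorted
        if (cur is not None and iv.chrom == cur["chrom"]
                and iv.start - cur["end"] <= gap_bp):
            cur["end"] = max(cur["end"], iv.end)
            if iv.score is not None:
                cur["scores"].append(iv.score)
        else:
            if cur is not None:
                merged.append(_emit(cur))
            cur = {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                   "scores": [] if iv.score is None else [iv.score]}
    if cur is not None:
        merged.append(_emit(cur))
    return PeakSet(label=a.label, intervals=merged, genome_id=a.genome_id)


def _emit(cur: dict) -> GenomicInterval:
    score = sum(cur["scores"]) / len(cur["scores"]) if cur["scores"] else None
    return GenomicInterval(cur["chrom"], cur["start"], cur["end"], score)


def midpoints(a: PeakSet) -> PeakSet:
    """Replace each interval by its 1-bp center floor((start+end)/2)."""
    ivs = [replace(iv, start=iv.midpoint, end=iv.midpoint + 1) for iv in a]
    return PeakSet(label=a.label, intervals=ivs, genome_id=a.genome_id)


def filter_by_length(a: PeakSet, min_bp: int) -> PeakSet:
    """Keep exactly the intervals with length >= min_bp."""
    if min_bp < 1:
        raise ValueError("min_bp must be a positive integer")
    ivs = [iv for iv in a if iv.length >= min_bp]
    return PeakSet(label=a.label, intervals=ivs, genome_id=a.genome_id)
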