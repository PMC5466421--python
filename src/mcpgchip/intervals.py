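"""Genomic interval algebra: the coordinate currency of the whole pipeline.

All coordinates are 0-based half-open (BED convention). 1-based inputs
(cytosine reports) are converted on load and back on write.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)`` on ``chrom``.

    ``strand`` is "+", "-" or "." (unspecified; peaks are unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint; the anchor for signal-region construction."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 bp overlap; intervals sharing only a boundary do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def extended(self, flank_bp: int) -> "GenomicInterval":
        """Interval extended by ``flank_bp`` on both sides, clamped at 0."""
        return replace(self, start=max(0, self.start - flank_bp), end=self.end + flank_bp)

    def contains_pos(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


@dataclass(frozen=True)
class Peak:
    """A ChIP enrichment peak: an interval with a score and a unique name."""

    interval: GenomicInterval
    score: float = 0.0
    name: str = ""

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def as_interval(item: "GenomicInterval | Peak") -> GenomicInterval:
    return item.interval if isinstance(item, Peak) else item


def find_overlaps(
    set_a: Sequence["GenomicInterval | Peak"],
    set_b: Sequence["GenomicInterval | Peak"],
) -> Dict[int, List[int]]:
    """Map each index in ``set_a`` to the indices in ``set_b`` it overlaps.

    Overlap means same chromosome and >=1 shared bp (half-open semantics).
    Only a-indices with at least one partner appear in the result. Input
    order is irrelevant; unsorted input is permitted.
    """
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for j, item in enumerate(set_b):
        iv = as_interval(item)
        trees[iv.chrom].addi(iv.start, iv.end, j)
    out: Dict[int, List[int]] = {}
    for i, item in enumerate(set_a):
        iv = as_interval(item)
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = sorted(h.data for h in tree.overlap(iv.start, iv.end))
        if hits:
            out[i] = hits
    return out


def overlaps_any(
    query: Sequence["GenomicInterval | Peak"],
    subject: Sequence["GenomicInterval | Peak"],
) -> List[bool]:
    """Per-query boolean: does it overlap >=1 subject interval."""
    hits = find_overlaps(query, subject)
    return [i in hits for i in range(len(query))]


def validate_chromosomes(
    named_sets: Mapping[str, Iterable["GenomicInterval | Peak"]],
) -> List[str]:
    """Warn-level check: chromosome names present in only some inputs.

    Matching is exact string equality (no "chr" aliasing): aliasing would
    silently hide input errors. Returns human-readable warning lines.
    """
    seen: Dict[str, set] = {
        name: {as_interval(x).chrom for x in items} for name, items in named_sets.items()
    }
    universe = set().union(*seen.values()) if seen else set()
    warnings = []
    for chrom in sorted(universe):
        holders = [name for name, chroms in seen.items() if chrom in chroms]
        if len(holders) < len(seen):
            missing = sorted(set(seen) - set(holders))
            warnings.append(
                f"chromosome {chrom!r} present in {sorted(holders)} but absent from {missing}"
            )
    return warnings
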