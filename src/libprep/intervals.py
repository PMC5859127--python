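"""Genomic interval primitives.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
GTF input/output converts to/from the 1-based closed convention at the
boundary (see :mod:`libprep.annotation`).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval on a chromosome.

    Invariants: ``0 <= start < end``, non-empty ``chrom``, strand one of
    ``+ - .``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 for different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0


def union_intervals(
    intervals: Iterable[GenomicInterval], strand: str | None = None
) -> list[GenomicInterval]:
    """Merge possibly overlapping intervals into a sorted disjoint union.

    All intervals must share a chromosome. Touching intervals
    (``a.end == b.start``) are merged.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    if not ivs:
        return []
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) > 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    out_strand = strand if strand is not None else ivs[0].strand
    merged: list[list[int]] = [[ivs[0].start, ivs[0].end]]
    for iv in ivs[1:]:
        if iv.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    chrom = ivs[0].chrom
    return [GenomicInterval(chrom, s, e, out_strand) for s, e in merged]


def complement_within(
    span: GenomicInterval, intervals: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Intervals of ``span`` not covered by ``intervals`` (must be disjoint,
    sorted, contained in span). Used to derive introns from union exons."""
    out = []
    cursor = span.start
    for iv in intervals:
        if iv.start < cursor or iv.end > span.end:
            raise ValueError("intervals not sorted/disjoint or outside span")
        if iv.start > cursor:
            out.append(GenomicInterval(span.chrom, cursor, iv.start, span.strand))
        cursor = iv.end
    if cursor < span.end:
        out.append(GenomicInterval(span.chrom, cursor, span.end, span.strand))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)
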