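"""Aligned fragments and their on-disk formats.

A fragment is one sequenced cDNA fragment (a read pair counted once) as a
set of spliced alignment blocks on a chromosome. Alignment itself is
upstream; this module only reads what an aligner produced:

* BED12 — one fragment per row; blocks from blockSizes/blockStarts; the
  score column carries the unique-mapping flag (1 unique, 0 multi-mapped).
* SAM/BAM — primary alignments of read 1; blocks from the CIGAR (M/=/X/D
  extend the current block, N splits); uniqueness from the NH tag when
  present, else MAPQ > 3.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignedFragment:
    """One uniquely/multi-mapped fragment as sorted disjoint blocks."""

    read_id: str
    chrom: str
    blocks: tuple[GenomicInterval, ...]
    strand: str
    is_unique: bool = True

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"fragment {self.read_id}: no blocks")
        prev_end = -1
        for b in self.blocks:
            if b.chrom != self.chrom:
                raise ValueError(f"fragment {self.read_id}: blocks on mixed chroms")
            if b.start < prev_end:
                raise ValueError(f"fragment {self.read_id}: blocks overlap/unsorted")
            prev_end = b.end

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end


@dataclass(frozen=True)
class SampleInfo:
    """One sequencing library: tissue x protocol x replicate."""

    sample_id: str
    tissue: str  # blood | colon | synthetic
    protocol: str  # polyA | riboZ
    replicate: int
    total_sequenced_reads: int

    def __post_init__(self) -> None:
        if self.protocol not in ("polyA", "riboZ"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.total_sequenced_reads < 0:
            raise ValueError("total_sequenced_reads must be >= 0")


BED12_COLUMNS = [
    "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
    "blockStarts",
]


def read_bed12(path: str | Path) -> list[AlignedFragment]:
    """Read fragments from BED12; score column 1 => uniquely mapped."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED12_COLUMNS,
                     comment="#", dtype={"chrom": str})
    fragments = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        if len(sizes) != int(row.blockCount) or len(starts) != int(row.blockCount):
            raise ValueError(f"fragment {row.name}: inconsistent block fields")
        blocks = tuple(
            GenomicInterval(row.chrom, row.chromStart + off,
                            row.chromStart + off + size, row.strand)
            for off, size in zip(starts, sizes)
        )
        fragments.append(
            AlignedFragment(
                read_id=str(row.name),
                chrom=row.chrom,
                blocks=blocks,
                strand=row.strand,
                is_unique=int(row.score) == 1,
            )
        )
    return fragments


def write_bed12(fragments: Iterable[AlignedFragment], path: str | Path) -> None:
    rows = []
    for f in fragments:
        sizes = ",".join(str(b.length) for b in f.blocks)
        starts = ",".join(str(b.start - f.start) for b in f.blocks)
        rows.append(
            (f.chrom, f.start, f.end, f.read_id, int(f.is_unique), f.strand,
             f.start, f.end, "0,0,0", len(f.blocks), sizes, starts)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _blocks_from_cigar(chrom: str, pos: int, cigartuples, strand: str):
    """CIGAR walk: M(0)/=(7)/X(8)/D(2) extend the block, N(3) splits it."""
    blocks = []
    block_start = pos
    cursor = pos
    for op, length in cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            cursor += length
        elif op == 3:  # N: intron gap
            if cursor > block_start:
                blocks.append(GenomicInterval(chrom, block_start, cursor, strand))
            cursor += length
            block_start = cursor
        # I, S, H, P consume no reference
    if cursor > block_start:
        blocks.append(GenomicInterval(chrom, block_start, cursor, strand))
    return tuple(blocks)


def read_sam(path: str | Path) -> list[AlignedFragment]:
    """Read fragments from SAM/BAM: primary alignments, read 1 of a pair."""
    fragments = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_paired and read.is_read2:
                continue
            strand = "-" if read.is_reverse else "+"
            blocks = _blocks_from_cigar(
                read.reference_name, read.reference_start,
                read.cigartuples or [], strand,
            )
            if not blocks:
                continue
            nh = read.get_tag("NH") if read.has_tag("NH") else None
            is_unique = (nh == 1) if nh is not None else read.mapping_quality > 3
            fragments.append(
                AlignedFragment(
                    read_id=read.query_name,
                    chrom=read.reference_name,
                    blocks=blocks,
                    strand=strand,
                    is_unique=is_unique,
                )
            )
    return fragments


SAMPLE_SHEET_COLUMNS = [
    "sample_id", "tissue", "protocol", "replicate", "total_sequenced_reads",
]


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    """Sample sheet TSV with columns sample_id/tissue/protocol/replicate/
    total_sequenced_reads."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return [
        SampleInfo(
            sample_id=str(r.sample_id),
            tissue=str(r.tissue),
            protocol=str(r.protocol),
            replicate=int(r.replicate),
            total_sequenced_reads=int(r.total_sequenced_reads),
        )
        for r in df.itertuples(index=False)
    ]


def write_sample_sheet(samples: Sequence[SampleInfo], path: str | Path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.tissue, s.protocol, s.replicate, s.total_sequenced_reads)
         for s in samples],
        columns=SAMPLE_SHEET_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
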