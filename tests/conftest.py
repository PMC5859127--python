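"""Shared fixtures: a hand-checkable 3-gene GTF and random toy data makers."""
from __future__ import annotations

import numpy as np
import pytest

from libprep.annotation import (
    RawGeneRecord,
    build_gene_models,
    compute_overlap_flags,
)
from libprep.fragments import AlignedFragment
from libprep.intervals import GenomicInterval

# Three genes on chrT (1-based closed GTF coordinates):
#   GA protein_coding, 2 transcripts: exons 101-200, 301-400 and 151-250
#     -> union exons [100,250), [300,400); one intron [250,300)
#   GB lincRNA, single exon 1001-1600 (intron-less)
#   GC miRNA, single exon 261-290 -> sits inside GA's intron [250,300)
TOY_GTF = """\
chrT	toy	gene	101	400	.	+	.	gene_id "GA"; gene_type "protein_coding";
chrT	toy	transcript	101	400	.	+	.	gene_id "GA"; gene_type "protein_coding"; transcript_id "GA.1";
chrT	toy	exon	101	200	.	+	.	gene_id "GA"; gene_type "protein_coding"; transcript_id "GA.1";
chrT	toy	exon	301	400	.	+	.	gene_id "GA"; gene_type "protein_coding"; transcript_id "GA.1";
chrT	toy	transcript	151	250	.	+	.	gene_id "GA"; gene_type "protein_coding"; transcript_id "GA.2";
chrT	toy	exon	151	250	.	+	.	gene_id "GA"; gene_type "protein_coding"; transcript_id "GA.2";
chrT	toy	gene	1001	1600	.	-	.	gene_id "GB"; gene_type "lincRNA";
chrT	toy	transcript	1001	1600	.	-	.	gene_id "GB"; gene_type "lincRNA"; transcript_id "GB.1";
chrT	toy	exon	1001	1600	.	-	.	gene_id "GB"; gene_type "lincRNA"; transcript_id "GB.1";
chrT	toy	gene	261	290	.	+	.	gene_id "GC"; gene_type "miRNA";
chrT	toy	transcript	261	290	.	+	.	gene_id "GC"; gene_type "miRNA"; transcript_id "GC.1";
chrT	toy	exon	261	290	.	+	.	gene_id "GC"; gene_type "miRNA"; transcript_id "GC.1";
"""

# hand-parsed expectations for the fixture (0-based half-open)
TOY_EXPECT = {
    "GA": {"union": [(100, 250), (300, 400)], "introns": [(250, 300)],
           "exonic_length": 250, "category": "protein-coding",
           "overlaps": True},
    "GB": {"union": [(1000, 1600)], "introns": [], "exonic_length": 600,
           "category": "lncRNA", "overlaps": False},
    "GC": {"union": [(260, 290)], "introns": [], "exonic_length": 30,
           "category": "small RNA", "overlaps": True},
}


@pytest.fixture
def toy_gtf() -> str:
    return TOY_GTF


@pytest.fixture
def toy_models():
    from libprep.annotation import parse_gtf

    models, multi = compute_overlap_flags(build_gene_models(parse_gtf(TOY_GTF)))
    return models, multi


def make_fragment(chrom, blocks, read_id="r", strand="+", is_unique=True):
    return AlignedFragment(
        read_id=read_id,
        chrom=chrom,
        blocks=tuple(GenomicInterval(chrom, s, e, strand) for s, e in blocks),
        strand=strand,
        is_unique=is_unique,
    )


def random_toy_annotation(rng: np.random.Generator, n_genes: int = 20,
                          chrom_len: int = 100_000):
    """Random gene set that may overlap: 1-4 transcripts per gene, random
    exon structures, random strands. Returns (models, multi_regions,
    chrom_len)."""
    records = []
    biotypes = ["protein_coding", "lincRNA", "miRNA", "processed_pseudogene",
                "TR_J_gene"]
    for i in range(n_genes):
        gene_start = int(rng.integers(0, chrom_len - 5000))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        for _t in range(int(rng.integers(1, 5))):
            pos = gene_start + int(rng.integers(0, 200))
            for _e in range(int(rng.integers(1, 5))):
                elen = int(rng.integers(30, 400))
                end = min(pos + elen, chrom_len)
                if end > pos:
                    exons.append(GenomicInterval("chrR", pos, end, strand))
                pos = end + int(rng.integers(50, 1500))
                if pos >= chrom_len:
                    break
        if not exons:
            exons = [GenomicInterval("chrR", gene_start, gene_start + 100, strand)]
        records.append(RawGeneRecord(
            gene_id=f"G{i:03d}",
            gene_type=str(rng.choice(biotypes)),
            chrom="chrR", strand=strand, exons=exons,
        ))
    models, multi = compute_overlap_flags(build_gene_models(records))
    return models, multi, chrom_len


def random_fragments(rng: np.random.Generator, n: int, chrom_len: int,
                     chrom: str = "chrR"):
    """Random 1-2 block fragments scattered over the chromosome."""
    out = []
    for i in range(n):
        start = int(rng.integers(0, chrom_len - 600))
        strand = "+" if rng.random() < 0.5 else "-"
        spliced = rng.random() < 0.3
        if spliced:
            l1 = int(rng.integers(20, 60))
            gap = int(rng.integers(50, 3000))
            l2 = int(rng.integers(20, 60))
            b2_start = start + l1 + gap
            b2_end = min(b2_start + l2, chrom_len)
            if b2_end > b2_start:
                blocks = [(start, start + l1), (b2_start, b2_end)]
            else:
                blocks = [(start, start + l1)]
        else:
            blocks = [(start, start + int(rng.integers(30, 120)))]
        out.append(make_fragment(chrom, blocks, read_id=f"r{i:05d}",
                                 strand=strand,
                                 is_unique=bool(rng.random() > 0.05)))
    return out
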