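"""Gene models from a Gencode-dialect GTF.

Gene quantification here is union-exon based: every transcript's exons are
merged into one disjoint, sorted exon set per gene; the gaps inside the gene
span are the (derived) introns. The union exon set defines the gene's
quantification length, and the intron set feeds the intron-rate statistic.

Two overlap notions are computed and deliberately kept separate:

* ``overlaps_other_gene`` — span-vs-span, strand-blind by default; this is
  the *filter* used by the intron-rate analysis ("exclude a gene that
  overlaps any other gene").
* multi-gene exonic regions — genomic positions covered by union exons of
  two or more distinct genes; fragments touching these are *excluded from
  counting* (reads mapped to gene-overlapping regions are not assigned).
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .biotypes import classify_biotype
from .intervals import (
    GenomicInterval,
    complement_within,
    total_length,
    union_intervals,
)

logger = logging.getLogger(__name__)

KNOWN_FEATURES = {"gene", "transcript", "exon"}


class GtfParseError(ValueError):
    """Malformed GTF content; message carries the 1-based line number."""


class AnnotationError(ValueError):
    """Inconsistent gene structure (e.g. exons on mixed chromosomes)."""


@dataclass
class RawGeneRecord:
    """Per-gene bag of raw (unmerged) transcript exons from the GTF."""

    gene_id: str
    gene_type: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    gene_name: str = ""


@dataclass
class GeneModel:
    """A gene as the unit of quantification.

    ``union_exons`` and ``introns`` exactly tile ``span``; coordinates are
    0-based half-open.
    """

    gene_id: str
    gencode_biotype: str
    category: str
    chrom: str
    strand: str
    span: GenomicInterval
    union_exons: list[GenomicInterval]
    introns: list[GenomicInterval]
    exonic_length_bp: int
    n_introns: int
    total_intron_length_bp: int
    overlaps_other_gene: bool = False
    gene_name: str = ""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str, line_no: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if not attrs:
        raise GtfParseError(
            f"line {line_no}: cannot parse attribute block {attr_field!r}"
        )
    return attrs


def parse_gtf(source: str | Path) -> list[RawGeneRecord]:
    """Parse a GTF file (or GTF text) into raw per-gene exon records.

    GTF coordinates are 1-based closed and converted here to the internal
    0-based half-open convention. ``gene``/``transcript`` lines contribute
    only attributes; exon lines contribute intervals. Unknown feature types
    are skipped (logged at debug level). Input line order does not affect
    the result: records are returned sorted by gene_id with exons sorted by
    coordinate.
    """
    if isinstance(source, Path) or (
        "\n" not in str(source) and Path(str(source)).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)

    records: dict[str, RawGeneRecord] = {}
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"line {line_no}: expected 9 tab-separated fields, got {len(fields)}"
            )
        _, _, feature, start_s, end_s, _, strand, _, attr_field = fields
        if feature not in KNOWN_FEATURES:
            logger.debug("line %d: skipping feature type %r", line_no, feature)
            continue
        chrom = fields[0]
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise GtfParseError(f"line {line_no}: non-integer coordinates") from exc
        if end1 < start1:
            raise GtfParseError(
                f"line {line_no}: end ({end1}) < start ({start1})"
            )
        attrs = _parse_attributes(attr_field, line_no)
        if "gene_id" not in attrs:
            raise GtfParseError(f"line {line_no}: missing gene_id attribute")
        gene_id = attrs["gene_id"]
        rec = records.get(gene_id)
        if rec is None:
            rec = RawGeneRecord(
                gene_id=gene_id,
                gene_type=attrs.get("gene_type", ""),
                chrom=chrom,
                strand=strand,
                gene_name=attrs.get("gene_name", ""),
            )
            records[gene_id] = rec
        if not rec.gene_type and attrs.get("gene_type"):
            rec.gene_type = attrs["gene_type"]
        if not rec.gene_name and attrs.get("gene_name"):
            rec.gene_name = attrs["gene_name"]
        if feature == "exon":
            # GTF 1-based closed -> 0-based half-open
            rec.exons.append(GenomicInterval(chrom, start1 - 1, end1, strand))
    for rec in records.values():
        rec.exons.sort(key=lambda iv: (iv.start, iv.end))
    return [records[g] for g in sorted(records)]


def build_gene_models(
    raw_records: Iterable[RawGeneRecord],
    biotype_table: dict[str, str] | None = None,
) -> list[GeneModel]:
    """Collapse raw transcript exons into union-exon gene models.

    Raises :class:`AnnotationError` naming the gene if its exons sit on
    mixed chromosomes or strands, or if a record has no exons.
    """
    models = []
    for rec in raw_records:
        if not rec.exons:
            raise AnnotationError(f"gene {rec.gene_id}: no exons")
        chroms = {e.chrom for e in rec.exons}
        strands = {e.strand for e in rec.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"gene {rec.gene_id}: exons on mixed chromosomes/strands "
                f"({sorted(chroms)}, {sorted(strands)})"
            )
        union = union_intervals(rec.exons, strand=rec.strand)
        span = GenomicInterval(
            rec.chrom, union[0].start, union[-1].end, rec.strand
        )
        introns = complement_within(span, union)
        models.append(
            GeneModel(
                gene_id=rec.gene_id,
                gencode_biotype=rec.gene_type,
                category=classify_biotype(rec.gene_type, biotype_table),
                chrom=rec.chrom,
                strand=rec.strand,
                span=span,
                union_exons=union,
                introns=introns,
                exonic_length_bp=total_length(union),
                n_introns=len(introns),
                total_intron_length_bp=total_length(introns),
                gene_name=rec.gene_name,
            )
        )
    return models


def compute_overlap_flags(
    models: Sequence[GeneModel],
    mode: str = "span",
    stranded: bool = False,
) -> tuple[list[GeneModel], dict[str, list[GenomicInterval]]]:
    """Set ``overlaps_other_gene`` and derive multi-gene exonic regions.

    ``mode`` selects whether the gene-overlap *filter* flag compares spans
    (default, the conservative reading) or union exons. The multi-gene
    exonic regions — positions covered by union exons of >=2 distinct genes —
    are always exon-based and are what the counting exclusion uses.
    Strand-blind unless ``stranded``.
    """
    if mode not in ("span", "exon"):
        raise ValueError(f"unknown overlap mode {mode!r}")

    flagged = [replace(m) for m in models]

    def keys(m: GeneModel):
        return (m.chrom, m.strand) if stranded else (m.chrom,)

    # pairwise flag via per-chromosome sweep over the chosen feature set
    by_chrom: dict[tuple, list[tuple[int, int, int]]] = {}
    for idx, m in enumerate(flagged):
        feats = [m.span] if mode == "span" else m.union_exons
        for iv in feats:
            by_chrom.setdefault(keys(m), []).append((iv.start, iv.end, idx))
    for ivs in by_chrom.values():
        ivs.sort()
        active: list[tuple[int, int, int]] = []  # (end, start, idx)
        for start, end, idx in ivs:
            active = [a for a in active if a[0] > start]
            for a_end, _a_start, a_idx in active:
                if a_idx != idx:
                    flagged[idx].overlaps_other_gene = True
                    flagged[a_idx].overlaps_other_gene = True
            active.append((end, start, idx))

    # multi-gene exonic regions: coverage >= 2 sweep over union exons
    multi: dict[str, list[GenomicInterval]] = {}
    exons_by_chrom: dict[tuple, list[tuple[int, int]]] = {}
    for m in flagged:
        for iv in m.union_exons:
            exons_by_chrom.setdefault(keys(m), []).append((iv.start, iv.end))
    for key, ivs in exons_by_chrom.items():
        chrom = key[0]
        events: list[tuple[int, int]] = []
        for s, e in ivs:
            events.append((s, +1))
            events.append((e, -1))
        events.sort()
        depth = 0
        region_start = None
        out = multi.setdefault(chrom, [])
        for pos, delta in events:
            new_depth = depth + delta
            if depth < 2 <= new_depth:
                region_start = pos
            elif new_depth < 2 <= depth and region_start is not None:
                if pos > region_start:
                    out.append(GenomicInterval(chrom, region_start, pos))
                region_start = None
            depth = new_depth
    # merge adjacent pieces per chromosome
    multi = {
        chrom: union_intervals(ivs) if ivs else []
        for chrom, ivs in multi.items()
    }
    return flagged, multi


def load_gene_models(
    gtf: str | Path,
    biotype_table: dict[str, str] | None = None,
    overlap_mode: str = "span",
    stranded_overlap: bool = False,
) -> tuple[list[GeneModel], dict[str, list[GenomicInterval]]]:
    """Convenience: parse_gtf -> build_gene_models -> compute_overlap_flags."""
    records = parse_gtf(gtf)
    models = build_gene_models(records, biotype_table)
    return compute_overlap_flags(models, mode=overlap_mode, stranded=stranded_overlap)


def write_gene_models_bed12(models: Sequence[GeneModel], path: str | Path) -> None:
    """Dump gene models as BED12 (one row per gene, blocks = union exons)
    with a JSON sidecar carrying biotype/overlap metadata."""
    lines = []
    meta = {}
    for m in sorted(models, key=lambda m: (m.chrom, m.span.start, m.gene_id)):
        sizes = ",".join(str(iv.length) for iv in m.union_exons)
        starts = ",".join(str(iv.start - m.span.start) for iv in m.union_exons)
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    m.chrom,
                    m.span.start,
                    m.span.end,
                    m.gene_id,
                    0,
                    m.strand,
                    m.span.start,
                    m.span.end,
                    "0,0,0",
                    len(m.union_exons),
                    sizes,
                    starts,
                )
            )
        )
        meta[m.gene_id] = {
            "gencode_biotype": m.gencode_biotype,
            "category": m.category,
            "exonic_length_bp": m.exonic_length_bp,
            "n_introns": m.n_introns,
            "total_intron_length_bp": m.total_intron_length_bp,
            "overlaps_other_gene": m.overlaps_other_gene,
            "gene_name": m.gene_name,
        }
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1, sort_keys=True)
    )
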