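"""Synthetic two-protocol RNA-seq fragment generator with truth labels.

The generator emulates, on a toy chromosome, the read-provenance structure
that distinguishes polyA+ selection from rRNA depletion libraries:

* **mature** fragments drawn from a gene's spliced (union-exon) transcript —
  these are the usable, countable reads;
* **nascent** fragments drawn uniformly from the unspliced gene span
  (pre-mRNA), the dominant source of intronic reads in rRNA-depleted
  libraries;
* **intergenic** background.

Protocol differences are encoded as: a per-gene polyA capture probability
(polyA protocol only — polyA− genes such as replication-dependent histones
and small RNAs are invisible to oligo(dT) capture), and per-protocol
nascent/intergenic fractions (polyA-like ~0.06 nascent; rRNA-depletion-like
0.34–0.50 nascent).

The annotation contains the scenario genes the analysis is sensitive to:
multi-exon protein-coding genes, an intron-less polyA− histone-like gene, a
dominant unspliced lncRNA (MALAT1-like, a configurable share of counted
reads), a dominant free-standing small RNA (RN7SL-like), a 66 bp small RNA
nested in a host gene's intron, and a T-cell-receptor-like constant gene
whose long intron hosts several 60 bp J segments — the geometry that makes
nested small genes soak up host pre-mRNA reads and overestimates their
expression under rRNA depletion.

``abundance_profile`` entries are expected shares of *counted* reads.
Because nascent fragments are mostly never counted, gene draw weights are
rescaled by each gene's counting probability
``(1 - f) + f * kappa_g`` (``f`` = nascent fraction, ``kappa_g`` = the
exactly computed probability that a nascent fragment of the gene is
exonic-assigned to it), so that configured shares are recovered in
expectation by the pipeline.

Every fragment carries a :class:`TruthLabel`, enabling parameter-recovery
tests without external data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    RawGeneRecord,
    build_gene_models,
    compute_overlap_flags,
)
from .biotypes import LNCRNA, PROTEIN_CODING, PSEUDOGENE, SMALL_RNA, TCR_BCR
from .counting import DEFAULT_MIN_OVERLAP
from .fragments import AlignedFragment, SampleInfo
from .intervals import GenomicInterval

PROVENANCES = ("mature_exonic", "nascent_intronic", "nascent_exonic", "intergenic")

#: preset (nascent_fraction, intergenic_fraction) per tissue x protocol;
#: nascent_fraction is conditional on a fragment being genic
PRESET_MIXTURES = {
    ("blood", "polyA"): (0.06, 0.23),
    ("blood", "riboZ"): (0.50, 0.28),
    ("colon", "polyA"): (0.06, 0.24),
    ("colon", "riboZ"): (0.34, 0.20),
}


@dataclass
class AnnotationConfig:
    """Layout of the toy chromosome. Lengths in bp."""

    chrom: str = "chrS"
    n_coding: int = 12
    n_lnc: int = 2
    n_pseudo: int = 2
    n_j_genes: int = 6
    exon_length: tuple[int, int] = (120, 200)
    n_exons: tuple[int, int] = (4, 8)
    intron_length: tuple[int, int] = (8000, 16000)
    gap_length: tuple[int, int] = (4000, 12000)
    nested_small_rna_length: int = 66
    j_gene_length: int = 60

    def __post_init__(self) -> None:
        if self.n_coding < 2:
            raise ValueError("need at least 2 protein-coding genes (one hosts "
                             "the nested small RNA, one is globin-like)")
        for lo, hi in (self.exon_length, self.n_exons, self.intron_length,
                       self.gap_length):
            if not (0 < lo <= hi):
                raise ValueError("invalid range in AnnotationConfig")


@dataclass
class SyntheticAnnotation:
    """A generated annotation: GTF text plus the expected gene models."""

    chrom: str
    chrom_length: int
    gtf_text: str
    models: list[GeneModel]
    multi_regions: dict[str, list[GenomicInterval]]
    roles: dict[str, list[str]]
    gaps: list[GenomicInterval] = field(default_factory=list)

    def model_map(self) -> dict[str, GeneModel]:
        return {m.gene_id: m for m in self.models}


def _gene_record(gene_id, gene_type, chrom, strand, exon_coords, gene_name=""):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    return RawGeneRecord(gene_id=gene_id, gene_type=gene_type, chrom=chrom,
                         strand=strand, exons=exons, gene_name=gene_name)


def generate_annotation(
    config: AnnotationConfig | None = None, seed: int = 0
) -> SyntheticAnnotation:
    """Lay out the toy chromosome deterministically for a seed.

    Gene structure (exon counts, exon/intron/gap lengths) is drawn from the
    config ranges; scenario genes are always present. The returned models
    round-trip exactly through the GTF text and the annotation pipeline.
    """
    config = config or AnnotationConfig()
    rng = np.random.default_rng(seed)
    chrom = config.chrom
    records: list[RawGeneRecord] = []
    roles: dict[str, list[str]] = {}
    cursor = int(rng.integers(*config.gap_length))

    def role(name: str, gene_id: str) -> None:
        roles.setdefault(name, []).append(gene_id)

    def gap() -> int:
        return int(rng.integers(config.gap_length[0], config.gap_length[1] + 1))

    def strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    def spliced_exons(start, n_ex, exon_rng, intron_rng):
        coords = []
        pos = start
        for i in range(n_ex):
            e = int(rng.integers(exon_rng[0], exon_rng[1] + 1))
            coords.append((pos, pos + e))
            pos += e
            if i < n_ex - 1:
                pos += int(rng.integers(intron_rng[0], intron_rng[1] + 1))
        return coords, pos

    # multi-exon protein-coding genes; the first hosts the nested small RNA,
    # the second is the compact globin-like gene
    nested_host_intron: GenomicInterval | None = None
    for i in range(config.n_coding):
        gid = f"PC{i + 1:03d}"
        st = strand()
        if i == 1:  # globin-like: compact, 3 short exons, tiny introns
            coords, end = spliced_exons(cursor, 3, (150, 250), (120, 200))
            records.append(_gene_record(gid, "protein_coding", chrom, st, coords,
                                        gene_name="globin-like"))
            role("globin_like", gid)
        else:
            n_ex = int(rng.integers(config.n_exons[0], config.n_exons[1] + 1))
            coords, end = spliced_exons(
                cursor, n_ex, config.exon_length, config.intron_length
            )
            records.append(_gene_record(gid, "protein_coding", chrom, st, coords))
            if i == 0:
                # remember the middle intron for the nested small RNA
                mid = len(coords) // 2 - 1
                nested_host_intron = GenomicInterval(
                    chrom, coords[mid][1], coords[mid + 1][0], st
                )
                role("nested_host", gid)
        role("coding", gid)
        cursor = end + gap()

    # intron-less polyA− histone-like protein-coding gene
    hist_len = 500
    records.append(_gene_record("HISTL1", "protein_coding", chrom, strand(),
                                [(cursor, cursor + hist_len)],
                                gene_name="histone-like"))
    role("histone_like", "HISTL1")
    cursor += hist_len + gap()

    # dominant unspliced lncRNA (MALAT1-like): one long exon, no introns
    lncd_len = 8000
    records.append(_gene_record("LNCD1", "lincRNA", chrom, strand(),
                                [(cursor, cursor + lncd_len)],
                                gene_name="dominant-lncRNA"))
    role("dominant_lncRNA", "LNCD1")
    cursor += lncd_len + gap()

    # spliced lncRNAs
    for i in range(config.n_lnc):
        gid = f"LNC{i + 1:03d}"
        coords, end = spliced_exons(cursor, 3, (150, 250), (8000, 12000))
        records.append(_gene_record(gid, "lincRNA", chrom, strand(), coords))
        role("lncRNA", gid)
        cursor = end + gap()

    # processed pseudogenes: single exon
    for i in range(config.n_pseudo):
        gid = f"PSG{i + 1:03d}"
        plen = int(rng.integers(800, 2000))
        records.append(_gene_record(gid, "processed_pseudogene", chrom, strand(),
                                    [(cursor, cursor + plen)]))
        role("pseudogene", gid)
        cursor += plen + gap()

    # dominant free-standing small RNA (RN7SL-like) and a free snoRNA
    records.append(_gene_record("SRNAD1", "misc_RNA", chrom, strand(),
                                [(cursor, cursor + 300)],
                                gene_name="dominant-smallRNA"))
    role("dominant_small_rna", "SRNAD1")
    cursor += 300 + gap()
    records.append(_gene_record("SNO001", "snoRNA", chrom, strand(),
                                [(cursor, cursor + 150)]))
    role("small_rna_free", "SNO001")
    cursor += 150 + gap()

    # nested small RNA inside the host gene's intron
    assert nested_host_intron is not None
    m_len = config.nested_small_rna_length
    m_start = nested_host_intron.start + (nested_host_intron.length - m_len) // 2
    records.append(_gene_record("MIRN1", "miRNA", chrom, nested_host_intron.strand,
                                [(m_start, m_start + m_len)],
                                gene_name="nested-miRNA"))
    role("nested_small_rna", "MIRN1")

    # TCR-like constant gene with J segments in its long intron
    trc_st = strand()
    e1, e2, trc_intron = 300, 400, 25000
    trc_coords = [(cursor, cursor + e1),
                  (cursor + e1 + trc_intron, cursor + e1 + trc_intron + e2)]
    records.append(_gene_record("TRC001", "TR_C_gene", chrom, trc_st, trc_coords,
                                gene_name="constant-like"))
    role("tcr_constant", "TRC001")
    j_spacing = trc_intron // (config.n_j_genes + 1)
    for j in range(config.n_j_genes):
        gid = f"TRJ{j + 1:03d}"
        j_start = cursor + e1 + (j + 1) * j_spacing
        records.append(_gene_record(gid, "TR_J_gene", chrom, trc_st,
                                    [(j_start, j_start + config.j_gene_length)]))
        role("j_gene", gid)
    cursor = trc_coords[1][1] + gap()

    chrom_length = cursor + gap()

    models, multi = compute_overlap_flags(build_gene_models(records))

    # intergenic gaps (complement of gene spans, trimmed of zero-length)
    spans = sorted((m.span.start, m.span.end) for m in models)
    gaps: list[GenomicInterval] = []
    prev = 0
    for s, e in spans:
        if s > prev:
            gaps.append(GenomicInterval(chrom, prev, s))
        prev = max(prev, e)
    if prev < chrom_length:
        gaps.append(GenomicInterval(chrom, prev, chrom_length))

    gtf_text = _records_to_gtf(records)
    return SyntheticAnnotation(
        chrom=chrom, chrom_length=chrom_length, gtf_text=gtf_text,
        models=models, multi_regions=multi, roles=roles, gaps=gaps,
    )


def _records_to_gtf(records: Sequence[RawGeneRecord]) -> str:
    lines = []
    for rec in records:
        start1 = min(e.start for e in rec.exons) + 1
        end1 = max(e.end for e in rec.exons)
        attrs = f'gene_id "{rec.gene_id}"; gene_type "{rec.gene_type}";'
        if rec.gene_name:
            attrs += f' gene_name "{rec.gene_name}";'
        lines.append("\t".join([rec.chrom, "synthetic", "gene", str(start1),
                                str(end1), ".", rec.strand, ".", attrs]))
        tx_attrs = attrs + f' transcript_id "{rec.gene_id}.t1";'
        lines.append("\t".join([rec.chrom, "synthetic", "transcript", str(start1),
                                str(end1), ".", rec.strand, ".", tx_attrs]))
        for k, ex in enumerate(rec.exons, start=1):
            ex_attrs = tx_attrs + f' exon_number "{k}";'
            lines.append("\t".join([rec.chrom, "synthetic", "exon",
                                    str(ex.start + 1), str(ex.end), ".",
                                    rec.strand, ".", ex_attrs]))
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class TruthLabel:
    """Ground-truth provenance of one generated fragment."""

    fragment_id: str
    source_gene: str  # "" for intergenic
    provenance: str  # mature_exonic | nascent_intronic | nascent_exonic | intergenic
    category: str  # biotype category of the source gene ("" for intergenic)


@dataclass
class ProtocolSimConfig:
    """Knobs of one simulated library.

    ``nascent_fraction`` is the probability that a *genic* fragment is
    pre-mRNA (drawn uniformly from the gene span); ``intergenic_fraction``
    is the unconditional probability of intergenic background.
    ``abundance_profile`` maps gene_id -> expected share of counted reads
    (genes absent from the map are not transcribed); ``polya_capture`` maps
    gene_id -> capture probability, applied only under the polyA protocol.
    """

    n_fragments: int = 100_000
    nascent_fraction: float = 0.06
    intergenic_fraction: float = 0.05
    polya_capture: dict[str, float] = field(default_factory=dict)
    abundance_profile: dict[str, float] = field(default_factory=dict)
    fragment_length_bp: int = 75
    multimapped_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nascent_fraction", "intergenic_fraction",
                     "multimapped_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_fragments < 0 or self.fragment_length_bp <= 0:
            raise ValueError("n_fragments/fragment_length_bp must be positive")
        total = sum(self.abundance_profile.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"abundance shares sum to {total} > 1")
        for g, p in self.polya_capture.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"polya_capture[{g!r}] = {p} not a probability")


#: category-level default polyA capture probabilities
DEFAULT_CAPTURE_BY_CATEGORY = {
    PROTEIN_CODING: 1.0,
    LNCRNA: 0.6,
    PSEUDOGENE: 0.8,
    SMALL_RNA: 0.0,  # not polyadenylated and removed by size selection
    TCR_BCR: 1.0,
}


def default_polya_capture(annotation: SyntheticAnnotation) -> dict[str, float]:
    """Per-gene capture probabilities: category defaults plus the scenario
    overrides (polyA− histone-like gene 0, mostly-uncaptured dominant
    lncRNA 0.05, J segments 0)."""
    capture = {
        m.gene_id: DEFAULT_CAPTURE_BY_CATEGORY.get(m.category, 0.0)
        for m in annotation.models
    }
    for gid in annotation.roles.get("histone_like", []):
        capture[gid] = 0.0
    for gid in annotation.roles.get("dominant_lncRNA", []):
        capture[gid] = 0.05
    for gid in annotation.roles.get("j_gene", []):
        capture[gid] = 0.0
    return capture


def default_abundance(
    annotation: SyntheticAnnotation,
    seed: int = 0,
    tissue: str = "blood",
    dominant_lncrna_share: float = 0.027,
    dominant_small_rna_share: float = 0.027,
) -> dict[str, float]:
    """Counted-read shares: the two dominant genes get their configured
    shares; nested small RNAs and J segments are truly silent (share 0, so
    any reads they accrue are the overlap artifact); the rest is spread
    over coding genes (log-normal), lncRNAs and pseudogenes. The blood
    preset gives the globin-like gene a large share."""
    rng = np.random.default_rng(seed)
    roles = annotation.roles
    shares: dict[str, float] = {}
    shares[roles["dominant_lncRNA"][0]] = dominant_lncrna_share
    shares[roles["dominant_small_rna"][0]] = dominant_small_rna_share
    globin = roles["globin_like"][0]
    shares[globin] = 0.15 if tissue == "blood" else 0.01
    shares[roles["histone_like"][0]] = 0.008
    shares[roles["small_rna_free"][0]] = 0.003
    shares[roles["tcr_constant"][0]] = 0.01
    for gid in roles.get("lncRNA", []):
        shares[gid] = 0.006
    for gid in roles.get("pseudogene", []):
        shares[gid] = 0.004
    coding = [g for g in roles["coding"] if g != globin]
    weights = rng.lognormal(mean=0.0, sigma=0.8, size=len(coding))
    remaining = 1.0 - sum(shares.values())
    for gid, w in zip(coding, weights):
        shares[gid] = remaining * w / weights.sum()
    # nested small RNA and J genes: configured share 0 (absent from map)
    return shares


def preset_config(
    tissue: str,
    protocol: str,
    annotation: SyntheticAnnotation,
    n_fragments: int = 100_000,
    seed: int = 0,
) -> ProtocolSimConfig:
    """Blood-like / colon-like preset for either protocol."""
    try:
        nascent, intergenic = PRESET_MIXTURES[(tissue, protocol)]
    except KeyError:
        raise ValueError(f"no preset for tissue={tissue!r}, protocol={protocol!r}")
    return ProtocolSimConfig(
        n_fragments=n_fragments,
        nascent_fraction=nascent,
        intergenic_fraction=intergenic,
        polya_capture=default_polya_capture(annotation),
        abundance_profile=default_abundance(annotation, seed=seed, tissue=tissue),
        seed=seed,
    )


def assignable_fraction(
    model: GeneModel, fragment_length: int, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> float:
    """Probability that a nascent (uniform-start, single-block) fragment of
    this gene overlaps its own union exons by >= min_overlap bp — i.e. would
    be exonic-assigned, considering the source gene alone."""
    L = fragment_length
    span = model.span
    if span.length <= L:
        return 1.0 if model.exonic_length_bp >= min(min_overlap, span.length) else 0.0
    starts = np.arange(span.start, span.end - L + 1)
    total = np.zeros(len(starts), dtype=np.int64)
    for ex in model.union_exons:
        ov = np.clip(
            np.minimum(starts + L, ex.end) - np.maximum(starts, ex.start), 0, None
        )
        total += ov
    return float(np.mean(total >= min_overlap))


def _mature_blocks(model: GeneModel, t: int, L: int) -> tuple[GenomicInterval, ...]:
    """Map a spliced-transcript offset t to genomic blocks of length L."""
    blocks = []
    remaining = L
    offset = t
    for ex in model.union_exons:
        if offset >= ex.length:
            offset -= ex.length
            continue
        take = min(remaining, ex.length - offset)
        blocks.append(GenomicInterval(model.chrom, ex.start + offset,
                                      ex.start + offset + take, model.strand))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    return tuple(blocks)


def simulate_fragments(
    annotation: SyntheticAnnotation,
    protocol: str,
    config: ProtocolSimConfig,
    seed: int | None = None,
    fragment_prefix: str = "f",
) -> tuple[list[AlignedFragment], list[TruthLabel]]:
    """Draw one library of labelled fragments. Reproducible for a seed."""
    if protocol not in ("polyA", "riboZ"):
        raise ValueError(f"unknown protocol {protocol!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L = config.fragment_length_bp
    models = annotation.model_map()
    f = config.nascent_fraction

    gene_ids = sorted(g for g, s in config.abundance_profile.items() if s > 0)
    if not gene_ids and config.intergenic_fraction < 1.0:
        raise ValueError("abundance_profile has no transcribed genes")
    shares = np.array([config.abundance_profile[g] for g in gene_ids])
    if protocol == "polyA":
        capture = np.array([config.polya_capture.get(g, 1.0) for g in gene_ids])
        shares = shares * capture
        if shares.sum() == 0 and config.intergenic_fraction < 1.0:
            raise ValueError("polyA capture removed every transcribed gene")
    kappa = np.array(
        [assignable_fraction(models[g], L) for g in gene_ids]
    )
    p_counted = (1.0 - f) + f * kappa
    weights = shares / p_counted
    wsum = weights.sum()

    gaps = [g for g in annotation.gaps if g.length >= L]
    gap_weights = np.array([g.length - L + 1 for g in gaps], dtype=float)
    gap_weights = gap_weights / gap_weights.sum()

    n = config.n_fragments
    is_intergenic = rng.random(n) < config.intergenic_fraction
    gene_choice = (
        rng.choice(len(gene_ids), size=n, p=weights / wsum) if wsum > 0
        else np.zeros(n, dtype=int)
    )
    is_nascent = rng.random(n) < f
    is_multi = rng.random(n) < config.multimapped_fraction

    # precompute per-gene exon arrays for the nascent intron/exon label
    exon_arrays = {
        g: np.array([(e.start, e.end) for e in models[g].union_exons])
        for g in gene_ids
    }

    fragments: list[AlignedFragment] = []
    labels: list[TruthLabel] = []
    for i in range(n):
        fid = f"{fragment_prefix}{i:07d}"
        if is_intergenic[i] or wsum == 0:
            gi = rng.choice(len(gaps), p=gap_weights)
            gap = gaps[gi]
            s = int(rng.integers(gap.start, gap.end - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            blocks = (GenomicInterval(annotation.chrom, s, s + L, strand),)
            gene, prov, cat = "", "intergenic", ""
        else:
            gene = gene_ids[gene_choice[i]]
            m = models[gene]
            cat = m.category
            strand = m.strand
            if is_nascent[i]:
                span = m.span
                if span.length <= L:
                    s, e = span.start, span.end
                else:
                    s = int(rng.integers(span.start, span.end - L + 1))
                    e = s + L
                blocks = (GenomicInterval(m.chrom, s, e, strand),)
                ex = exon_arrays[gene]
                touches_exon = bool(np.any((ex[:, 0] < e) & (ex[:, 1] > s)))
                prov = "nascent_exonic" if touches_exon else "nascent_intronic"
            else:
                mlen = m.exonic_length_bp
                if mlen <= L:
                    blocks = tuple(m.union_exons)
                else:
                    t = int(rng.integers(0, mlen - L + 1))
                    blocks = _mature_blocks(m, t, L)
                prov = "mature_exonic"
        fragments.append(
            AlignedFragment(read_id=fid, chrom=annotation.chrom, blocks=blocks,
                            strand=strand, is_unique=not is_multi[i])
        )
        labels.append(TruthLabel(fragment_id=fid, source_gene=gene,
                                 provenance=prov, category=cat))
    return fragments, labels


@dataclass
class TruthSummary:
    """Exact tallies over truth labels; the recovery targets."""

    n_fragments: int
    fragment_shares: pd.Series  # per source gene, over all fragments
    mature_shares: pd.Series  # per source gene, over mature fragments
    true_intronic_fraction: float
    true_intergenic_fraction: float
    detected_genes: frozenset[str]
    provenance_counts: pd.Series


def truth_summaries(labels: Sequence[TruthLabel]) -> TruthSummary:
    df = pd.DataFrame(
        {
            "source_gene": [l.source_gene for l in labels],
            "provenance": [l.provenance for l in labels],
        }
    )
    n = len(df)
    genic = df[df.source_gene != ""]
    mature = genic[genic.provenance == "mature_exonic"]
    prov_counts = df.provenance.value_counts().reindex(PROVENANCES).fillna(0)
    return TruthSummary(
        n_fragments=n,
        fragment_shares=genic.source_gene.value_counts() / n,
        mature_shares=(
            mature.source_gene.value_counts() / len(mature)
            if len(mature) else pd.Series(dtype=float)
        ),
        true_intronic_fraction=float((df.provenance == "nascent_intronic").mean()),
        true_intergenic_fraction=float((df.provenance == "intergenic").mean()),
        detected_genes=frozenset(genic.source_gene.unique()),
        provenance_counts=prov_counts.astype(int),
    )


def sample_info_for(
    sample_id: str, tissue: str, protocol: str, replicate: int,
    config: ProtocolSimConfig,
) -> SampleInfo:
    """SampleInfo for a simulated library (every fragment is sequenced)."""
    return SampleInfo(
        sample_id=sample_id, tissue=tissue, protocol=protocol,
        replicate=replicate, total_sequenced_reads=config.n_fragments,
    )
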