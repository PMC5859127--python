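"""Fragment classification and gene assignment.

Two deliberately different overlap rules coexist, mirroring how QC
summaries and gene counts are produced in practice:

* **classification** (:func:`classify_read_region`) — a fragment is exonic
  if any block overlaps any gene's union exon by >= 1 bp; else intronic if
  it touches any intron; else intergenic. This feeds the per-sample
  read-category summary and the exonic-read percentage.
* **assignment** (:func:`assign_fragment_to_gene`) — featureCounts-style:
  a fragment is counted for gene G only if its blocks overlap G's union
  exons by at least ``min_overlap`` bp in total (default 25), no overlapped
  base lies in a multi-gene exonic region, and no second gene also reaches
  ``min_overlap`` (else ambiguous, counted for nobody). Fragments that fail
  exonic assignment but touch introns are tallied as intronic for the gene
  with the largest intronic overlap (ties broken by gene_id) — the input to
  the per-gene intron-rate statistic.

Only uniquely mapped fragments are counted; multi-mapped fragments are
dropped before classification. Both rules are strand-blind by default; a
``stranded`` switch restricts all overlaps to same-strand features.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel
from .fragments import AlignedFragment, SampleInfo
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 25

#: read-category labels for the per-sample summary
CATEGORIES = ("exonic", "intronic", "intergenic")


class GenomeIndex:
    """Interval-tree index over union exons, introns and multi-gene exonic
    regions, keyed per chromosome (or per chromosome+strand if stranded)."""

    def __init__(
        self,
        models: Sequence[GeneModel],
        multi_regions: Mapping[str, Sequence[GenomicInterval]] | None = None,
        stranded: bool = False,
    ):
        self.models = {m.gene_id: m for m in models}
        self.stranded = stranded
        self.exon_trees: dict = {}
        self.intron_trees: dict = {}
        self.multi_trees: dict = {}
        for m in models:
            for iv in m.union_exons:
                self._tree(self.exon_trees, m.chrom, m.strand).addi(
                    iv.start, iv.end, m.gene_id
                )
            for iv in m.introns:
                self._tree(self.intron_trees, m.chrom, m.strand).addi(
                    iv.start, iv.end, m.gene_id
                )
        if multi_regions:
            for chrom, ivs in multi_regions.items():
                for iv in ivs:
                    # multi-gene regions are strand-collapsed by construction
                    for strand in ("+", "-", "."):
                        self._tree(self.multi_trees, chrom, strand).addi(
                            iv.start, iv.end, None
                        )
        self.known_chroms = {m.chrom for m in models}

    def _key(self, chrom: str, strand: str):
        return (chrom, strand) if self.stranded else chrom

    def _tree(self, trees: dict, chrom: str, strand: str) -> IntervalTree:
        key = self._key(chrom, strand)
        if key not in trees:
            trees[key] = IntervalTree()
        return trees[key]

    def _query(self, trees: dict, fragment: AlignedFragment):
        key = self._key(fragment.chrom, fragment.strand)
        tree = trees.get(key)
        if tree is None:
            return ()
        hits = []
        for b in fragment.blocks:
            for iv in tree.overlap(b.start, b.end):
                ov = min(b.end, iv.end) - max(b.start, iv.begin)
                hits.append((iv.data, ov))
        return hits

    def exon_overlaps(self, fragment: AlignedFragment) -> dict[str, int]:
        """Total per-gene bp overlap of the fragment's blocks with union exons."""
        out: dict[str, int] = {}
        for gene_id, ov in self._query(self.exon_trees, fragment):
            out[gene_id] = out.get(gene_id, 0) + ov
        return out

    def intron_overlaps(self, fragment: AlignedFragment) -> dict[str, int]:
        out: dict[str, int] = {}
        for gene_id, ov in self._query(self.intron_trees, fragment):
            out[gene_id] = out.get(gene_id, 0) + ov
        return out

    def touches_multi_region(self, fragment: AlignedFragment) -> bool:
        key = self._key(fragment.chrom, fragment.strand)
        # multi trees were populated for every strand
        tree = self.multi_trees.get(key)
        if tree is None:
            return False
        return any(tree.overlap(b.start, b.end) for b in fragment.blocks)


def classify_read_region(
    fragment: AlignedFragment, index: GenomeIndex
) -> str:
    """Classify a unique fragment as exonic / intronic / intergenic (>=1 bp
    touch rule). Fragments on chromosomes absent from the annotation are
    intergenic (logged)."""
    if not fragment.is_unique:
        raise ValueError("classify_read_region expects uniquely mapped fragments")
    if fragment.chrom not in index.known_chroms:
        logger.debug("fragment %s on unknown chrom %s -> intergenic",
                     fragment.read_id, fragment.chrom)
        return "intergenic"
    if index.exon_overlaps(fragment):
        return "exonic"
    if index.intron_overlaps(fragment):
        return "intronic"
    return "intergenic"


def assign_fragment_to_gene(
    fragment: AlignedFragment,
    index: GenomeIndex,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[str, str | None]:
    """Assign a unique fragment under the counting rules.

    Returns one of ``("exonic", gene_id)``, ``("intronic", gene_id)``,
    ``("ambiguous", None)``, ``("unassigned_exonic", None)``,
    ``("intergenic", None)``.
    """
    if min_overlap <= 0:
        raise ValueError("min_overlap must be positive")
    if not fragment.is_unique:
        raise ValueError("assign_fragment_to_gene expects uniquely mapped fragments")
    exon_ov = index.exon_overlaps(fragment)
    candidates = [g for g, ov in exon_ov.items() if ov >= min_overlap]
    if candidates:
        if len(candidates) == 1 and not index.touches_multi_region(fragment):
            return "exonic", candidates[0]
        return "ambiguous", None
    intron_ov = index.intron_overlaps(fragment)
    if intron_ov:
        # deterministic: largest intronic overlap, ties -> lexicographic id
        best = min(intron_ov.items(), key=lambda kv: (-kv[1], kv[0]))
        return "intronic", best[0]
    if exon_ov:
        return "unassigned_exonic", None
    return "intergenic", None


@dataclass
class CountTable:
    """Per-gene exonic/intronic counts per sample plus per-sample totals.

    ``summary`` rows (one per sample): unique_fragments, exonic, intronic,
    intergenic (classification totals), assigned_exonic
    (= counted library size), assigned_intronic, ambiguous,
    unassigned_exonic, total_sequenced_reads.
    """

    exonic: pd.DataFrame
    intronic: pd.DataFrame
    summary: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.exonic.index

    @property
    def samples(self) -> pd.Index:
        return self.exonic.columns

    @property
    def counted_library_size(self) -> pd.Series:
        """Counted reads per sample = sum of exonic assigned counts."""
        return self.exonic.sum(axis=0)

    def exonic_read_percent(self) -> pd.Series:
        """Classification-based exonic reads as % of total sequenced reads."""
        return (
            self.summary["exonic"] / self.summary["total_sequenced_reads"] * 100.0
        )

    def usable_fraction(self) -> pd.Series:
        """Assigned (counted) reads / total sequenced reads per sample."""
        return self.counted_library_size / self.summary["total_sequenced_reads"]

    def to_tsv(self, outdir: str | Path, prefix: str = "counts") -> None:
        outdir = Path(outdir)
        self.exonic.to_csv(outdir / f"{prefix}_exonic.tsv", sep="\t")
        self.intronic.to_csv(outdir / f"{prefix}_intronic.tsv", sep="\t")
        self.summary.to_csv(outdir / f"{prefix}_summary.tsv", sep="\t")


def count_sample(
    fragments: Iterable[AlignedFragment],
    index: GenomeIndex,
    sample: SampleInfo,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[pd.Series, pd.Series, dict]:
    """Count one sample: exonic/intronic per-gene vectors + category totals.

    Multi-mapped fragments are dropped here. Result is independent of
    fragment order.
    """
    genes = sorted(index.models)
    exonic = dict.fromkeys(genes, 0)
    intronic = dict.fromkeys(genes, 0)
    totals = {
        "unique_fragments": 0, "exonic": 0, "intronic": 0, "intergenic": 0,
        "assigned_exonic": 0, "assigned_intronic": 0, "ambiguous": 0,
        "unassigned_exonic": 0,
    }
    n_seen = 0
    for frag in fragments:
        n_seen += 1
        if not frag.is_unique:
            continue
        totals["unique_fragments"] += 1
        totals[classify_read_region(frag, index)] += 1
        status, gene_id = assign_fragment_to_gene(frag, index, min_overlap)
        if status == "exonic":
            exonic[gene_id] += 1
            totals["assigned_exonic"] += 1
        elif status == "intronic":
            intronic[gene_id] += 1
            totals["assigned_intronic"] += 1
        elif status == "ambiguous":
            totals["ambiguous"] += 1
        elif status == "unassigned_exonic":
            totals["unassigned_exonic"] += 1
    if n_seen == 0:
        logger.warning("sample %s: empty fragment set", sample.sample_id)
    if sample.total_sequenced_reads < n_seen:
        raise ValueError(
            f"sample {sample.sample_id}: total_sequenced_reads "
            f"({sample.total_sequenced_reads}) < supplied fragments ({n_seen})"
        )
    totals["total_sequenced_reads"] = sample.total_sequenced_reads
    return (
        pd.Series(exonic, name=sample.sample_id),
        pd.Series(intronic, name=sample.sample_id),
        totals,
    )


def count_samples(
    fragment_sets: Mapping[str, Iterable[AlignedFragment]],
    index: GenomeIndex,
    samples: Sequence[SampleInfo],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> CountTable:
    """Count several samples into one :class:`CountTable`."""
    by_id = {s.sample_id: s for s in samples}
    exonic_cols, intronic_cols, summaries = [], [], {}
    for sample_id, frags in fragment_sets.items():
        ex, intr, totals = count_sample(
            frags, index, by_id[sample_id], min_overlap
        )
        exonic_cols.append(ex)
        intronic_cols.append(intr)
        summaries[sample_id] = totals
    return CountTable(
        exonic=pd.concat(exonic_cols, axis=1),
        intronic=pd.concat(intronic_cols, axis=1),
        summary=pd.DataFrame(summaries).T,
    )


def subsample_fragments(
    fragments: Sequence[AlignedFragment], n: int, seed: int
) -> list[AlignedFragment]:
    """Uniform subsample without replacement, reproducible for a seed and
    independent of input order (fragments are canonicalised by read_id)."""
    if n > len(fragments):
        raise ValueError(f"cannot sample {n} of {len(fragments)} fragments")
    ordered = sorted(fragments, key=lambda f: f.read_id)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ordered), size=n, replace=False)
    idx.sort()
    return [ordered[i] for i in idx]
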