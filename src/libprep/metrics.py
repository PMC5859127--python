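"""Summary statistics for the protocol comparison.

Everything downstream of the count table lives here: RPKM/CPM, merged
replicates, expressed-gene detection classes (Both / PolyA / RiboZ / None
at RPKM > 0.1), biotype breakdowns of genes and of counted reads,
usable-read fractions and the extra-depth requirement, sample correlation,
per-biotype concordance between protocols, and the per-gene intron-rate
analysis with its filters.

Library size for CPM/RPKM defaults to the per-sample *counted* reads
(sum of exonic assigned counts); callers can pass any other size vector
(e.g. uniquely mapped reads) — the choice is recorded in the result's
provenance field.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .biotypes import CATEGORIES
from .counting import CountTable

logger = logging.getLogger(__name__)

EXPRESSED_RPKM = 0.1
CORR_FILTER_RPKM = 0.5
INTRON_RATE_MIN_RPKM = 1.0

DETECTION_CLASSES = ("Both", "PolyA", "RiboZ", "None")


def compute_rpkm(
    counts: pd.DataFrame | pd.Series,
    exonic_length_bp: pd.Series,
    library_size: pd.Series | float,
) -> pd.DataFrame | pd.Series:
    """Reads per kilobase of (union-exon) transcript per million counted
    reads: ``count / (length/1e3) / (library/1e6)``."""
    if np.any(np.asarray(library_size) <= 0):
        raise ValueError("library_size must be > 0")
    if (exonic_length_bp <= 0).any():
        raise ValueError("exonic_length_bp must be > 0")
    lengths_kb = exonic_length_bp.loc[counts.index] / 1e3
    per_million = library_size / 1e6
    return counts.div(lengths_kb, axis=0) / per_million


def compute_cpm(
    counts: pd.DataFrame | pd.Series, library_size: pd.Series | float
) -> pd.DataFrame | pd.Series:
    """Counts per million: ``count / (library/1e6)``."""
    if np.any(np.asarray(library_size) <= 0):
        raise ValueError("library_size must be > 0")
    return counts / (library_size / 1e6)


@dataclass
class ExpressionMatrix:
    """RPKM and CPM per gene x sample, with the library-size provenance."""

    rpkm: pd.DataFrame
    cpm: pd.DataFrame
    library_size: pd.Series
    library_size_mode: str  # "counted" | "unique_mapped" | "custom"


def expression_from_counts(
    counts: pd.DataFrame,
    models: Mapping[str, GeneModel] | Sequence[GeneModel],
    library_size: pd.Series | None = None,
    library_size_mode: str = "counted",
) -> ExpressionMatrix:
    """Build RPKM/CPM from an exonic count matrix.

    With ``library_size=None`` the per-sample counted reads (column sums)
    are used.
    """
    if not isinstance(models, Mapping):
        models = {m.gene_id: m for m in models}
    lengths = pd.Series(
        {g: models[g].exonic_length_bp for g in counts.index}, name="length"
    )
    if library_size is None:
        library_size = counts.sum(axis=0)
        library_size_mode = "counted"
    return ExpressionMatrix(
        rpkm=compute_rpkm(counts, lengths, library_size),
        cpm=compute_cpm(counts, library_size),
        library_size=pd.Series(library_size),
        library_size_mode=library_size_mode,
    )


def merge_replicates(
    count_table: CountTable, groups: Mapping[str, Sequence[str]]
) -> CountTable:
    """Sum counts and library/category totals across replicates per group.

    Every sample must belong to exactly one group; groups must be non-empty.
    """
    seen: list[str] = []
    for name, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"group {name!r} has no samples")
        seen.extend(members)
    if len(seen) != len(set(seen)):
        raise ValueError("a sample appears in more than one group")
    missing = set(seen) - set(count_table.samples)
    if missing:
        raise ValueError(f"unknown samples in groups: {sorted(missing)}")
    exonic = pd.DataFrame(
        {g: count_table.exonic[list(m)].sum(axis=1) for g, m in groups.items()}
    )
    intronic = pd.DataFrame(
        {g: count_table.intronic[list(m)].sum(axis=1) for g, m in groups.items()}
    )
    summary = pd.DataFrame(
        {g: count_table.summary.loc[list(m)].sum(axis=0) for g, m in groups.items()}
    ).T
    return CountTable(exonic=exonic, intronic=intronic, summary=summary)


def detection_classes(
    rpkm_polya: pd.Series,
    rpkm_riboz: pd.Series,
    threshold: float = EXPRESSED_RPKM,
) -> pd.Series:
    """Partition genes into Both / PolyA / RiboZ / None by strict RPKM >
    threshold in the merged per-protocol samples."""
    if not rpkm_polya.index.equals(rpkm_riboz.index):
        rpkm_riboz = rpkm_riboz.reindex(rpkm_polya.index)
        if rpkm_riboz.isna().any():
            raise ValueError("gene universes differ between protocols")
    in_polya = rpkm_polya > threshold
    in_riboz = rpkm_riboz > threshold
    out = pd.Series("None", index=rpkm_polya.index, name="detection_class")
    out[in_polya & in_riboz] = "Both"
    out[in_polya & ~in_riboz] = "PolyA"
    out[~in_polya & in_riboz] = "RiboZ"
    return out


def biotype_gene_fractions(
    detection: pd.Series, categories: pd.Series
) -> pd.DataFrame:
    """Fraction of genes of each biotype within each detection class
    (five-way; 'other' genes are excluded and logged). Rows sum to 1."""
    cats = categories.loc[detection.index]
    other = (~cats.isin(CATEGORIES)).sum()
    if other:
        logger.info("excluding %d genes of category 'other' from breakdown", other)
    keep = cats.isin(CATEGORIES)
    tab = (
        pd.crosstab(detection[keep], cats[keep])
        .reindex(index=list(DETECTION_CLASSES), columns=list(CATEGORIES))
        .fillna(0)
    )
    totals = tab.sum(axis=1)
    return tab.div(totals.replace(0, np.nan), axis=0)


def biotype_expressed_gene_fractions(
    rpkm: pd.DataFrame, categories: pd.Series, threshold: float = EXPRESSED_RPKM
) -> pd.DataFrame:
    """Per sample: fraction of expressed genes (RPKM > threshold) in each
    biotype. Rows (samples) sum to 1 over the five categories."""
    cats = categories.loc[rpkm.index]
    keep = cats.isin(CATEGORIES)
    rows = {}
    for sample in rpkm.columns:
        expressed = rpkm.loc[keep, sample] > threshold
        counts = cats[keep][expressed].value_counts().reindex(CATEGORIES).fillna(0)
        total = counts.sum()
        rows[sample] = counts / total if total else counts
    return pd.DataFrame(rows).T[list(CATEGORIES)]


def biotype_read_fractions(
    counts: pd.DataFrame, categories: pd.Series
) -> pd.DataFrame:
    """Per sample: fraction of counted reads in each biotype
    (category read sums / counted library size)."""
    cats = categories.loc[counts.index]
    keep = cats.isin(CATEGORIES)
    sums = counts[keep].groupby(cats[keep]).sum().reindex(CATEGORIES).fillna(0)
    lib = counts.sum(axis=0)
    return (sums / lib).T[list(CATEGORIES)]


def usable_fraction(
    counted_library_size: float | pd.Series,
    total_sequenced_reads: float | pd.Series,
) -> float | pd.Series:
    """Counted (assigned) reads over total sequenced reads, in [0, 1]."""
    if np.any(np.asarray(total_sequenced_reads) <= 0):
        raise ValueError("total_sequenced_reads must be > 0")
    frac = counted_library_size / total_sequenced_reads
    if np.any(np.asarray(frac) < 0) or np.any(np.asarray(frac) > 1):
        raise ValueError("usable fraction outside [0, 1]")
    return frac


def extra_depth_required(
    frac_polya: float, frac_riboz: float, round_to: int | None = 10
) -> tuple[float, float]:
    """Percent additional sequencing needed by the rRNA-depletion protocol
    to match the polyA+ protocol's exonic depth.

    ``raw = (frac_polya / frac_riboz - 1) * 100``; the reported value is the
    raw value rounded to the nearest ``round_to`` percent (None: no
    rounding). Returns ``(reported, raw)``.
    """
    if not (0 < frac_polya <= 1):
        raise ValueError("frac_polya must be in (0, 1]")
    if not (0 < frac_riboz <= 1):
        raise ValueError("frac_riboz must be in (0, 1] (zero => infinite depth)")
    raw = (frac_polya / frac_riboz - 1.0) * 100.0
    reported = raw if round_to is None else round(raw / round_to) * round_to
    return float(reported), float(raw)


def correlation_matrix(
    expression: ExpressionMatrix,
    rpkm_filter: float = CORR_FILTER_RPKM,
    method: str = "pearson",
) -> pd.DataFrame:
    """Sample x sample correlation of log2(CPM+1) after dropping genes with
    RPKM < ``rpkm_filter`` in *every* sample."""
    if expression.cpm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    keep = (expression.rpkm >= rpkm_filter).any(axis=1)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes survive the expression filter")
    logcpm = np.log2(expression.cpm[keep] + 1.0)
    return logcpm.corr(method=method)


def concordance_by_biotype(
    cpm_polya: pd.Series,
    cpm_riboz: pd.Series,
    categories: pd.Series,
    fc_flag: float = 4.0,
    method: str = "pearson",
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-biotype correlation of log2(CPM+1) between protocols, plus the
    genes whose |log2((cpm_riboZ+1)/(cpm_polyA+1))| exceeds ``fc_flag``.

    Returns (table with columns r/n/n_flagged per category, boolean Series
    of flagged genes). Categories with < 2 genes get r = NaN.
    """
    cats = categories.loc[cpm_polya.index]
    x = np.log2(cpm_polya + 1.0)
    y = np.log2(cpm_riboz.loc[cpm_polya.index] + 1.0)
    log2fc = y - x
    flagged = log2fc.abs() > fc_flag
    rows = {}
    for cat in CATEGORIES:
        mask = cats == cat
        n = int(mask.sum())
        if n >= 2 and x[mask].std() > 0 and y[mask].std() > 0:
            r = float(x[mask].corr(y[mask], method=method))
        else:
            r = np.nan
        rows[cat] = {"r": r, "n": n, "n_flagged": int(flagged[mask].sum())}
    return pd.DataFrame(rows).T, flagged


INTRON_LENGTH_BIN_EDGES = 10.0 ** np.arange(2.0, 7.5, 0.5)  # half-decade bins
N_INTRON_BINS = ((1, 1), (2, 5), (6, 10), (11, 20), (21, np.inf))


@dataclass
class IntronRateResult:
    """Per-gene intron rates with filters, plus per-sample summaries.

    * ``records`` — per gene: category, n_introns, total intron length,
      overlap flag, filter_pass.
    * ``rates`` — gene x sample intron rate (NaN where the denominator is
      zero or the gene fails the filters).
    * ``medians`` — median rate per sample x category over filter-passing
      genes.
    * ``by_intron_length`` / ``by_n_introns`` — median rate per structure
      bin and sample.
    """

    records: pd.DataFrame
    rates: pd.DataFrame
    medians: pd.DataFrame
    by_intron_length: pd.DataFrame
    by_n_introns: pd.DataFrame


def intron_rate_analysis(
    count_table: CountTable,
    models: Mapping[str, GeneModel] | Sequence[GeneModel],
    rpkm: pd.DataFrame,
    min_rpkm: float = INTRON_RATE_MIN_RPKM,
) -> IntronRateResult:
    """Per-gene intron rate = intronic / (intronic + exonic) counts.

    A gene is excluded (filter_pass=False) if it overlaps any other gene,
    has no introns, or its RPKM is < ``min_rpkm`` in any sample of the
    supplied matrix. Genes with a zero denominator in a sample get NaN
    there (logged).
    """
    if not isinstance(models, Mapping):
        models = {m.gene_id: m for m in models}
    genes = count_table.genes
    meta = pd.DataFrame(
        {
            "category": [models[g].category for g in genes],
            "n_introns": [models[g].n_introns for g in genes],
            "intron_length_bp": [models[g].total_intron_length_bp for g in genes],
            "overlaps_other_gene": [models[g].overlaps_other_gene for g in genes],
        },
        index=genes,
    )
    expressed_everywhere = (rpkm.loc[genes] >= min_rpkm).all(axis=1)
    meta["filter_pass"] = (
        ~meta["overlaps_other_gene"]
        & (meta["n_introns"] > 0)
        & expressed_everywhere
    )
    denom = count_table.exonic + count_table.intronic
    rates = count_table.intronic / denom.where(denom > 0)
    n_zero = int(((denom == 0) & meta["filter_pass"].values[:, None]).sum().sum())
    if n_zero:
        logger.info("%d gene/sample cells with zero intronic+exonic counts", n_zero)
    rates = rates.where(meta["filter_pass"], np.nan)

    passing = rates[meta["filter_pass"]]
    med_rows = {}
    for sample in rates.columns:
        med_rows[sample] = passing[sample].groupby(
            meta.loc[passing.index, "category"]
        ).median()
    medians = pd.DataFrame(med_rows).T

    len_bins = pd.cut(
        meta.loc[passing.index, "intron_length_bp"],
        bins=[0, *INTRON_LENGTH_BIN_EDGES],
    )
    by_len = passing.groupby(len_bins, observed=True).median()

    def n_intron_bin(n: int) -> str:
        for lo, hi in N_INTRON_BINS:
            if lo <= n <= hi:
                return f"{lo}" if lo == hi else (f">{lo - 1}" if np.isinf(hi) else f"{lo}-{hi}")
        return "0"

    nbins = meta.loc[passing.index, "n_introns"].map(n_intron_bin)
    by_n = passing.groupby(nbins).median()

    return IntronRateResult(
        records=meta,
        rates=rates,
        medians=medians,
        by_intron_length=by_len,
        by_n_introns=by_n,
    )
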