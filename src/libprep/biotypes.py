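"""Five-way gene biotype classification.

Gencode annotates dozens of fine-grained ``gene_type`` strings; protocol
comparisons summarise them into five categories: protein-coding, lncRNA,
pseudogene, small RNA, and TCR/BCR (T- and B-cell receptor segments).
Anything unrecognised falls into an explicit "other" bucket which is logged
and excluded from five-way summaries.

The exact-string part of the mapping ships as a TSV data table
(``data/biotype_map.tsv``) and can be overridden; two rule-based families
are applied on top because Gencode spells them combinatorially:

* any ``gene_type`` containing ``pseudogene`` -> pseudogene
* ``TR_*`` / ``IG_*`` prefixes -> TCR/BCR
"""
from __future__ import annotations

import csv
import logging
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

PROTEIN_CODING = "protein-coding"
LNCRNA = "lncRNA"
PSEUDOGENE = "pseudogene"
SMALL_RNA = "small RNA"
TCR_BCR = "TCR/BCR"
OTHER = "other"

#: the five summary categories (order used in reports)
CATEGORIES = (PROTEIN_CODING, LNCRNA, PSEUDOGENE, SMALL_RNA, TCR_BCR)
ALL_CATEGORIES = CATEGORIES + (OTHER,)


def load_biotype_map(path: str | Path | None = None) -> dict[str, str]:
    """Load the gene_type -> category table (packaged default or override).

    The TSV has a header line ``gene_type<TAB>category``; categories must be
    one of the five summary categories.
    """
    if path is None:
        source = resources.files("libprep.data").joinpath("biotype_map.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, str] = {}
    reader = csv.reader(text.splitlines(), delimiter="\t")
    header = next(reader)
    if header != ["gene_type", "category"]:
        raise ValueError(f"bad biotype map header: {header}")
    for row in reader:
        if not row:
            continue
        gene_type, category = row
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r} for {gene_type!r}")
        table[gene_type] = category
    return table


_DEFAULT_MAP: dict[str, str] | None = None


def classify_biotype(gene_type: str, table: dict[str, str] | None = None) -> str:
    """Map a Gencode ``gene_type`` string onto a summary category.

    Total function: unknown strings return ``"other"`` with a logged warning.
    """
    global _DEFAULT_MAP
    if table is None:
        if _DEFAULT_MAP is None:
            _DEFAULT_MAP = load_biotype_map()
        table = _DEFAULT_MAP
    if gene_type in table:
        return table[gene_type]
    if "pseudogene" in gene_type:
        return PSEUDOGENE
    if gene_type.startswith(("TR_", "IG_")):
        return TCR_BCR
    logger.warning("unrecognised gene_type %r -> 'other'", gene_type)
    return OTHER
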