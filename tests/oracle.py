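"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (per-base bitmaps, O(n^2) loops,
literal formulas) and shares no code with the package implementation.
"""
from __future__ import annotations

import numpy as np


def bitmap_union(exons: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    """Interval union via a per-base boolean mask."""
    mask = np.zeros(length, dtype=bool)
    for s, e in exons:
        mask[s:e] = True
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, length))
    return out


def _ov(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def brute_force_overlap_flags(spans: dict[str, tuple[str, int, int]]) -> dict[str, bool]:
    """All-pairs span intersection test. spans: gene -> (chrom, start, end)."""
    flags = dict.fromkeys(spans, False)
    genes = sorted(spans)
    for i, g1 in enumerate(genes):
        for g2 in genes[i + 1:]:
            c1, s1, e1 = spans[g1]
            c2, s2, e2 = spans[g2]
            if c1 == c2 and _ov((s1, e1), (s2, e2)) > 0:
                flags[g1] = flags[g2] = True
    return flags


def brute_force_multi_regions(
    exons_by_gene: dict[str, list[tuple[str, int, int]]], length: int
) -> dict[str, list[tuple[int, int]]]:
    """Per-base count of distinct genes covering each position (per chrom)."""
    chroms = {c for exs in exons_by_gene.values() for c, _, _ in exs}
    out = {}
    for chrom in chroms:
        cover = np.zeros(length, dtype=int)
        for exs in exons_by_gene.values():
            gene_mask = np.zeros(length, dtype=bool)
            for c, s, e in exs:
                if c == chrom:
                    gene_mask[s:e] = True
            cover += gene_mask
        out[chrom] = bitmap_union(
            [(i, i + 1) for i in np.nonzero(cover >= 2)[0]], length
        )
    return out


def oracle_count(
    fragments,
    models,
    multi_regions: dict[str, list[tuple[int, int]]],
    min_overlap: int = 25,
):
    """Nested-loop reimplementation of classification + assignment.

    fragments: objects with .chrom, .blocks (objects with .start/.end),
    .is_unique; models: objects with .gene_id/.chrom/.union_exons/.introns.
    Returns (exonic_counts, intronic_counts, totals) as plain dicts.
    """
    exonic = {m.gene_id: 0 for m in models}
    intronic = {m.gene_id: 0 for m in models}
    totals = {"unique_fragments": 0, "exonic": 0, "intronic": 0,
              "intergenic": 0, "assigned_exonic": 0, "assigned_intronic": 0,
              "ambiguous": 0, "unassigned_exonic": 0}
    for frag in fragments:
        if not frag.is_unique:
            continue
        totals["unique_fragments"] += 1
        blocks = [(b.start, b.end) for b in frag.blocks]
        exon_ov: dict[str, int] = {}
        intron_ov: dict[str, int] = {}
        for m in models:
            if m.chrom != frag.chrom:
                continue
            eo = sum(_ov(b, (iv.start, iv.end))
                     for b in blocks for iv in m.union_exons)
            io = sum(_ov(b, (iv.start, iv.end))
                     for b in blocks for iv in m.introns)
            if eo:
                exon_ov[m.gene_id] = eo
            if io:
                intron_ov[m.gene_id] = io
        # classification (>=1 bp touch)
        if exon_ov:
            totals["exonic"] += 1
        elif intron_ov:
            totals["intronic"] += 1
        else:
            totals["intergenic"] += 1
        # assignment
        touches_multi = any(
            _ov(b, r) > 0
            for b in blocks for r in multi_regions.get(frag.chrom, [])
        )
        cands = sorted(g for g, ov in exon_ov.items() if ov >= min_overlap)
        if cands:
            if len(cands) == 1 and not touches_multi:
                exonic[cands[0]] += 1
                totals["assigned_exonic"] += 1
            else:
                totals["ambiguous"] += 1
        elif intron_ov:
            best = sorted(intron_ov.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            intronic[best] += 1
            totals["assigned_intronic"] += 1
        elif exon_ov:
            totals["unassigned_exonic"] += 1
    return exonic, intronic, totals


def bh_stepup(pvalues: np.ndarray) -> np.ndarray:
    """Literal Benjamini–Hochberg step-up: sort ascending, adj_(i) =
    min_{j >= i} (m / j) * p_(j), capped at 1, original order restored."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, m / rank * p[idx])
        adj_sorted[rank - 1] = running_min
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def binom_tail_doubling(k: int, n: int, p: float) -> float:
    """Two-sided binomial p-value by tail doubling, via explicit pmf sums."""
    from math import comb

    pmf = [comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    lower = sum(pmf[: k + 1])
    upper = sum(pmf[k:])
    return min(1.0, 2.0 * min(lower, upper))
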