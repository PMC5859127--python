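"""Differential expression between protocols.

The comparison's contribution is the *definition* of a DE gene — fold
change > 2, Benjamini–Hochberg adjusted p < 0.05, mean expression
> 0.5 RPKM — and the per-biotype summaries, not the count model. The
default per-gene test is therefore a deliberately simple exact conditional
binomial on pooled counts: conditional on a gene's total count across both
groups, the group-A share is Binomial(total, libA/(libA+libB)) under the
null of equal concentration; the two-sided p-value doubles the smaller
tail. Externally computed p-values (e.g. from a negative-binomial GLM) can
be supplied instead via the ``pvalues`` hook.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import compute_cpm, compute_rpkm

FC_THRESHOLD = 2.0
ALPHA = 0.05
RPKM_FLOOR = 0.5
LOG2FC_PSEUDOCOUNT = 0.5

DIRECTIONS = ("up_in_riboZ", "down_in_riboZ", "none")


def two_group_count_test(
    counts_a: pd.DataFrame | pd.Series,
    counts_b: pd.DataFrame | pd.Series,
    lib_sizes_a: float | pd.Series,
    lib_sizes_b: float | pd.Series,
) -> pd.Series:
    """Exact conditional binomial test per gene on pooled counts.

    ``counts_a``/``counts_b`` are gene x replicate matrices (or Series for a
    single replicate); replicates are pooled. Two-sided p by tail doubling:
    ``min(1, 2 * min(P(X <= k), P(X >= k)))`` with
    ``X ~ Binomial(kA + kB, NA / (NA + NB))``. Genes with zero total count
    get p = 1 (no evidence).
    """
    ka = counts_a.sum(axis=1) if isinstance(counts_a, pd.DataFrame) else counts_a
    kb = counts_b.sum(axis=1) if isinstance(counts_b, pd.DataFrame) else counts_b
    na = float(np.sum(np.asarray(lib_sizes_a)))
    nb = float(np.sum(np.asarray(lib_sizes_b)))
    if na <= 0 or nb <= 0:
        raise ValueError("library sizes must be > 0")
    total = ka + kb
    p_null = na / (na + nb)
    lower = stats.binom.cdf(ka, total, p_null)
    upper = stats.binom.sf(ka - 1, total, p_null)
    pvals = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    pvals = np.where(total == 0, 1.0, pvals)
    return pd.Series(pvals, index=ka.index, name="pvalue")


def bh_adjust(pvalues: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1, original
    order preserved)."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1] if arr.size else arr
    if isinstance(pvalues, pd.Series):
        return pd.Series(adj, index=pvalues.index, name="adj_p")
    return adj


def apply_de_criteria(
    log2fc: pd.Series,
    adj_p: pd.Series,
    mean_rpkm: pd.Series,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
    rpkm_floor: float = RPKM_FLOOR,
) -> pd.DataFrame:
    """Label genes DE iff |log2FC| > log2(fc_threshold) AND adj_p < alpha
    AND mean RPKM > rpkm_floor (all strict, as printed)."""
    is_de = (
        (log2fc.abs() > np.log2(fc_threshold))
        & (adj_p < alpha)
        & (mean_rpkm > rpkm_floor)
    )
    direction = pd.Series("none", index=log2fc.index, name="direction")
    direction[is_de & (log2fc > 0)] = "up_in_riboZ"
    direction[is_de & (log2fc < 0)] = "down_in_riboZ"
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "adj_p": adj_p,
            "mean_rpkm": mean_rpkm,
            "is_de": is_de,
            "direction": direction,
        }
    )


def de_between_protocols(
    exonic_counts: pd.DataFrame,
    polya_samples: list[str],
    riboz_samples: list[str],
    exonic_length_bp: pd.Series,
    pvalues: pd.Series | None = None,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
    rpkm_floor: float = RPKM_FLOOR,
    pseudocount: float = LOG2FC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Full DE table between rRNA depletion and polyA+ selection.

    log2FC = log2((mean CPM_riboZ + pc) / (mean CPM_polyA + pc)) with mean
    CPM over replicates; mean RPKM = average of the two merged-replicate
    per-protocol RPKMs. ``pvalues`` overrides the default binomial test.
    """
    ca = exonic_counts[polya_samples]
    cb = exonic_counts[riboz_samples]
    lib_a = ca.sum(axis=0)
    lib_b = cb.sum(axis=0)
    cpm_a = compute_cpm(ca, lib_a).mean(axis=1)
    cpm_b = compute_cpm(cb, lib_b).mean(axis=1)
    log2fc = np.log2((cpm_b + pseudocount) / (cpm_a + pseudocount))
    log2fc.name = "log2fc"
    rpkm_a = compute_rpkm(ca.sum(axis=1), exonic_length_bp, float(lib_a.sum()))
    rpkm_b = compute_rpkm(cb.sum(axis=1), exonic_length_bp, float(lib_b.sum()))
    mean_rpkm = (rpkm_a + rpkm_b) / 2.0
    mean_rpkm.name = "mean_rpkm"
    if pvalues is None:
        pvalues = two_group_count_test(ca, cb, lib_a, lib_b)
    adj = bh_adjust(pvalues)
    out = apply_de_criteria(
        log2fc, adj, mean_rpkm, fc_threshold, alpha, rpkm_floor
    )
    out.insert(1, "pvalue", pvalues)
    return out


def de_summary_by_biotype(
    de_results: pd.DataFrame,
    categories: pd.Series,
    expressed: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-biotype DE summaries.

    Returns two tables indexed by category:

    * fractions of *expressed* genes that are DE, split by direction
      (``expressed`` is a boolean Series; default: all genes in
      ``de_results``);
    * direction split among DE genes, up/(up+down) and down/(up+down);
      NaN for categories without DE genes.
    """
    cats = categories.loc[de_results.index]
    if expressed is None:
        expressed = pd.Series(True, index=de_results.index)
    rows_b, rows_c = {}, {}
    for cat in pd.unique(cats):
        mask = cats == cat
        n_expr = int((mask & expressed).sum())
        up = int((mask & de_results["is_de"]
                  & (de_results["direction"] == "up_in_riboZ")).sum())
        down = int((mask & de_results["is_de"]
                    & (de_results["direction"] == "down_in_riboZ")).sum())
        rows_b[cat] = {
            "n_expressed": n_expr,
            "frac_up": up / n_expr if n_expr else np.nan,
            "frac_down": down / n_expr if n_expr else np.nan,
        }
        n_de = up + down
        rows_c[cat] = {
            "n_de": n_de,
            "up_fraction": up / n_de if n_de else np.nan,
            "down_fraction": down / n_de if n_de else np.nan,
        }
    return pd.DataFrame(rows_b).T, pd.DataFrame(rows_c).T
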