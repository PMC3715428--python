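"""Joint classification of deregulated genes by their ChIP-binding pattern.

Genes deregulated in the tumourigenic contrast fall into six mutually
exclusive classes by crossing their deregulation pattern (deregulated in
both contrasts, or in the tumour contrast only) with their peak-association
pattern across the two ChIP conditions:

====== ===================== =====================
class  deregulated in        peaks in
====== ===================== =====================
1      both                  both conditions
2      tumour only           both conditions
3      both                  tumour condition only
4      tumour only           tumour condition only
5      both or tumour only   no condition
6      both or tumour only   non-tumour condition only
====== ===================== =====================

Genes deregulated only in the non-tumour contrast (or not at all) receive
no class number.  The module also reports all Venn bookkeeping counts and
provides a generic hypergeometric term-enrichment test.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, Sequence

import pandas as pd
from scipy import stats

from .expression import bh_adjust

UNCLASSIFIED = 0  # class_label for genes outside the six classes

DEREG_PATTERNS = ("none", "ab_only", "tumour_only", "both")
PEAK_PATTERNS = ("none", "ab_only", "tumour_only", "both")


def peak_pattern(has_ab: bool, has_tumour: bool) -> str:
    if has_ab and has_tumour:
        return "both"
    if has_ab:
        return "ab_only"
    if has_tumour:
        return "tumour_only"
    return "none"


def class_of(dereg: str, peaks: str) -> int:
    """Class number for one gene, or UNCLASSIFIED (0)."""
    if dereg not in ("both", "tumour_only"):
        return UNCLASSIFIED
    if peaks == "both":
        return 1 if dereg == "both" else 2
    if peaks == "tumour_only":
        return 3 if dereg == "both" else 4
    if peaks == "none":
        return 5
    return 6  # peaks in the non-tumour condition only


def filter_to_array_universe(
    target_flags: pd.DataFrame, universe: Iterable[str]
) -> pd.DataFrame:
    """Drop ChIP target flags for genes not measured on the array."""
    universe = set(universe)
    kept = target_flags[target_flags["gene_id"].isin(universe)]
    if len(kept) == 0 and len(target_flags) > 0:
        raise ValueError(
            "no ChIP gene ids found in the expression universe; "
            "gene-id namespaces probably differ"
        )
    return kept.reset_index(drop=True)


def classify_genes(
    gene_calls: pd.DataFrame,
    target_flags: pd.DataFrame,
    conditions: Sequence[str] = ("ab", "scrib_ab"),
) -> pd.DataFrame:
    """Per-gene class labels from deregulation calls and target flags.

    ``gene_calls`` needs gene_id and assignment (none/ab_only/tumour_only/
    both); ``target_flags`` needs gene_id plus has_peak_<cond> for the two
    conditions (non-tumour first).  Genes absent from the flag table are
    treated as having no peaks.
    """
    ab_col, tum_col = (f"has_peak_{c}" for c in conditions)
    flags = target_flags.set_index("gene_id")
    missing = ~gene_calls["gene_id"].isin(flags.index)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} genes without target flags treated as "
            "peak pattern 'none'",
            RuntimeWarning,
            stacklevel=2,
        )
    rows = []
    for row in gene_calls.itertuples(index=False):
        if row.gene_id in flags.index:
            has_ab = bool(flags.at[row.gene_id, ab_col])
            has_t = bool(flags.at[row.gene_id, tum_col])
        else:
            has_ab = has_t = False
        pp = peak_pattern(has_ab, has_t)
        rows.append(
            {
                "gene_id": row.gene_id,
                "dereg_pattern": row.assignment,
                "peak_pattern": pp,
                "class_label": class_of(row.assignment, pp),
            }
        )
    return pd.DataFrame(rows)


def venn_report(
    probe_df: pd.DataFrame,
    gene_calls: pd.DataFrame,
    target_flags: pd.DataFrame,
    classification: pd.DataFrame,
    contrasts: Sequence[str] = ("ab", "scrib_ab"),
) -> Dict:
    """All Venn counts of the integrated analysis.

    Probe-level: unique/shared/none deregulation patterns and per-contrast
    totals.  Gene-level: deregulated gene counts per pattern.  ChIP-level:
    unique/shared target-gene counts.  Class sizes 1-6, and the rounded
    percentage of deregulated genes carrying a peak in their own sample.
    """
    ab, tum = contrasts
    d_ab = probe_df[f"dir_{ab}"].to_numpy(int) != 0
    d_t = probe_df[f"dir_{tum}"].to_numpy(int) != 0
    probe_counts = {
        "unique_ab": int((d_ab & ~d_t).sum()),
        "unique_tumour": int((~d_ab & d_t).sum()),
        "shared": int((d_ab & d_t).sum()),
        "none": int((~d_ab & ~d_t).sum()),
    }
    probe_counts["total_ab"] = probe_counts["unique_ab"] + probe_counts["shared"]
    probe_counts["total_tumour"] = probe_counts["unique_tumour"] + probe_counts["shared"]
    probe_counts["total_dereg"] = (
        probe_counts["unique_ab"] + probe_counts["unique_tumour"] + probe_counts["shared"]
    )
    probe_counts["universe"] = int(len(probe_df))

    gene_counts = gene_calls["assignment"].value_counts().to_dict()
    gene_counts = {p: int(gene_counts.get(p, 0)) for p in DEREG_PATTERNS}

    ha = target_flags[f"has_peak_{ab}"].to_numpy(bool)
    ht = target_flags[f"has_peak_{tum}"].to_numpy(bool)
    chip_counts = {
        "unique_ab": int((ha & ~ht).sum()),
        "unique_tumour": int((~ha & ht).sum()),
        "shared": int((ha & ht).sum()),
    }
    chip_counts["total_ab"] = chip_counts["unique_ab"] + chip_counts["shared"]
    chip_counts["total_tumour"] = chip_counts["unique_tumour"] + chip_counts["shared"]

    class_sizes = {
        k: int((classification["class_label"] == k).sum()) for k in range(1, 7)
    }

    # % of deregulated genes with >=1 peak in their own sample
    merged = classification
    dereg_ab_mask = merged["dereg_pattern"].isin(["both", "ab_only"])
    dereg_t_mask = merged["dereg_pattern"].isin(["both", "tumour_only"])
    peak_ab_mask = merged["peak_pattern"].isin(["both", "ab_only"])
    peak_t_mask = merged["peak_pattern"].isin(["both", "tumour_only"])
    n_ab = int(dereg_ab_mask.sum())
    n_t = int(dereg_t_mask.sum())
    with_ab = int((dereg_ab_mask & peak_ab_mask).sum())
    with_t = int((dereg_t_mask & peak_t_mask).sum())
    percentages = {
        "dereg_ab_genes": n_ab,
        "dereg_ab_with_peaks": with_ab,
        "pct_ab": int(round(100 * with_ab / n_ab)) if n_ab else 0,
        "dereg_tumour_genes": n_t,
        "dereg_tumour_with_peaks": with_t,
        "pct_tumour": int(round(100 * with_t / n_t)) if n_t else 0,
    }
    return {
        "probe": probe_counts,
        "genes": gene_counts,
        "chip": chip_counts,
        "classes": class_sizes,
        "percentages": percentages,
    }


def term_enrichment(
    gene_set: Iterable[str], term_table: pd.DataFrame, universe: Iterable[str]
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation per term, BH-adjusted.

    ``term_table`` is a two-column frame (term_id, gene_id).  For a universe
    of N genes, a term of K genes and a query set of n genes with k genes in
    common, p = P[X >= k] for X ~ Hypergeometric(N, K, n).
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene set is not a subset of the universe")
    terms = term_table[term_table["gene_id"].isin(universe)]
    rows = []
    n = len(gene_set)
    N = len(universe)
    for term_id, grp in terms.groupby("term_id", sort=True):
        members = set(grp["gene_id"])
        k = len(members & gene_set)
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term_id, "overlap": k, "term_size": K,
                     "set_size": n, "universe_size": N, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"])
    return out
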