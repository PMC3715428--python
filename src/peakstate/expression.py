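"""Differential-expression calling on replicated log2 array intensities.

Each non-control genotype is contrasted against the control genotype with a
two-sample t-test on log2 intensities (Welch by default), p-values are
adjusted per contrast with the Benjamini-Hochberg step-up procedure, and a
probe set is called deregulated when |log2FC| exceeds the fold-change
threshold AND the adjusted p falls below the significance threshold (strict
inequalities).  Direction codes follow the +1/-1/0 convention.  Probe-level
calls are then reconciled into gene-level deregulation calls, since a gene
may be interrogated by more than one probe set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONTROL = "control"
#: the two non-control genotypes of the study design: the transcription
#: factor overexpressed alone, and overexpressed in polarity-mutant
#: (tumourigenic) clones.
CONTRASTS = ("ab", "scrib_ab")


@dataclass
class DEThresholds:
    """Deregulation call thresholds (|log2FC| > 1, adjusted p < 0.05)."""

    min_abs_log2fc: float = 1.0
    max_adj_p: float = 0.05

    def validate(self) -> None:
        if self.min_abs_log2fc <= 0:
            raise ValueError("min_abs_log2fc must be > 0")
        if not 0 < self.max_adj_p < 1:
            raise ValueError("max_adj_p must be in (0,1)")


def sample_columns(expr: pd.DataFrame, genotype: str) -> List[str]:
    """Columns of one genotype, named ``<genotype>_<replicate>``."""
    cols = [c for c in expr.columns if c.rsplit("_", 1)[0] == genotype]
    if not cols:
        raise ValueError(f"no sample columns for genotype {genotype!r}")
    return cols


def compute_contrast(
    expr: pd.DataFrame,
    genotype: str,
    control: str = CONTROL,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-probe log2 fold change and raw p for genotype vs control.

    log2FC is the difference of group means on the log2 scale.  The p-value
    comes from a two-sided two-sample t-test, Welch-Satterthwaite by default
    (``equal_var=True`` selects the pooled-variance test).  Degenerate
    zero-variance probes get p=1 when the means agree and p=0 (with a
    warning) when they differ.
    """
    g = expr[sample_columns(expr, genotype)].to_numpy(float)
    c = expr[sample_columns(expr, control)].to_numpy(float)
    if g.shape[1] < 2 or c.shape[1] < 2:
        raise ValueError("need >=2 replicates per group")
    log2fc = g.mean(axis=1) - c.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(g, c, axis=1, equal_var=equal_var)
        pvals = np.asarray(res.pvalue, float)
    degenerate = (g.var(axis=1) == 0) & (c.var(axis=1) == 0)
    if degenerate.any():
        equal_means = degenerate & np.isclose(log2fc, 0.0)
        pvals[equal_means] = 1.0
        shifted = degenerate & ~np.isclose(log2fc, 0.0)
        if shifted.any():
            warnings.warn(
                f"{int(shifted.sum())} probes have zero variance but unequal "
                "means; p set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            pvals[shifted] = 0.0
    return pd.DataFrame(
        {
            "probe_set_id": expr["probe_set_id"].to_numpy(),
            "gene_id": expr["gene_id"].to_numpy(),
            "log2fc": log2fc,
            "pval": pvals,
        }
    )


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def call_probes(
    log2fc: Sequence[float], adj_p: Sequence[float], thresholds: DEThresholds | None = None
) -> np.ndarray:
    """+1/-1/0 direction codes from effect size and adjusted significance."""
    th = thresholds or DEThresholds()
    th.validate()
    log2fc = np.asarray(log2fc, float)
    adj_p = np.asarray(adj_p, float)
    called = (np.abs(log2fc) > th.min_abs_log2fc) & (adj_p < th.max_adj_p)
    return np.where(called, np.sign(log2fc).astype(int), 0)


def de_table(
    expr: pd.DataFrame,
    thresholds: DEThresholds | None = None,
    contrasts: Iterable[str] = CONTRASTS,
    control: str = CONTROL,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Full probe-level result table over all contrasts.

    BH adjustment is applied per contrast across all probe sets jointly.
    Columns per contrast g: ``log2fc_<g>``, ``p_<g>``, ``q_<g>``, ``dir_<g>``.
    """
    out = expr[["probe_set_id", "gene_id"]].copy()
    for g in contrasts:
        res = compute_contrast(expr, g, control=control, equal_var=equal_var)
        q = bh_adjust(res["pval"])
        out[f"log2fc_{g}"] = res["log2fc"].to_numpy()
        out[f"p_{g}"] = res["pval"].to_numpy()
        out[f"q_{g}"] = q
        out[f"dir_{g}"] = call_probes(res["log2fc"], q, thresholds)
    return out


def _gene_group_call(dirs: np.ndarray) -> Tuple[bool, bool, bool, bool, str, bool]:
    """Reconcile one gene's probe direction codes (n_probes x 2 array)."""
    d_ab, d_t = dirs[:, 0], dirs[:, 1]
    dereg_ab = bool((d_ab != 0).any())
    dereg_t = bool((d_t != 0).any())
    conflict_ab = bool((d_ab == 1).any() and (d_ab == -1).any())
    conflict_t = bool((d_t == 1).any() and (d_t == -1).any())
    mixed = False
    if ((d_ab != 0) & (d_t != 0)).any():
        assignment = "both"
    elif dereg_ab and dereg_t:
        # distinct probe sets deregulated in different single genotypes:
        # union semantics, flagged as mixed evidence
        assignment, mixed = "both", True
    elif dereg_ab:
        assignment = "ab_only"
    elif dereg_t:
        assignment = "tumour_only"
    else:
        assignment = "none"
    return dereg_ab, dereg_t, conflict_ab, conflict_t, assignment, mixed


def reconcile_genes(
    probe_df: pd.DataFrame, contrasts: Sequence[str] = CONTRASTS
) -> pd.DataFrame:
    """Gene-level deregulation calls from probe-level direction codes.

    A gene is deregulated in a contrast when any of its probe sets is; it is
    assigned to both genotypes when a single probe set is deregulated in
    both.  A conflict flag marks contrasts where the gene carries both up-
    and downregulated probe sets.  Probes without a gene id are dropped
    (count reported via warning).
    """
    ab, tum = contrasts
    df = probe_df
    missing = df["gene_id"].isna() | (df["gene_id"] == "")
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} probe sets without gene_id excluded",
            RuntimeWarning,
            stacklevel=2,
        )
        df = df[~missing]
    rows = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        dirs = grp[[f"dir_{ab}", f"dir_{tum}"]].to_numpy(int)
        dereg_ab, dereg_t, c_ab, c_t, assignment, mixed = _gene_group_call(dirs)
        rows.append(
            {
                "gene_id": gene_id,
                "n_probes": len(grp),
                "dereg_ab": dereg_ab,
                "dereg_tumour": dereg_t,
                "assignment": assignment,
                "conflict_ab": c_ab,
                "conflict_tumour": c_t,
                "mixed_evidence": mixed,
            }
        )
    return pd.DataFrame(rows)
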