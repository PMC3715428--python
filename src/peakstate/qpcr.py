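"""Relative quantification arithmetic for qPCR validation assays.

Expression validation uses the 2^(-ddCt) method: per condition, dCt is the
mean target Ct minus the mean Ct of the normalizer gene (CG6044 by
default), technical replicates being averaged on the Ct scale first;
ddCt is dCt(condition) - dCt(reference) and the fold change is 2^(-ddCt),
so the reference condition sits at 1 by construction.

ChIP validation compares the antibody immunoprecipitation to a
nonspecific-IgG control IP: fold enrichment = 2^(Ct_controlIP - Ct_antibodyIP)
per replicate, the control baseline being identically 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

DEFAULT_NORMALIZER = "CG6044"


@dataclass
class FoldChangeResult:
    target_gene: str
    condition: str
    fold_change: float
    replicate_folds: List[float]
    sd: float


def _mean_ct(ct: pd.DataFrame, gene: str, condition: str, replicate=None) -> float:
    sel = (ct["target_gene"] == gene) & (ct["condition"] == condition)
    if replicate is not None:
        sel &= ct["replicate"] == replicate
    vals = ct.loc[sel, "ct"]
    if len(vals) == 0:
        raise ValueError(f"no Ct values for {gene!r} in condition {condition!r}")
    return float(vals.mean())


def _replicates(ct: pd.DataFrame, gene: str, condition: str) -> List:
    sel = (ct["target_gene"] == gene) & (ct["condition"] == condition)
    return sorted(ct.loc[sel, "replicate"].unique())


def _delta_ct(
    ct: pd.DataFrame, target: str, normalizer: str, condition: str, replicate=None
) -> float:
    return _mean_ct(ct, target, condition, replicate) - _mean_ct(
        ct, normalizer, condition, replicate
    )


def ddct_fold_change(
    ct: pd.DataFrame,
    target: str,
    condition: str,
    reference_condition: str,
    normalizer: str = DEFAULT_NORMALIZER,
) -> FoldChangeResult:
    """Fold change of a target gene relative to the reference condition.

    Technical replicates are averaged on the Ct scale before dCt; the
    overall fold uses condition means, while replicate-level folds pair
    biological replicates of the two conditions by index.
    """
    if not (ct["target_gene"] == normalizer).any():
        raise ValueError(f"normalizer {normalizer!r} absent from Ct table")
    ddct = _delta_ct(ct, target, normalizer, condition) - _delta_ct(
        ct, target, normalizer, reference_condition
    )
    reps_c = _replicates(ct, target, condition)
    reps_r = _replicates(ct, target, reference_condition)
    rep_folds = [
        float(
            2.0
            ** -(
                _delta_ct(ct, target, normalizer, condition, rc)
                - _delta_ct(ct, target, normalizer, reference_condition, rr)
            )
        )
        for rc, rr in zip(reps_c, reps_r)
    ]
    sd = float(np.std(rep_folds, ddof=1)) if len(rep_folds) > 1 else 0.0
    return FoldChangeResult(
        target_gene=target,
        condition=condition,
        fold_change=float(2.0**-ddct),
        replicate_folds=rep_folds,
        sd=sd,
    )


def chip_fold_enrichment(
    ct: pd.DataFrame,
    target: str,
    antibody_condition: str = "antibody_ip",
    control_condition: str = "control_ip",
) -> FoldChangeResult:
    """Fold enrichment of the antibody IP over the control (IgG) IP."""
    if not (
        (ct["target_gene"] == target) & (ct["condition"] == control_condition)
    ).any():
        raise ValueError(f"no control IP rows for {target!r}")
    reps_a = _replicates(ct, target, antibody_condition)
    reps_c = _replicates(ct, target, control_condition)
    rep_folds = [
        float(
            2.0
            ** (
                _mean_ct(ct, target, control_condition, rc)
                - _mean_ct(ct, target, antibody_condition, ra)
            )
        )
        for ra, rc in zip(reps_a, reps_c)
    ]
    fold = float(
        2.0
        ** (
            _mean_ct(ct, target, control_condition)
            - _mean_ct(ct, target, antibody_condition)
        )
    )
    sd = float(np.std(rep_folds, ddof=1)) if len(rep_folds) > 1 else 0.0
    return FoldChangeResult(
        target_gene=target,
        condition=antibody_condition,
        fold_change=fold,
        replicate_folds=rep_folds,
        sd=sd,
    )
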