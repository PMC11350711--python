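"""Relative quantification of qPCR cycle thresholds by the 2^-ddCt method.

Replicate Ct values are averaged per (sample, gene); dCt is target minus
reference (GAPDH for mRNA/lncRNA assays, U6 for miRNA); ddCt subtracts the
calibrator-group mean dCt; relative quantity RQ = 2^-ddCt.  The calibrator
defaults to the low group, so RQ > 1 in the high group reads as
upregulation, matching the sign of the DE log2 fold-change.  Group
comparison is a two-sided t-test on log2(RQ) by default (variance
stabilization); the raw-RQ variant is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleSheet

CT_COLUMNS = ["sample_id", "gene_id", "replicate", "ct"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in CT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"Ct table {path} lacks required column '{col}'")
    if not np.isfinite(df["ct"]).all():
        raise ValueError(f"Ct table {path} contains non-finite Ct values")
    return df[CT_COLUMNS]


@dataclass
class DdctResult:
    """Per-sample relative expression and the group comparison."""

    target: str
    reference: str
    calibrator: str
    per_sample: pd.DataFrame  # sample_id, group, dct, ddct, rq
    group_stats: pd.DataFrame  # group, mean_rq, sd_rq, n
    t: float
    p: float
    log2_rq_ratio: float  # mean log2 RQ, high minus low


def _mean_ct(ct: pd.DataFrame, gene: str) -> pd.Series:
    sub = ct[ct["gene_id"] == gene]
    return sub.groupby("sample_id")["ct"].mean()


def ddct_relative_expression(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    samples: SampleSheet,
    calibrator: str = "low",
    log_scale_ttest: bool = True,
) -> DdctResult:
    """2^-ddCt relative expression of ``target`` against ``reference``.

    Both genes must be measured in every sample of the sheet; a missing
    reference measurement is a hard error.
    """
    target_ct = _mean_ct(ct, target)
    ref_ct = _mean_ct(ct, reference)
    for name, series in (("target", target_ct), ("reference", ref_ct)):
        missing = [s for s in samples.sample_ids if s not in series.index]
        if missing:
            raise ValueError(f"{name} gene not measured in sample(s) {missing}")
    order = list(samples.sample_ids)
    dct = target_ct.loc[order] - ref_ct.loc[order]
    groups = pd.Series(samples.groups, index=order)
    cal_mean = dct[groups == calibrator].mean()
    ddct = dct - cal_mean
    rq = np.power(2.0, -ddct)
    per_sample = pd.DataFrame(
        {"sample_id": order, "group": groups.values, "dct": dct.values,
         "ddct": ddct.values, "rq": rq.values}
    )
    gs = (
        per_sample.groupby("group")["rq"]
        .agg(mean_rq="mean", sd_rq="std", n="size")
        .reset_index()
    )
    hi = per_sample.loc[per_sample["group"] == "high", "rq"].to_numpy()
    lo = per_sample.loc[per_sample["group"] == "low", "rq"].to_numpy()
    if log_scale_ttest:
        t, p = stats.ttest_ind(np.log2(hi), np.log2(lo), equal_var=True)
    else:
        t, p = stats.ttest_ind(hi, lo, equal_var=True)
    if np.isnan(t):  # zero variance in both groups
        equal = np.isclose(hi.mean(), lo.mean())
        t = 0.0 if equal else float("inf")
        p = 1.0 if equal else 0.0
    log2_ratio = float(np.mean(np.log2(hi)) - np.mean(np.log2(lo)))
    return DdctResult(
        target=target,
        reference=reference,
        calibrator=calibrator,
        per_sample=per_sample,
        group_stats=gs,
        t=float(t),
        p=float(p),
        log2_rq_ratio=log2_ratio,
    )
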