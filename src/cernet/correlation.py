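"""Spearman-correlation filtering of predicted miRNA-target pairs.

Only differentially expressed features are scored.  Correlations are
computed on normalized expression across all samples: size-factor-normalized
counts for mRNA/lncRNA and per-million counts for miRNA.  Candidate
miRNA-target pairs must correlate more negatively than ``scc_neg_max``
(default -0.7, strict); candidate lncRNA-mRNA ceRNA pairs must share at
least one passing miRNA and correlate above ``scc_pos_min`` (default 0.9,
strict).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .de import size_factors, tpm_normalize
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["a_id", "b_id", "pair_type", "scc", "passes"]


def spearman_scc(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of average ranks).

    Ties receive mean ranks.  Returns ``nan`` when either vector is
    constant (ranks undefined); callers exclude such pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def normalized_expression(
    matrices: dict[str, ExpressionMatrix],
) -> dict[str, pd.DataFrame]:
    """Correlation substrate per RNA class.

    mRNA and lncRNA counts are divided by median-of-ratios size factors;
    miRNA counts are scaled per million.
    """
    out = {}
    for cls, mat in matrices.items():
        if cls == "miRNA":
            out[cls] = tpm_normalize(mat).data
        else:
            out[cls] = mat.data / size_factors(mat).to_numpy()[None, :]
    return out


def _significant_ids(de_table: pd.DataFrame) -> set:
    return set(de_table.loc[de_table["significant"], "feature_id"])


def filter_mirna_pairs(
    targets: pd.DataFrame,
    de: dict[str, pd.DataFrame],
    expr: dict[str, pd.DataFrame],
    cfg: RunConfig,
) -> pd.DataFrame:
    """Score predicted miRNA-target edges between DE features.

    Edges whose endpoints are both significant DE features are scored by
    Spearman correlation; an edge passes iff ``scc < cfg.scc_neg_max``.
    Edges naming a feature absent from the expression matrices, or with a
    constant expression vector, are skipped with a warning (counted in
    ``result.attrs["n_skipped"]``).

    Returns a DataFrame with columns a_id, b_id, pair_type, scc, passes,
    where a lncRNA-miRNA row has ``a_id`` = lncRNA and a miRNA-mRNA row has
    ``a_id`` = miRNA.
    """
    sig = {cls: _significant_ids(t) for cls, t in de.items()}
    rows = []
    n_skipped = 0
    for mirna, target, tclass in targets[["mirna_id", "target_id", "target_class"]].itertuples(
        index=False
    ):
        if mirna not in sig.get("miRNA", set()) or target not in sig.get(tclass, set()):
            continue
        if mirna not in expr["miRNA"].index or target not in expr[tclass].index:
            logger.warning("skipping edge %s-%s: feature missing from matrices", mirna, target)
            n_skipped += 1
            continue
        scc = spearman_scc(expr["miRNA"].loc[mirna], expr[tclass].loc[target])
        if np.isnan(scc):
            logger.warning("skipping edge %s-%s: constant expression vector", mirna, target)
            n_skipped += 1
            continue
        if tclass == "lncRNA":
            rows.append((target, mirna, "lncRNA-miRNA", scc, scc < cfg.scc_neg_max))
        else:
            rows.append((mirna, target, "miRNA-mRNA", scc, scc < cfg.scc_neg_max))
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    out["passes"] = out["passes"].astype(bool)
    out.attrs["n_skipped"] = n_skipped
    return out


def candidate_cerna_pairs(
    targets: pd.DataFrame,
    de: dict[str, pd.DataFrame],
    expr: dict[str, pd.DataFrame],
    cfg: RunConfig,
    passing_pairs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score lncRNA-mRNA pairs that share at least one passing miRNA.

    ``passing_pairs`` defaults to :func:`filter_mirna_pairs` output; only
    rows with ``passes`` are used to form the shared-miRNA requirement.
    A pair passes iff its Spearman correlation exceeds ``cfg.scc_pos_min``.
    """
    if passing_pairs is None:
        passing_pairs = filter_mirna_pairs(targets, de, expr, cfg)
    ok = passing_pairs[passing_pairs["passes"]]
    lnc_sets: dict[str, set] = {}
    mrna_sets: dict[str, set] = {}
    for a, b, ptype in ok[["a_id", "b_id", "pair_type"]].itertuples(index=False):
        if ptype == "lncRNA-miRNA":
            lnc_sets.setdefault(a, set()).add(b)
        elif ptype == "miRNA-mRNA":
            mrna_sets.setdefault(b, set()).add(a)
    rows = []
    n_skipped = 0
    for lnc in sorted(lnc_sets):
        for mrna in sorted(mrna_sets):
            if not lnc_sets[lnc] & mrna_sets[mrna]:
                continue
            scc = spearman_scc(expr["lncRNA"].loc[lnc], expr["mRNA"].loc[mrna])
            if np.isnan(scc):
                n_skipped += 1
                continue
            rows.append((lnc, mrna, "lncRNA-mRNA", scc, scc > cfg.scc_pos_min))
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    out["passes"] = out["passes"].astype(bool)
    out.attrs["n_skipped"] = n_skipped
    return out
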