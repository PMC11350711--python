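"""Hypergeometric shared-miRNA test for candidate lncRNA-mRNA ceRNA pairs.

For a candidate pair, let ``K`` and ``n`` be the sizes of the mRNA's and
lncRNA's passing-miRNA sets, ``k`` their overlap, and ``N`` the miRNA
universe.  Under random draws the overlap is Hypergeometric(N, K, n); the
reported p-value is the upper tail ``P(X >= k)`` — an enrichment of shared
miRNAs, which is what the ceRNA (sponge) hypothesis predicts.  Pairs with
``p < cerna_p_max`` are the final ceRNA pairs.

The same kernel serves the enrichment module.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig

logger = logging.getLogger(__name__)

CERNA_COLUMNS = [
    "lncrna_id",
    "mrna_id",
    "shared_mirnas",
    "k",
    "K",
    "n",
    "N",
    "scc",
    "hyper_p",
    "padj",
    "final",
]


def _empty_result() -> pd.DataFrame:
    out = pd.DataFrame(columns=CERNA_COLUMNS)
    return out.astype({"final": bool, "hyper_p": float, "scc": float})


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability ``P(X >= k)``.

    ``X`` counts marked items (out of ``K`` among ``N``) in a size-``n``
    draw.  Symmetric in ``(K, n)``; ``k = 0`` gives exactly 1.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if max(K, n) > N:
        raise ValueError(f"max(K, n) = {max(K, n)} exceeds universe N = {N}")
    if k > min(K, n):
        raise ValueError(f"overlap k = {k} exceeds min(K, n) = {min(K, n)}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def mirna_partner_sets(passing_pairs: pd.DataFrame) -> tuple[dict, dict, set]:
    """Passing-miRNA sets per lncRNA and per mRNA, plus the pooled universe.

    ``passing_pairs`` is :func:`cernet.correlation.filter_mirna_pairs`
    output; only rows with ``passes`` contribute.
    """
    ok = passing_pairs[passing_pairs["passes"]]
    lnc_sets: dict[str, set] = {}
    mrna_sets: dict[str, set] = {}
    universe: set = set()
    for a, b, ptype in ok[["a_id", "b_id", "pair_type"]].itertuples(index=False):
        if ptype == "lncRNA-miRNA":
            lnc_sets.setdefault(a, set()).add(b)
            universe.add(b)
        elif ptype == "miRNA-mRNA":
            mrna_sets.setdefault(b, set()).add(a)
            universe.add(a)
    return lnc_sets, mrna_sets, universe


def score_pairs(
    candidates: pd.DataFrame,
    mirna_sets: tuple[dict, dict, set],
    cfg: RunConfig,
    universe: set | None = None,
) -> pd.DataFrame:
    """Hypergeometric test for each passing candidate lncRNA-mRNA pair.

    ``mirna_sets`` is :func:`mirna_partner_sets` output.  The universe
    defaults to the distinct miRNAs of all passing pairs
    (``cfg.mirna_universe == "passing"``); pass ``universe`` explicitly
    (e.g. all DE miRNAs) with ``cfg.mirna_universe == "all_de"``.
    Rows are sorted by ascending p, then descending correlation, then ids.
    """
    lnc_sets, mrna_sets_, pooled = mirna_sets
    if cfg.mirna_universe == "all_de":
        if universe is None:
            raise ValueError("mirna_universe='all_de' requires an explicit universe")
    else:
        universe = pooled
    N = len(universe)
    cand = candidates[candidates["passes"]]
    if N == 0:
        logger.warning("empty miRNA universe; no ceRNA pairs scored")
        return _empty_result()
    rows = []
    for lnc, mrna, scc in cand[["a_id", "b_id", "scc"]].itertuples(index=False):
        shared = lnc_sets.get(lnc, set()) & mrna_sets_.get(mrna, set())
        k = len(shared)
        if k == 0:
            continue
        K = len(mrna_sets_[mrna] & universe)
        n = len(lnc_sets[lnc] & universe)
        p = hypergeom_upper_tail(N, K, n, k)
        rows.append((lnc, mrna, tuple(sorted(shared)), k, K, n, N, scc, p))
    out = pd.DataFrame(
        rows,
        columns=["lncrna_id", "mrna_id", "shared_mirnas", "k", "K", "n", "N", "scc", "hyper_p"],
    )
    if out.empty:
        return _empty_result()
    out["padj"] = stats.false_discovery_control(out["hyper_p"], method="bh")
    out["final"] = out["hyper_p"] < cfg.cerna_p_max
    out = out.sort_values(
        ["hyper_p", "scc", "lncrna_id", "mrna_id"],
        ascending=[True, False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return out[CERNA_COLUMNS]


def write_cerna_pairs(pairs: pd.DataFrame, path) -> None:
    out = pairs.copy()
    out["shared_mirnas"] = [";".join(s) for s in out["shared_mirnas"]]
    out.to_csv(path, sep="\t", index=False)
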