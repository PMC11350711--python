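"""Hypergeometric over-representation against a local annotation table.

A stand-in for web enrichment services: the user supplies a term-to-gene
table (GO namespaces or pathways) and a query gene set; each term is scored
with the same exact hypergeometric upper-tail kernel as the ceRNA test.
The universe defaults to all genes in the annotation table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from scipy import stats

from .cerna import hypergeom_upper_tail
from .config import RunConfig

logger = logging.getLogger(__name__)

NAMESPACES = ("BP", "MF", "CC", "pathway")
RESULT_COLUMNS = [
    "term_id",
    "term_name",
    "namespace",
    "k_hits",
    "n_query",
    "K_term",
    "N_universe",
    "p",
    "padj",
    "significant",
]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns term_id, term_name, namespace, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["term_id", "term_name", "namespace", "gene_id"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"annotation {path} lacks required column '{col}'")
    bad = set(df["namespace"]) - set(NAMESPACES)
    if bad:
        raise ValueError(f"annotation {path}: unknown namespace(s) {sorted(bad)}")
    if df.duplicated(subset=["term_id", "gene_id"]).any():
        raise ValueError(f"annotation {path}: duplicate (term_id, gene_id) rows")
    return df[required]


def enrich(
    query: set,
    annot: pd.DataFrame,
    cfg: RunConfig,
    universe: set | None = None,
) -> pd.DataFrame:
    """Per-term hypergeometric over-representation of ``query``.

    Query genes outside the universe are dropped with a warning.  For a
    term annotating ``K`` universe genes, the p-value is
    ``P(X >= k_hits)`` for ``X ~ Hypergeometric(N, K, n_query)``.  Rows are
    sorted by p then term id; ``significant`` applies
    ``p < cfg.enrich_p_max`` (strict, unadjusted, as in the emulated
    workflow; a BH column is provided for reference).
    """
    if universe is None:
        universe = set(annot["gene_id"])
    if not universe:
        raise ValueError("empty gene universe")
    if not query:
        raise ValueError("empty query gene set")
    dropped = set(query) - set(universe)
    if dropped:
        logger.warning("%d query gene(s) outside the universe dropped", len(dropped))
    query_in = set(query) & set(universe)
    if not query_in:
        raise ValueError("no query genes remain after intersecting with the universe")
    N, n_query = len(universe), len(query_in)
    rows = []
    for (term_id, term_name, namespace), genes in annot.groupby(
        ["term_id", "term_name", "namespace"], sort=True
    )["gene_id"]:
        term_genes = set(genes) & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query_in)
        p = hypergeom_upper_tail(N, K, n_query, k)
        rows.append((term_id, term_name, namespace, k, n_query, K, N, p))
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-2])
    out["padj"] = stats.false_discovery_control(out["p"], method="bh") if len(out) else []
    out["significant"] = out["p"] < cfg.enrich_p_max
    return out.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
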