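"""Readers and writers for the pipeline's tabular formats.

All files are UTF-8, tab-separated, ``.`` decimal.  Count matrices are
feature-by-sample with a header row of sample ids and feature ids in the
first column.  Network exports target Cytoscape: a SIF file, a GraphML file
with full attributes, or a pair of edge/node TSV tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RNA_CLASSES = ("mRNA", "miRNA", "lncRNA")
GROUPS = ("high", "low")


@dataclass(frozen=True)
class SampleSheet:
    """Sample-to-group assignment for a two-group design.

    ``groups[i]`` is the group (``"high"`` or ``"low"``) of ``sample_ids[i]``.
    Both groups must be present with at least two samples each.
    """

    sample_ids: tuple
    groups: tuple
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.groups):
            raise ValueError("sample_ids and groups must have equal length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in GROUPS:
            n = sum(1 for x in self.groups if x == g)
            if n < 2:
                raise ValueError(f"group '{g}' needs >= 2 samples, found {n}")

    def samples_in(self, group: str) -> list:
        return [s for s, g in zip(self.sample_ids, self.groups) if g == group]

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.groups])

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class ExpressionMatrix:
    """Counts (or normalized expression) for one RNA class.

    ``data`` is a features-by-samples DataFrame whose columns follow the
    sample-sheet order.  Values must be non-negative; they may be non-integer
    (normalized matrices re-enter the pipeline), but the DE test re-validates
    integrality itself.
    """

    rna_class: str
    data: pd.DataFrame
    samples: SampleSheet

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"rna_class must be one of {RNA_CLASSES}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dup}")
        if list(self.data.columns) != list(self.samples.sample_ids):
            missing = set(self.samples.sample_ids) - set(self.data.columns)
            if missing:
                raise ValueError(f"matrix is missing sample columns: {sorted(missing)}")
            # reorder to sheet order
            self.data = self.data.loc[:, list(self.samples.sample_ids)]
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.isnan(vals).any() or (vals < 0).any():
            raise ValueError("counts must be non-negative and finite")

    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def shape(self) -> tuple:
        return self.data.shape


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV with columns ``sample_id`` and ``group`` (extra columns
    become covariates)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"sample sheet {path} lacks required column '{col}'")
    extra = [c for c in df.columns if c not in ("sample_id", "group")]
    cov = {c: dict(zip(df["sample_id"], df[c])) for c in extra}
    return SampleSheet(tuple(df["sample_id"]), tuple(df["group"]), cov)


def write_sample_sheet(samples: SampleSheet, path: str | Path) -> None:
    pd.DataFrame({"sample_id": samples.sample_ids, "group": samples.groups}).to_csv(
        path, sep="\t", index=False
    )


def read_counts(path: str | Path, rna_class: str, samples: SampleSheet) -> ExpressionMatrix:
    """Read a feature-by-sample count TSV and align columns to the sheet.

    The header row holds sample ids and the first column feature ids.
    Non-numeric cells are reported with their line number; a sheet sample
    absent from the file, or a duplicated feature id, is a hard error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s for s in samples.sample_ids if s not in df.columns]
    if missing:
        raise ValueError(f"{path}: count matrix is missing sample column(s) {missing}")
    df = df.loc[:, list(samples.sample_ids)]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        rows = np.where(bad.any(axis=1))[0]
        # +2: one for the header line, one for 1-based numbering
        lines = ", ".join(str(r + 2) for r in rows[:10])
        raise ValueError(f"{path}: non-numeric count value(s) at line(s) {lines}")
    if numeric.isna().to_numpy().any():
        rows = np.where(numeric.isna().any(axis=1))[0]
        lines = ", ".join(str(r + 2) for r in rows[:10])
        raise ValueError(f"{path}: missing count value(s) at line(s) {lines}")
    return ExpressionMatrix(rna_class, numeric, samples)


def write_counts(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_target_map(path: str | Path, provenance: str = "") -> pd.DataFrame:
    """Read predicted miRNA-target interactions.

    Columns: ``mirna_id``, ``target_id``, ``target_class`` (``mRNA`` or
    ``lncRNA``).  Duplicate edges are a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["mirna_id", "target_id", "target_class"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"target map {path} lacks required column '{col}'")
    bad = set(df["target_class"]) - {"mRNA", "lncRNA"}
    if bad:
        raise ValueError(f"target map {path}: unknown target_class value(s) {sorted(bad)}")
    if df.duplicated(subset=required).any():
        n = int(df.duplicated(subset=required).sum())
        raise ValueError(f"target map {path}: {n} duplicate edge(s)")
    df = df[required].reset_index(drop=True)
    df.attrs["provenance"] = provenance
    return df


def write_target_map(targets: pd.DataFrame, path: str | Path) -> None:
    targets.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network exports

EDGE_COLUMNS = ["source", "target", "edge_type", "scc", "regulation"]
NODE_COLUMNS = ["id", "class", "direction", "degree", "is_hub"]


def _edge_table(net) -> pd.DataFrame:
    g = net.graph
    rows = []
    for u, v, attrs in sorted(g.edges(data=True), key=lambda e: (e[2]["edge_type"], e[0], e[1])):
        # orient edges lncRNA->miRNA, miRNA->mRNA, lncRNA->mRNA
        et = attrs["edge_type"]
        first = et.split("-")[0]
        if g.nodes[u]["node_class"] != first:
            u, v = v, u
        rows.append((u, v, et, attrs["scc"], attrs["regulation"]))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def _node_table(net) -> pd.DataFrame:
    g = net.graph
    hubs = net.hubs
    rows = [
        (n, a["node_class"], a["direction"], g.degree[n], n in hubs)
        for n, a in sorted(g.nodes(data=True))
    ]
    return pd.DataFrame(rows, columns=NODE_COLUMNS)


def write_network(net, path: str | Path, dialect: str = "edge_tsv") -> None:
    """Export a ceRNA network for Cytoscape.

    ``edge_tsv`` writes ``<path>`` with columns source/target/edge_type/scc/
    regulation plus a node table next to it (``<stem>.nodes.tsv``); ``sif``
    uses the edge type as the relation token; ``graphml`` keeps all node and
    edge attributes.
    """
    net.validate()
    path = Path(path)
    if dialect == "edge_tsv":
        _edge_table(net).to_csv(path, sep="\t", index=False)
        _node_table(net).to_csv(path.with_suffix(".nodes.tsv"), sep="\t", index=False)
    elif dialect == "sif":
        edges = _edge_table(net)
        with open(path, "w", encoding="utf-8") as fh:
            for _, row in edges.iterrows():
                fh.write(f"{row['source']}\t{row['edge_type']}\t{row['target']}\n")
    elif dialect == "graphml":
        g = net.graph.copy()
        hubs = net.hubs
        for n in g.nodes:
            g.nodes[n]["degree"] = int(net.graph.degree[n])
            g.nodes[n]["is_hub"] = n in hubs
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown dialect '{dialect}'")


def read_edge_tsv(path: str | Path) -> pd.DataFrame:
    """Read back an ``edge_tsv`` network export."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != EDGE_COLUMNS:
        raise ValueError(f"{path} is not an edge_tsv export (columns {list(df.columns)})")
    return df
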