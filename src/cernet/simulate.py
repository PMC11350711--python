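"""Synthetic whole-transcriptome datasets with known ground truth.

The generator emulates the emulated study's design: two groups (high/low
growth rate) of four animals each, overdispersed (gamma-Poisson, i.e.
negative-binomial) counts for mRNA/miRNA/lncRNA, planted differentially
expressed features at a known log2 effect, and planted ceRNA triples.

Each planted triple (lncRNA, miRNA, mRNA) is driven by a per-sample latent
miRNA activity ``a_s`` = group shift (+/- lfc_de/2 in log2 units) plus a
shared jitter of SD ``sponge_strength``: the miRNA's mean scales as
``2**a_s`` and both partners as ``2**-a_s`` (a monotone, log-linear link).
This induces negative miRNA-partner and positive lncRNA-mRNA Spearman
correlations — the statistical signature the pipeline's filters look for —
while also making all three members differentially expressed.  Decoy
miRNA-target edges are added uniformly at random at a stated per-miRNA
rate.

Everything is reproducible from the single ``seed``; phenotype and qPCR
simulations draw from independent streams derived from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleSheet

DEFAULT_PHENOTYPE_TRAITS = {
    "live_weight_at_slaughter_kg": ((148.38, 8.97), (88.75, 9.13)),
    "muscle_fiber_diameter_um": ((40.87, 3.85), (40.34, 5.68)),
}


@dataclass
class SimParams:
    """Generator settings; defaults are the emulated study conditions.

    ``sponge_strength`` is the SD (log2 units) of the shared latent-activity
    jitter within groups; its default was calibrated once so that planted
    pairs exceed the |SCC| thresholds with high probability at n = 8 (see
    the methods note).  ``frac_de_*`` set how many extra DE features are
    planted per class beyond the triple members.
    """

    n_per_group: int = 4
    n_mrna: int = 200
    n_mirna: int = 50
    n_lncrna: int = 100
    frac_de_mrna: float = 0.1
    frac_de_mirna: float = 0.5
    frac_de_lncrna: float = 0.1
    lfc_de: float = 2.0
    nb_dispersion: float = 0.3
    dispersion_spread: float = 0.25
    triple_dispersion: float = 0.02
    n_triples: int = 20
    sponge_strength: float = 0.6
    decoy_targets_per_mirna: int = 2
    base_log_mean: float = 5.0
    base_log_sd: float = 1.5
    triple_base_min: float = 300.0
    triple_base_max: float = 1000.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_triples > min(self.n_mrna, self.n_mirna, self.n_lncrna):
            raise ValueError(
                f"n_triples = {self.n_triples} exceeds the smallest class size "
                f"{min(self.n_mrna, self.n_mirna, self.n_lncrna)}"
            )
        for name in ("frac_de_mrna", "frac_de_mirna", "frac_de_lncrna"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0 or self.triple_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset.

    ``de`` maps RNA class to a table of planted DE features with their
    direction (triple members included); ``triples`` lists the planted
    (lncRNA, miRNA, mRNA) ids; ``target_map`` is the full generated
    interaction table including decoys.
    """

    de: dict = field(default_factory=dict)
    triples: pd.DataFrame = None
    target_map: pd.DataFrame = None

    @property
    def planted_pairs(self) -> set:
        """The planted (lncRNA, mRNA) ceRNA pairs."""
        return {
            (l, m) for l, m in self.triples[["lncrna_id", "mrna_id"]].itertuples(index=False)
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de": {cls: t.to_dict(orient="records") for cls, t in self.de.items()},
            "triples": self.triples.to_dict(orient="records"),
            "target_map": self.target_map.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """Gamma-mixed Poisson draws with Var = mu + dispersion * mu^2.

    ``dispersion`` is per-feature and broadcast across samples.
    """
    disp = np.asarray(dispersion, dtype=float)[:, None]
    lam = rng.gamma(1.0 / disp, mean * disp)
    return rng.poisson(lam).astype(np.int64)


def _sample_sheet(n_per_group: int) -> SampleSheet:
    ids = [f"H{i+1}" for i in range(n_per_group)] + [f"L{i+1}" for i in range(n_per_group)]
    groups = ["high"] * n_per_group + ["low"] * n_per_group
    return SampleSheet(tuple(ids), tuple(groups))


def simulate_dataset(
    params: SimParams,
) -> tuple[dict, pd.DataFrame, GroundTruth]:
    """Generate the three count matrices, a target map, and ground truth.

    Returns ``(matrices, target_map, truth)`` where ``matrices`` maps
    ``"mRNA"``/``"miRNA"``/``"lncRNA"`` to :class:`ExpressionMatrix`.
    """
    rng = np.random.default_rng(params.seed)
    samples = _sample_sheet(params.n_per_group)
    n = len(samples)
    hi_mask = samples.group_mask("high")
    group_shift = np.where(hi_mask, params.lfc_de / 2, -params.lfc_de / 2)

    sizes = {"mRNA": params.n_mrna, "miRNA": params.n_mirna, "lncRNA": params.n_lncrna}
    prefixes = {"mRNA": "mRNA", "miRNA": "miR", "lncRNA": "lnc"}
    ids = {
        cls: [f"{prefixes[cls]}_{i:04d}" for i in range(sizes[cls])] for cls in sizes
    }
    frac_de = {
        "mRNA": params.frac_de_mrna,
        "miRNA": params.frac_de_mirna,
        "lncRNA": params.frac_de_lncrna,
    }

    # planted triples use the first n_triples features of each class; extra
    # independent DE features are drawn from the remainder
    triple_idx = {cls: np.arange(params.n_triples) for cls in sizes}
    log2_shift = {cls: np.zeros((sizes[cls], n)) for cls in sizes}
    de_records: dict[str, list] = {cls: [] for cls in sizes}

    for t in range(params.n_triples):
        jitter = rng.normal(0.0, params.sponge_strength, n)
        sign = 1.0 if t % 2 == 0 else -1.0  # alternate miRNA up/down in high
        activity = sign * group_shift + jitter
        log2_shift["miRNA"][t] = activity
        log2_shift["lncRNA"][t] = -activity
        log2_shift["mRNA"][t] = -activity
        mi_dir = "up" if sign > 0 else "down"
        partner_dir = "down" if sign > 0 else "up"
        de_records["miRNA"].append((ids["miRNA"][t], mi_dir))
        de_records["lncRNA"].append((ids["lncRNA"][t], partner_dir))
        de_records["mRNA"].append((ids["mRNA"][t], partner_dir))

    for cls in sizes:
        n_extra = round(frac_de[cls] * sizes[cls])
        pool = np.arange(params.n_triples, sizes[cls])
        if n_extra > pool.size:
            raise ValueError(
                f"{cls}: cannot plant {n_extra} extra DE features with only "
                f"{pool.size} non-triple features"
            )
        chosen = rng.choice(pool, size=n_extra, replace=False)
        for j, f in enumerate(chosen):
            sign = 1.0 if j % 2 == 0 else -1.0
            log2_shift[cls][f] = sign * group_shift
            de_records[cls].append((ids[cls][f], "up" if sign > 0 else "down"))

    matrices = {}
    for cls in ("mRNA", "miRNA", "lncRNA"):
        mu = rng.lognormal(params.base_log_mean, params.base_log_sd, sizes[cls])
        if params.n_triples:
            mu[triple_idx[cls]] = rng.uniform(
                params.triple_base_min, params.triple_base_max, params.n_triples
            )
        disp = params.nb_dispersion * rng.lognormal(0.0, params.dispersion_spread, sizes[cls])
        if params.n_triples:
            # sponge members are tightly co-regulated: the latent activity,
            # not residual dispersion, must dominate their ranks
            disp[triple_idx[cls]] = params.triple_dispersion
        mean_matrix = mu[:, None] * np.power(2.0, log2_shift[cls])
        counts = _nb_counts(rng, mean_matrix, disp)
        df = pd.DataFrame(counts, index=ids[cls], columns=list(samples.sample_ids))
        matrices[cls] = ExpressionMatrix(cls, df, samples)

    # target map: planted edges first, then uniform decoys
    edges = []
    for t in range(params.n_triples):
        mi = ids["miRNA"][t]
        edges.append((mi, ids["lncRNA"][t], "lncRNA"))
        edges.append((mi, ids["mRNA"][t], "mRNA"))
    seen = set(edges)
    all_targets = [(fid, "mRNA") for fid in ids["mRNA"]] + [
        (fid, "lncRNA") for fid in ids["lncRNA"]
    ]
    for mi in ids["miRNA"]:
        picks = rng.choice(len(all_targets), size=params.decoy_targets_per_mirna, replace=False)
        for pidx in picks:
            target, tclass = all_targets[pidx]
            edge = (mi, target, tclass)
            if edge not in seen:
                seen.add(edge)
                edges.append(edge)
    target_map = pd.DataFrame(edges, columns=["mirna_id", "target_id", "target_class"])
    target_map.attrs["provenance"] = "simulated"

    truth = GroundTruth(
        de={
            cls: pd.DataFrame(de_records[cls], columns=["feature_id", "direction"])
            for cls in sizes
        },
        triples=pd.DataFrame(
            [
                (ids["lncRNA"][t], ids["miRNA"][t], ids["mRNA"][t])
                for t in range(params.n_triples)
            ],
            columns=["lncrna_id", "mirna_id", "mrna_id"],
        ),
        target_map=target_map,
    )
    # generator contract: every planted miRNA maps to both partners
    planted = set(
        (r.mirna_id, r.lncrna_id) for r in truth.triples.itertuples(index=False)
    ) | set((r.mirna_id, r.mrna_id) for r in truth.triples.itertuples(index=False))
    assert planted <= set(zip(target_map["mirna_id"], target_map["target_id"]))
    return matrices, target_map, truth


def simulate_phenotypes(
    params: SimParams, traits: dict | None = None
) -> pd.DataFrame:
    """Per-animal phenotype draws (long format: trait, group, animal, value).

    ``traits`` maps a trait name to ``((mean_high, sd_high),
    (mean_low, sd_low))``; the default plants the live-weight and
    fiber-diameter group summaries of the emulated study.
    """
    traits = DEFAULT_PHENOTYPE_TRAITS if traits is None else traits
    rng = np.random.default_rng([params.seed, 7])
    samples = _sample_sheet(params.n_per_group)
    rows = []
    for trait, ((m_hi, s_hi), (m_lo, s_lo)) in traits.items():
        for sid, group in zip(samples.sample_ids, samples.groups):
            mean, sd = (m_hi, s_hi) if group == "high" else (m_lo, s_lo)
            rows.append((trait, group, sid, rng.normal(mean, sd) if sd > 0 else mean))
    return pd.DataFrame(rows, columns=["trait", "group", "animal", "value"])


def simulate_qpcr(
    truth: GroundTruth,
    params: SimParams,
    genes: list | None = None,
    reference: str = "GAPDH",
    n_replicates: int = 3,
    noise_sd: float = 0.15,
    baseline_ct: float = 30.0,
) -> pd.DataFrame:
    """Ct tables for planted DE genes plus a flat reference gene.

    The Ct model is ``Ct = baseline - log2(expression) + noise`` with
    per-replicate technical noise; a planted gene's group log2 expression
    ratio is ``+/- lfc_de``, so the 2^-ddCt analysis should recover a
    fold-change of ``2**lfc_de`` up to noise.  The reference gene is flat
    across groups.
    """
    de_mrna = truth.de["mRNA"]
    if genes is None:
        genes = list(de_mrna["feature_id"].head(3))
    directions = dict(zip(de_mrna["feature_id"], de_mrna["direction"]))
    unknown = [g for g in genes if g not in directions]
    if unknown:
        raise ValueError(f"gene(s) {unknown} are not planted DE mRNAs")
    rng = np.random.default_rng([params.seed, 13])
    samples = _sample_sheet(params.n_per_group)
    rows = []
    for gene in list(genes) + [reference]:
        for sid, group in zip(samples.sample_ids, samples.groups):
            if gene == reference:
                log2_expr = 0.0
            else:
                sign = 1.0 if directions[gene] == "up" else -1.0
                log2_expr = sign * (params.lfc_de / 2 if group == "high" else -params.lfc_de / 2)
            for rep in range(1, n_replicates + 1):
                ct = baseline_ct - log2_expr + rng.normal(0.0, noise_sd)
                rows.append((sid, gene, rep, ct))
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "replicate", "ct"])
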