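"""End-to-end orchestration: counts in, ceRNA network out.

``run_cerna_pipeline`` chains the stages exactly as the emulated workflow
does: per-class DE calling at |log2FC| >= 1 and p < 0.05, Spearman
filtering of predicted miRNA-target pairs at SCC < -0.7, candidate
lncRNA-mRNA pairs at SCC > 0.9, the hypergeometric shared-miRNA test at
p < 0.05, and network assembly with hub calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cerna import mirna_partner_sets, score_pairs
from .config import RunConfig
from .correlation import candidate_cerna_pairs, filter_mirna_pairs, normalized_expression
from .de import classify_de, nb_wald_test
from .io import ExpressionMatrix
from .network import CeRNANetwork, build_network
from .simulate import GroundTruth


@dataclass
class PipelineResult:
    de: dict = field(default_factory=dict)  # class -> classified DE table
    de_counts: dict = field(default_factory=dict)  # class -> (n_up, n_down)
    passing_pairs: pd.DataFrame = None
    candidates: pd.DataFrame = None
    cerna_pairs: pd.DataFrame = None
    network: CeRNANetwork = None

    @property
    def final_pairs(self) -> set:
        if self.cerna_pairs is None or self.cerna_pairs.empty:
            return set()
        fin = self.cerna_pairs[self.cerna_pairs["final"]]
        return set(zip(fin["lncrna_id"], fin["mrna_id"]))


def run_cerna_pipeline(
    matrices: dict[str, ExpressionMatrix],
    target_map: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> PipelineResult:
    """Run DE, correlation filtering, the ceRNA test and network assembly.

    ``matrices`` maps ``"mRNA"``/``"miRNA"``/``"lncRNA"`` to count
    matrices over the same sample sheet.
    """
    cfg = cfg or RunConfig()
    sheets = {tuple(m.samples.sample_ids) for m in matrices.values()}
    if len(sheets) != 1:
        raise ValueError("all matrices must share the same samples")
    result = PipelineResult()
    for cls, mat in matrices.items():
        table, counts = classify_de(nb_wald_test(mat), cfg)
        result.de[cls] = table
        result.de_counts[cls] = counts
    expr = normalized_expression(matrices)
    result.passing_pairs = filter_mirna_pairs(target_map, result.de, expr, cfg)
    result.candidates = candidate_cerna_pairs(
        target_map, result.de, expr, cfg, passing_pairs=result.passing_pairs
    )
    sets = mirna_partner_sets(result.passing_pairs)
    universe = None
    if cfg.mirna_universe == "all_de":
        de_mi = result.de["miRNA"]
        universe = set(de_mi.loc[de_mi["significant"], "feature_id"])
    result.cerna_pairs = score_pairs(result.candidates, sets, cfg, universe=universe)
    result.network = build_network(
        result.cerna_pairs,
        result.passing_pairs,
        result.de,
        include_lnc_mrna_edges=cfg.include_lnc_mrna_edges,
    )
    return result


def evaluate_recovery(result: PipelineResult, truth: GroundTruth) -> dict:
    """Recall and precision of the final ceRNA pairs against planted truth."""
    found = result.final_pairs
    planted = truth.planted_pairs
    tp = len(found & planted)
    return {
        "n_final": len(found),
        "n_planted": len(planted),
        "true_positives": tp,
        "recall": tp / len(planted) if planted else float("nan"),
        "precision": tp / len(found) if found else float("nan"),
    }
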