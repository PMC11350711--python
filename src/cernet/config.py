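"""Pipeline thresholds and run configuration.

Defaults are the thresholds of the study design this package emulates:
differential expression at |log2 fold-change| >= 1 and p < 0.05, Spearman
filters at SCC < -0.7 (miRNA-target) and SCC > 0.9 (lncRNA-mRNA), and
p < 0.05 for both the hypergeometric ceRNA test and enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Thresholds, seed and paths shared across pipeline stages.

    Parameters
    ----------
    lfc_min
        Minimum absolute log2 fold-change for a feature to be called
        differentially expressed (default 1, i.e. linear fold-change 2).
    p_max
        DE p-value threshold (strict ``<``).
    scc_neg_max
        Upper bound (strict) on Spearman correlation for candidate
        miRNA-target pairs; pairs must be more negative than this.
    scc_pos_min
        Lower bound (strict) on Spearman correlation for candidate
        lncRNA-mRNA ceRNA pairs.
    cerna_p_max
        Threshold (strict) on the hypergeometric shared-miRNA p-value.
    enrich_p_max
        Threshold (strict) on the enrichment p-value.
    mirna_universe
        ``"all_de"`` (default) uses all significant DE miRNAs as the
        hypergeometric universe; ``"passing"`` draws it from the miRNAs
        seen in correlation-passing pairs (degenerate for sparse target
        maps, see the methods note).
    include_lnc_mrna_edges
        Whether lncRNA-mRNA edges enter the network (and its degrees).
    """

    lfc_min: float = 1.0
    p_max: float = 0.05
    scc_neg_max: float = -0.7
    scc_pos_min: float = 0.9
    cerna_p_max: float = 0.05
    enrich_p_max: float = 0.05
    seed: int = 0
    mirna_universe: str = "all_de"
    include_lnc_mrna_edges: bool = True
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("p_max", "cerna_p_max", "enrich_p_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not self.scc_neg_max < 0 < self.scc_pos_min:
            raise ValueError(
                "scc_neg_max must be negative and scc_pos_min positive, got "
                f"{self.scc_neg_max} / {self.scc_pos_min}"
            )
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be non-negative")
        if self.mirna_universe not in ("passing", "all_de"):
            raise ValueError("mirna_universe must be 'passing' or 'all_de'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
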