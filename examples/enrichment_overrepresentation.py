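"""Hypergeometric over-representation of a DE gene set against a local
term-annotation table.

A small muscle-flavoured annotation stands in for a GO/pathway download;
the query is enriched for the glycogen-metabolism term, so that term should
surface with a small p-value while the broad background term stays at 1.
"""

import pandas as pd

from cernet import RunConfig, enrich

annotation = pd.DataFrame(
    [
        ("P1", "glycogen metabolism", "pathway", g)
        for g in ["PYGM", "PPP1R3A", "PGAM2", "GYS1"]
    ]
    + [
        ("P2", "muscle contraction", "pathway", g)
        for g in ["MYH1", "MYH7", "TNNT3", "ACTN3", "MYBPC1"]
    ]
    + [("P3", "housekeeping", "BP", f"HK{i}") for i in range(30)],
    columns=["term_id", "term_name", "namespace", "gene_id"],
)

query = {"PYGM", "PPP1R3A", "PGAM2", "MYH7"}
result = enrich(query, annotation, RunConfig())
print("Query:", sorted(query))
print(result.round(4).to_string(index=False))
print("\np is the exact hypergeometric upper tail P(X >= k_hits) for k_hits "
      "of the K_term annotated genes appearing in an n_query-gene draw from "
      "the N_universe annotated genes; 'significant' applies p < 0.05.")
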