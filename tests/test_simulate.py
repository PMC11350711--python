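import numpy as np
import pandas as pd
import pytest

from cernet import (
    RunConfig,
    SimParams,
    classify_de,
    nb_wald_test,
    run_cerna_pipeline,
    simulate_dataset,
    simulate_phenotypes,
    spearman_scc,
    t_test_from_summary,
)
from cernet.correlation import normalized_expression
from cernet.phenotype import GroupSummary


class TestDeterminism:
    def test_same_seed_is_byte_identical(self):
        a_mats, a_map, a_truth = simulate_dataset(SimParams(seed=5))
        b_mats, b_map, b_truth = simulate_dataset(SimParams(seed=5))
        for cls in a_mats:
            pd.testing.assert_frame_equal(a_mats[cls].data, b_mats[cls].data)
        pd.testing.assert_frame_equal(a_map, b_map)
        pd.testing.assert_frame_equal(a_truth.triples, b_truth.triples)

    def test_distinct_seeds_differ(self):
        a, _, _ = simulate_dataset(SimParams(seed=5))
        b, _, _ = simulate_dataset(SimParams(seed=6))
        assert not a["mRNA"].data.equals(b["mRNA"].data)

    def test_phenotype_and_qpcr_streams_are_seeded(self):
        params = SimParams(seed=5)
        pd.testing.assert_frame_equal(
            simulate_phenotypes(params), simulate_phenotypes(params)
        )


class TestGroundTruth:
    def test_planted_mirna_targets_both_partners(self):
        _, tmap, truth = simulate_dataset(SimParams(seed=1))
        edges = set(zip(tmap["mirna_id"], tmap["target_id"]))
        for row in truth.triples.itertuples(index=False):
            assert (row.mirna_id, row.lncrna_id) in edges
            assert (row.mirna_id, row.mrna_id) in edges

    def test_infeasible_params_rejected(self):
        with pytest.raises(ValueError, match="n_triples"):
            SimParams(n_triples=60, n_mirna=50)
        with pytest.raises(ValueError):
            SimParams(frac_de_mrna=1.5)

    def test_truth_json_round_trip(self, tmp_path):
        _, _, truth = simulate_dataset(SimParams(seed=1, n_triples=2))
        path = tmp_path / "truth.json"
        truth.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert len(payload["triples"]) == 2


class TestPlantedStructure:
    def test_planted_log2_ratio_matches_effect(self):
        params = SimParams(seed=2, n_per_group=24)
        mats, _, truth = simulate_dataset(params)
        expr = mats["mRNA"].data
        hi = expr.loc[:, [c for c in expr if c.startswith("H")]].mean(axis=1)
        lo = expr.loc[:, [c for c in expr if c.startswith("L")]].mean(axis=1)
        de = truth.de["mRNA"]
        for fid, direction in de.itertuples(index=False):
            ratio = np.log2((hi[fid] + 0.5) / (lo[fid] + 0.5))
            expected = params.lfc_de if direction == "up" else -params.lfc_de
            assert ratio == pytest.approx(expected, abs=1.0)

    def test_sponge_scc_contract_over_seeds(self):
        """Averaged over 50 seeds at the default n = 4 per group, planted
        miRNA-partner SCC is below -0.7 and lncRNA-mRNA SCC above 0.9 —
        the generator contract that makes the pipeline thresholds
        meaningful at the study's sample size."""
        neg, pos = [], []
        for seed in range(50):
            mats, _, truth = simulate_dataset(SimParams(seed=seed, n_triples=5))
            expr = normalized_expression(mats)
            for row in truth.triples.itertuples(index=False):
                neg.append(
                    spearman_scc(expr["miRNA"].loc[row.mirna_id], expr["mRNA"].loc[row.mrna_id])
                )
                pos.append(
                    spearman_scc(expr["lncRNA"].loc[row.lncrna_id], expr["mRNA"].loc[row.mrna_id])
                )
        assert np.mean(neg) < -0.7
        assert np.mean(pos) > 0.9

    def test_null_dataset_is_null(self):
        params = SimParams(
            seed=3, n_mrna=2000, frac_de_mrna=0.0, frac_de_mirna=0.0,
            frac_de_lncrna=0.0, n_triples=0,
        )
        mats, tmap, truth = simulate_dataset(params)
        assert truth.triples.empty
        res = nb_wald_test(mats["mRNA"])
        frac = (res["p_value"] < 0.05).mean()
        assert 0.02 < frac < 0.09  # near-nominal false-positive rate
        out = run_cerna_pipeline(mats, tmap)
        assert len(out.final_pairs) <= 2  # no planted structure to find

    def test_planted_case_dwarfs_null_cerna_count(self):
        mats, tmap, _ = simulate_dataset(SimParams(seed=4, n_per_group=12))
        planted_count = len(run_cerna_pipeline(mats, tmap).final_pairs)
        null_mats, null_map, _ = simulate_dataset(
            SimParams(seed=4, n_per_group=12, frac_de_mrna=0.0, frac_de_mirna=0.0,
                      frac_de_lncrna=0.0, n_triples=0)
        )
        null_count = len(run_cerna_pipeline(null_mats, null_map).final_pairs)
        assert planted_count >= 15
        assert null_count <= 2
        assert null_count < planted_count / 5


class TestPhenotypeSimulation:
    def test_planted_live_weight_split_recovers_letters(self):
        hits = 0
        for seed in range(20):
            table = simulate_phenotypes(SimParams(seed=seed))
            lw = table[table["trait"] == "live_weight_at_slaughter_kg"]
            hi = lw.loc[lw["group"] == "high", "value"]
            lo = lw.loc[lw["group"] == "low", "value"]
            res = t_test_from_summary(
                GroupSummary("high", hi.mean(), hi.std(ddof=1), len(hi)),
                GroupSummary("low", lo.mean(), lo.std(ddof=1), len(lo)),
            )
            if res.letters == ("A", "B"):
                hits += 1
        assert hits >= 16  # the planted split is highly significant "in most replicates"

    def test_equal_means_are_null(self):
        traits = {"flat": ((10.0, 1.0), (10.0, 1.0))}
        ps = []
        for seed in range(100):
            table = simulate_phenotypes(SimParams(seed=seed), traits=traits)
            hi = table.loc[table["group"] == "high", "value"]
            lo = table.loc[table["group"] == "low", "value"]
            res = t_test_from_summary(
                GroupSummary("h", hi.mean(), hi.std(ddof=1), 4),
                GroupSummary("l", lo.mean(), lo.std(ddof=1), 4),
            )
            ps.append(res.p)
        assert 0.0 <= np.mean(np.array(ps) < 0.05) <= 0.12

    def test_zero_sd_split(self):
        traits = {"exact": ((5.0, 0.0), (4.0, 0.0))}
        table = simulate_phenotypes(SimParams(seed=0), traits=traits)
        hi = table.loc[table["group"] == "high", "value"]
        lo = table.loc[table["group"] == "low", "value"]
        with pytest.warns(UserWarning):
            res = t_test_from_summary(
                GroupSummary("h", hi.mean(), hi.std(ddof=1), 4),
                GroupSummary("l", lo.mean(), lo.std(ddof=1), 4),
            )
        assert res.p == 0.0
        assert res.letters == ("A", "B")
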