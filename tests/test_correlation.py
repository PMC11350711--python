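import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cernet import RunConfig, candidate_cerna_pairs, filter_mirna_pairs, spearman_scc
from conftest import naive_spearman


class TestSpearmanKernel:
    def test_monotone_vectors(self):
        assert spearman_scc([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_scc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_classical_formula_example(self):
        # d = (1, -1, 1, -1, 0), sum d^2 = 4: 1 - 6*4/(5*24) = 0.8
        assert spearman_scc([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_constant_vector_is_undefined(self):
        assert np.isnan(spearman_scc([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError, match="mismatch"):
            spearman_scc([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="at least 3"):
            spearman_scc([1, 2], [1, 2])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.integers(min_value=0, max_value=8), min_size=4, max_size=12),
        st.data(),
    )
    def test_ties_agree_with_average_rank_oracle(self, xs, data):
        ys = data.draw(
            st.lists(
                st.integers(min_value=0, max_value=8), min_size=len(xs), max_size=len(xs)
            )
        )
        if len(set(xs)) < 2 or len(set(ys)) < 2:
            return
        assert spearman_scc(xs, ys) == pytest.approx(naive_spearman(xs, ys))

    @settings(derandomize=True, max_examples=200)
    @given(st.permutations(list(range(8))))
    def test_invariant_under_monotone_transform(self, ys):
        x = np.arange(8.0)
        y = np.asarray(ys, dtype=float)
        base = spearman_scc(x, y)
        assert spearman_scc(np.exp(x / 3), y) == pytest.approx(base)
        assert spearman_scc(x, y**3 + 5 * y) == pytest.approx(base)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x, y = rng.normal(size=10), rng.normal(size=10)
            s = spearman_scc(x, y)
            assert -1 <= s <= 1
            assert s == pytest.approx(spearman_scc(y, x))


def _expr_frames(sheet):
    """Expression where miR_a anti-tracks lnc_a/mRNA_a perfectly and miR_b
    is unrelated noise."""
    n = len(sheet)
    up = np.arange(1.0, n + 1)
    rng = np.random.default_rng(7)
    return {
        "miRNA": pd.DataFrame(
            [up[::-1], rng.permutation(up)],
            index=["miR_a", "miR_b"],
            columns=list(sheet.sample_ids),
        ),
        "mRNA": pd.DataFrame([up], index=["mRNA_a"], columns=list(sheet.sample_ids)),
        "lncRNA": pd.DataFrame([up], index=["lnc_a"], columns=list(sheet.sample_ids)),
    }


def _de_frames(sig=True):
    def table(fid):
        return pd.DataFrame(
            {"feature_id": [fid], "direction": ["up"], "significant": [sig]}
        )

    return {
        "miRNA": pd.concat([table("miR_a"), table("miR_b")], ignore_index=True),
        "mRNA": table("mRNA_a"),
        "lncRNA": table("lnc_a"),
    }


def _targets(rows):
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class"])


class TestPairFiltering:
    def test_strict_negative_threshold(self, sheet44, cfg):
        expr = _expr_frames(sheet44)
        targets = _targets([("miR_a", "mRNA_a", "mRNA")])
        out = filter_mirna_pairs(targets, _de_frames(), expr, cfg)
        assert out["scc"].iloc[0] == pytest.approx(-1.0)
        assert bool(out["passes"].iloc[0])
        # with the threshold AT -1, a perfect -1 must not pass (strict "<")
        strict = RunConfig(scc_neg_max=-1.0)
        out = filter_mirna_pairs(targets, _de_frames(), expr, strict)
        assert not out["passes"].any()

    def test_non_de_endpoints_are_never_scored(self, sheet44, cfg):
        expr = _expr_frames(sheet44)
        targets = _targets([("miR_a", "mRNA_a", "mRNA")])
        out = filter_mirna_pairs(targets, _de_frames(sig=False), expr, cfg)
        assert out.empty

    def test_unknown_feature_skipped_and_counted(self, sheet44, cfg):
        expr = _expr_frames(sheet44)
        de = _de_frames()
        de["mRNA"] = pd.concat(
            [de["mRNA"], pd.DataFrame({"feature_id": ["ghost"], "direction": ["up"], "significant": [True]})],
            ignore_index=True,
        )
        targets = _targets([("miR_a", "ghost", "mRNA"), ("miR_a", "mRNA_a", "mRNA")])
        out = filter_mirna_pairs(targets, de, expr, cfg)
        assert len(out) == 1
        assert out.attrs["n_skipped"] == 1

    def test_cerna_candidates_require_shared_mirna(self, sheet44, cfg):
        expr = _expr_frames(sheet44)
        de = _de_frames()
        # lnc_a passes with miR_a, but mRNA_a's only edge is miR_b (noise)
        targets = _targets([("miR_a", "lnc_a", "lncRNA"), ("miR_b", "mRNA_a", "mRNA")])
        out = candidate_cerna_pairs(targets, de, expr, cfg)
        assert out.empty

    def test_cerna_strict_positive_threshold(self, sheet44):
        expr = _expr_frames(sheet44)
        de = _de_frames()
        targets = _targets([("miR_a", "lnc_a", "lncRNA"), ("miR_a", "mRNA_a", "mRNA")])
        cfg = RunConfig()
        out = candidate_cerna_pairs(targets, de, expr, cfg)
        assert len(out) == 1
        assert out["scc"].iloc[0] == pytest.approx(1.0)  # identical rank vectors
        assert bool(out["passes"].iloc[0])
        strict = RunConfig(scc_pos_min=1.0)
        out = candidate_cerna_pairs(targets, de, expr, strict)
        assert not out["passes"].any()

    def test_tightening_thresholds_shrinks_candidate_sets(self, cfg):
        rng = np.random.default_rng(11)
        from cernet import SimParams, simulate_dataset
        from cernet.correlation import normalized_expression

        mats, tmap, _ = simulate_dataset(SimParams(seed=5, n_per_group=6))
        from cernet import classify_de, nb_wald_test

        de = {c: classify_de(nb_wald_test(m), cfg)[0] for c, m in mats.items()}
        expr = normalized_expression(mats)
        loose = filter_mirna_pairs(tmap, de, expr, RunConfig(scc_neg_max=-0.5))
        tight = filter_mirna_pairs(tmap, de, expr, RunConfig(scc_neg_max=-0.9))
        assert set(map(tuple, tight[tight.passes][["a_id", "b_id"]].values)) <= set(
            map(tuple, loose[loose.passes][["a_id", "b_id"]].values)
        )
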