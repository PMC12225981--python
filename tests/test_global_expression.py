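from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from te_karyoscan.annotations_io import AnnotationError, CountMatrix, RosettaMap, SampleSheet
from te_karyoscan.global_expression import (
    TeSubset,
    adjusted_sex_effect_test,
    build_te_subsets,
    flag_aneuploidy_suspects,
    global_te_proportion,
    multi_group_test,
    pairwise_group_test,
)


def mixed_matrix(gene_rows, te_rows):
    data = pd.DataFrame({**gene_rows, **te_rows}).T.astype(float)
    kinds = pd.Series(
        ["gene"] * len(gene_rows) + ["te_subfamily"] * len(te_rows), index=data.index
    )
    return CountMatrix(data, feature_kind="mixed", normalized=True, row_kinds=kinds)


def rank_sum_enumeration_p(x, y):
    """Brute-force exact two-sided rank-sum p over all labelings."""
    from itertools import combinations as combos

    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:n].sum()
    mean = n * (len(pooled) + 1) / 2
    stats_all = [
        ranks[list(idx)].sum() for idx in combos(range(len(pooled)), n)
    ]
    extreme = sum(1 for s in stats_all if abs(s - mean) >= abs(obs - mean) - 1e-9)
    return extreme / len(stats_all)


class TestGlobalProportion:
    def test_simple_arithmetic(self):
        m = mixed_matrix({"g": {"s1": 900.0}}, {"A": {"s1": 100.0}})
        prop = global_te_proportion(m)
        assert np.isclose(prop["s1"], 0.10)

    def test_empty_subset_gives_zero(self):
        m = mixed_matrix({"g": {"s1": 900.0}}, {"A": {"s1": 100.0}})
        prop = global_te_proportion(m, TeSubset("NONE", frozenset()))
        assert prop["s1"] == 0.0

    def test_class_subset_hand_computation(self):
        te = {
            "A": {"s1": 10.0, "s2": 20.0},
            "B": {"s1": 5.0, "s2": 5.0},
            "C": {"s1": 1.0, "s2": 2.0},
            "D": {"s1": 4.0, "s2": 0.0},
            "E": {"s1": 0.0, "s2": 3.0},
        }
        genes = {"g1": {"s1": 80.0, "s2": 70.0}}
        m = mixed_matrix(genes, te)
        ltr = TeSubset("LTR", frozenset({"A", "B"}))
        prop = global_te_proportion(m, ltr)
        # denominator includes genes + ALL TE subfamilies
        assert np.isclose(prop["s1"], (10 + 5) / (80 + 20))
        assert np.isclose(prop["s2"], (20 + 5) / (70 + 30))

    def test_singleton_partition_sums_to_all(self):
        rng = np.random.default_rng(0)
        te = {f"t{i}": {"s1": float(v)} for i, v in enumerate(rng.integers(0, 50, 10))}
        m = mixed_matrix({"g": {"s1": 500.0}}, te)
        total = sum(
            global_te_proportion(m, TeSubset(k, frozenset({k})))["s1"] for k in te
        )
        assert np.isclose(total, global_te_proportion(m)["s1"])

    def test_zero_total_sample_rejected(self):
        m = mixed_matrix({"g": {"s1": 0.0}}, {"A": {"s1": 0.0}})
        with pytest.raises(AnnotationError, match="zero total"):
            global_te_proportion(m)


class TestPairwiseGroupTest:
    def test_exact_separated_groups(self):
        values = pd.Series([1, 2, 3, 4, 5, 6.0], index=list("abcdef"))
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=values.index)
        res = pairwise_group_test(values, groups)
        assert np.isclose(res.pairwise_p[("A", "B")], 0.1)  # 2/20 labelings

    def test_identical_groups_give_p_one(self):
        values = pd.Series([1, 2, 3, 1, 2, 3.0], index=list("abcdef"))
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=values.index)
        res = pairwise_group_test(values, groups)
        assert res.pairwise_p[("A", "B")] > 0.99

    def test_three_groups_emit_three_pvalues(self):
        values = pd.Series(np.arange(9.0), index=[f"s{i}" for i in range(9)])
        groups = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 3, index=values.index)
        res = pairwise_group_test(values, groups)
        assert len(res.pairwise_p) == 3

    def test_label_symmetry(self):
        rng = np.random.default_rng(1)
        values = pd.Series(rng.normal(size=10), index=[f"s{i}" for i in range(10)])
        g1 = pd.Series(["A"] * 5 + ["B"] * 5, index=values.index)
        g2 = g1.map({"A": "B", "B": "A"})
        p1 = pairwise_group_test(values, g1).pairwise_p[("A", "B")]
        p2 = pairwise_group_test(values, g2).pairwise_p[("B", "A")]
        assert p1 == p2

    def test_small_group_rejected(self):
        values = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        groups = pd.Series(["A", "A", "B"], index=values.index)
        with pytest.raises(AnnotationError, match="<2"):
            pairwise_group_test(values, groups)

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(2, 5),
        m=st.integers(2, 5),
        seed=st.integers(0, 10**6),
    )
    def test_exact_branch_matches_enumeration(self, n, m, seed):
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1.0, n + m + 1))  # distinct -> no ties
        x, y = pooled[:n], pooled[n:]
        values = pd.Series(
            np.concatenate([x, y]), index=[f"s{i}" for i in range(n + m)]
        )
        groups = pd.Series(["A"] * n + ["B"] * m, index=values.index)
        p = pairwise_group_test(values, groups).pairwise_p[("A", "B")]
        assert np.isclose(p, rank_sum_enumeration_p(x, y), atol=1e-12)


class TestMultiGroupTest:
    def test_identical_values_degenerate_p_one(self):
        values = pd.Series([2.0] * 8, index=[f"s{i}" for i in range(8)])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=values.index)
        assert multi_group_test(values, groups) == 1.0

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 20)
        b = rng.normal(3, 1, 20)
        values = pd.Series(np.r_[a, b], index=[f"s{i}" for i in range(40)])
        groups = pd.Series(["A"] * 20 + ["B"] * 20, index=values.index)
        assert multi_group_test(values, groups) < 1e-3

    def test_null_calibration(self):
        # groups drawn from one distribution: rejection near alpha
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            values = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
            groups = pd.Series(
                ["A"] * 10 + ["B"] * 10 + ["C"] * 10, index=values.index
            )
            rejections += multi_group_test(values, groups) < 0.05
        assert 0.03 <= rejections / reps <= 0.07


def sheet_with(sex, age, index):
    karyo = ["XX" if s == "female" else "XY" for s in sex]
    return SampleSheet(
        pd.DataFrame(
            {"karyotype": karyo, "sex": sex, "age_group": age},
            index=pd.Index(index, name="sample_id"),
        )
    )


class TestAdjustedSexEffect:
    def test_type_i_calibration(self):
        rng = np.random.default_rng(5)
        reps, hits = 500, 0
        idx = [f"s{i}" for i in range(80)]
        sex = ["female"] * 40 + ["male"] * 40
        age = (["20-30", "30-40", "40-50", "50-60"] * 20)[:80]
        sheet = sheet_with(sex, age, idx)
        for _ in range(reps):
            values = pd.Series(rng.normal(size=80), index=idx)
            hits += adjusted_sex_effect_test(values, sheet) < 0.05
        assert 0.03 <= hits / reps <= 0.08

    def test_effect_recovery(self):
        rng = np.random.default_rng(6)
        idx = [f"s{i}" for i in range(100)]
        sex = ["female"] * 50 + ["male"] * 50
        age = (["20-30", "30-40"] * 50)[:100]
        sheet = sheet_with(sex, age, idx)
        values = pd.Series(
            rng.normal(0, 0.1, 100) + np.r_[np.zeros(50), np.ones(50)], index=idx
        )
        import statsmodels.api as sm

        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "sex_male": [1.0 if s == "male" else 0.0 for s in sex],
                "age": [1.0 if a == "30-40" else 0.0 for a in age],
            },
            index=idx,
        )
        coef = sm.OLS(values, X).fit().params["sex_male"]
        assert abs(coef - 1.0) < 0.05
        assert adjusted_sex_effect_test(values, sheet) < 1e-10

    def test_constant_age_collapses_to_t_test(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        idx = [f"s{i}" for i in range(20)]
        sex = ["female"] * 10 + ["male"] * 10
        sheet = sheet_with(sex, ["20-30"] * 20, idx)
        values = pd.Series(rng.normal(size=20), index=idx)
        p = adjusted_sex_effect_test(values, sheet)
        t = stats.ttest_ind(values[:10], values[10:])
        assert np.isclose(p, t.pvalue, atol=1e-12)


class TestAneuploidyFlag:
    def matrix(self, xist, usp9y, samples):
        return CountMatrix(
            pd.DataFrame([xist, usp9y], index=["XIST", "USP9Y"], columns=samples),
            feature_kind="gene",
            normalized=True,
        )

    def sheet(self, sexes, samples):
        karyo = ["XX" if s == "female" else "XY" for s in sexes]
        return SampleSheet(
            pd.DataFrame(
                {"karyotype": karyo, "sex": sexes},
                index=pd.Index(samples, name="sample_id"),
            )
        )

    def test_male_with_female_level_xist_and_y_marker_flagged(self):
        samples = ["f1", "f2", "f3", "m1", "m2"]
        m = self.matrix([100.0, 110, 90, 100, 1], [0.0, 0, 0, 50, 60], samples)
        sheet = self.sheet(["female"] * 3 + ["male"] * 2, samples)
        flags = flag_aneuploidy_suspects(m, sheet, "XIST", "USP9Y")
        assert flags["m1"] and not flags["m2"]

    def test_silent_xist_male_not_flagged(self):
        samples = ["f1", "f2", "m1"]
        m = self.matrix([100.0, 100, 0.1], [0.0, 0, 80], samples)
        sheet = self.sheet(["female", "female", "male"], samples)
        assert not flag_aneuploidy_suspects(m, sheet, "XIST", "USP9Y")["m1"]

    def test_females_never_flagged(self):
        samples = ["f1", "f2", "m1"]
        m = self.matrix([100.0, 120, 5], [90.0, 80, 70], samples)  # odd data
        sheet = self.sheet(["female", "female", "male"], samples)
        flags = flag_aneuploidy_suspects(m, sheet, "XIST", "USP9Y")
        assert not flags["f1"] and not flags["f2"]

    def test_missing_marker_rejected(self):
        samples = ["f1", "m1"]
        m = self.matrix([1.0, 1], [1.0, 1], samples)
        sheet = self.sheet(["female", "male"], samples)
        with pytest.raises(AnnotationError, match="absent"):
            flag_aneuploidy_suspects(m, sheet, "NOPE", "USP9Y")


def test_build_te_subsets_uses_lineage_and_prefixes():
    rosetta = RosettaMap(
        copy_to_subfamily={},
        subfamily_lineage={
            "HERVK-int": ("LTR", "ERVK"),
            "LTR5Hs": ("LTR", "ERVK"),
            "AluYa5": ("SINE", "Alu"),
            "AluSx": ("SINE", "Alu"),
            "L1HS": ("LINE", "L1"),
            "SVA_A": ("SVA", "SVA"),
            "Tigger1": ("DNA", "TcMar"),
        },
    )
    subsets = build_te_subsets(rosetta)
    assert subsets["LTR"].members == {"HERVK-int", "LTR5Hs"}
    assert subsets["SINE"].members == {"AluYa5", "AluSx"}
    assert "AluYa5" in subsets["AluY"].members and "AluSx" not in subsets["AluY"].members
    assert subsets["HERVK"].members == {"HERVK-int", "LTR5Hs"}  # LTR5 prefix rule
    assert subsets["L1"].members == {"L1HS"}
    assert subsets["SVA"].members == {"SVA_A"}
    assert subsets["ALL"].is_all
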