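import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fishnet_kit import (
    ComplexSet,
    WeightScheme,
    compute_weights,
    pfsnet_test,
    qpsp_hit_rates,
    qpsp_test,
    snet_beta,
    snet_family_test,
    snet_score,
    two_sample_t,
)
from conftest import make_rank_fixture


class TestQPSPHitRates:
    def test_weighted_intersection_over_size(self):
        weights = pd.DataFrame({"s1": [1.0, 0.8, 0.0]}, index=["P1", "P2", "P3"])
        cs = ComplexSet({"C": ["P1", "P2", "P3"]})
        h = qpsp_hit_rates(weights, cs)
        assert h.loc["C", "s1"] == pytest.approx(1.8 / 3)

    def test_all_members_full_weight(self):
        weights = pd.DataFrame({"s1": [1.0, 1.0, 1.0]}, index=["P1", "P2", "P3"])
        assert qpsp_hit_rates(weights, ComplexSet({"C": ["P1", "P2", "P3"]})).iloc[0, 0] == 1.0

    def test_no_member_in_top_band(self):
        weights = pd.DataFrame({"s1": [0.0, 0.0, 0.0]}, index=["P1", "P2", "P3"])
        assert qpsp_hit_rates(weights, ComplexSet({"C": ["P1", "P2", "P3"]})).iloc[0, 0] == 0.0


class TestTwoSampleT:
    def test_identical_groups_give_zero(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p_value == 1.0

    def test_matches_direct_formula_evaluation(self):
        xs, ys = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        m, n = len(xs), len(ys)
        sp = math.sqrt(((m - 1) * np.var(xs, ddof=1) + (n - 1) * np.var(ys, ddof=1)) / (m + n - 2))
        expected = (np.mean(xs) - np.mean(ys)) / (sp * math.sqrt(1 / m + 1 / n))
        res = two_sample_t(xs, ys)
        assert res.t == pytest.approx(expected, rel=1e-12)
        assert res.df == m + n - 2

    def test_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(3)
        xs, ys = rng.normal(size=5), rng.normal(1.0, size=7)
        a = two_sample_t(xs, ys)
        b = two_sample_t(ys, xs)
        assert a.t == pytest.approx(-b.t)
        assert a.p_value == pytest.approx(b.p_value)

    def test_welch_variant_matches_scipy(self):
        rng = np.random.default_rng(4)
        xs, ys = rng.normal(size=6), rng.normal(0.5, 2.0, size=9)
        res = two_sample_t(xs, ys, welch=True)
        ref = stats.ttest_ind(xs, ys, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_variance_unequal_means(self):
        res = two_sample_t([1.0, 1.0], [2.0, 2.0])
        assert res.p_value > 0 and res.p_value < 1e-300


class TestSnetPrimitives:
    def test_beta_is_class_proportion(self):
        weights = pd.DataFrame(
            [[1.0, 1.0, 1.0, 0.0, 0.0, 0.0]],
            index=["P1"],
            columns=[f"S{k}" for k in range(6)],
        )
        weights.loc["P2"] = [1.0, 1.0, 1.0, 1.0, 0.0, 0.0]
        classes = pd.Series(["x"] * 4 + ["y"] * 2, index=weights.columns)
        beta = snet_beta(weights, classes)
        assert beta.loc["P1", "x"] == pytest.approx(0.75)  # fs = 1 in 3 of 4
        assert beta.loc["P2", "x"] == pytest.approx(1.0)
        assert beta.loc["P1", "y"] == 0.0

    def test_score_is_weighted_sum(self):
        weights = pd.DataFrame({"s1": [1.0, 1.0, 0.8]}, index=["P1", "P2", "P3"])
        beta = pd.DataFrame({"x": [1.0, 0.5, 1.0]}, index=["P1", "P2", "P3"])
        assert snet_score(["P1", "P2", "P3"], "s1", weights, beta, "x") == pytest.approx(2.3)

    def test_all_zero_weights_score_zero(self):
        weights = pd.DataFrame({"s1": [0.0, 0.0]}, index=["P1", "P2"])
        beta = pd.DataFrame({"x": [1.0, 1.0]}, index=["P1", "P2"])
        assert snet_score(["P1", "P2"], "s1", weights, beta, "x") == 0.0

    def test_binary_scores_count_top_members(self):
        weights = pd.DataFrame({"s1": [1.0, 0.0, 1.0]}, index=["P1", "P2", "P3"])
        beta = pd.DataFrame({"x": [1.0, 1.0, 1.0]}, index=["P1", "P2", "P3"])
        assert snet_score(["P1", "P2", "P3"], "s1", weights, beta, "x") == 2.0


class TestSnetFamily:
    def test_identical_classes_select_nothing(self, tiny_matrix, tiny_complexes):
        matrix = pd.concat([tiny_matrix.iloc[:, :3]] * 2, axis=1)
        matrix.columns = [f"S{j}" for j in range(6)]
        classes = pd.Series(["a"] * 3 + ["b"] * 3, index=matrix.columns)
        for variant in ("snet", "fsnet"):
            res = snet_family_test(matrix, classes, tiny_complexes, variant=variant)
            assert not res["selected"].any()

    def test_class1_abundant_complex_and_label_swap(self):
        members = ["G00", "G01", "G02"]
        matrix, classes = make_rank_fixture(members)
        cs = ComplexSet({"hot": members, "cold": ["G10", "G11", "G12"]})
        res = snet_family_test(matrix, classes, cs, variant="fsnet").set_index("complex_id")
        assert res.loc["hot", "selected"]
        assert res.loc["hot", "direction"] == "up_in_class1"
        swapped = classes.map({"a": "b", "b": "a"})
        res2 = snet_family_test(matrix, swapped, cs, variant="fsnet").set_index("complex_id")
        assert res2.loc["hot", "direction"] == "up_in_class2"
        assert res2.loc["hot", "p_value"] == pytest.approx(res.loc["hot", "p_value"])

    def test_snet_equals_fsnet_when_fuzzy_band_collapses(self, null_matrix, tiny_classes):
        classes = pd.Series(["a"] * 6 + ["b"] * 6, index=null_matrix.columns)
        prot = list(null_matrix.index)
        cs = ComplexSet({f"C{k}": prot[5 * k : 5 * k + 5] for k in range(10)})
        a = snet_family_test(null_matrix, classes, cs, variant="snet", alpha2=0.10)
        b = snet_family_test(null_matrix, classes, cs, variant="fsnet", alpha2=0.10)
        assert np.allclose(a["p_value"], b["p_value"])
        assert (a["selected"] == b["selected"]).all()


class TestPFSNet:
    def test_identical_classes_all_deltas_zero(self, tiny_matrix):
        matrix = pd.concat([tiny_matrix.iloc[:, :3]] * 2, axis=1)
        matrix.columns = [f"S{j}" for j in range(6)]
        classes = pd.Series(["a"] * 3 + ["b"] * 3, index=matrix.columns)
        prot = list(matrix.index)
        cs = ComplexSet({"C1": prot[:3], "C2": prot[3:6]})
        res = pfsnet_test(matrix, classes, cs)
        assert not res["selected"].any()
        assert (res["p_value"] == 1.0).all()

    def test_closed_form_delta_fixture(self):
        # every class-1 sample has all members in the top 10%; no class-2 sample does
        members = ["G00", "G01", "G02"]
        matrix, classes = make_rank_fixture(members)
        cs = ComplexSet({"hot": members})
        res = pfsnet_test(matrix, classes, cs)
        assert res["selected"][0]
        assert res["direction"][0] == "up_in_class1"
        # closed form: beta_a = 1, beta_b = 0 for members, so delta = |S| on
        # class-1 samples and 0 on class-2 samples
        scheme = WeightScheme("fuzzy_fractional")
        weights = compute_weights(matrix, scheme)
        assert (weights.loc[members, classes[classes == "a"].index] == 1.0).all().all()
        assert (weights.loc[members, classes[classes == "b"].index] == 0.0).all().all()

    def test_rank_methods_invariant_to_monotone_transform(self, null_matrix):
        classes = pd.Series(["a"] * 6 + ["b"] * 6, index=null_matrix.columns)
        prot = list(null_matrix.index)
        cs = ComplexSet({f"C{k}": prot[7 * k : 7 * k + 7] for k in range(8)})
        transformed = null_matrix**2  # strictly monotone on non-negative values
        for test in (qpsp_test, pfsnet_test):
            a, b = test(null_matrix, classes, cs), test(transformed, classes, cs)
            assert np.allclose(a["p_value"], b["p_value"])


def test_qpsp_label_swap_symmetry(null_matrix):
    classes = pd.Series(["a"] * 6 + ["b"] * 6, index=null_matrix.columns)
    prot = list(null_matrix.index)
    cs = ComplexSet({f"C{k}": prot[6 * k : 6 * k + 6] for k in range(8)})
    res = qpsp_test(null_matrix, classes, cs)
    swapped = qpsp_test(null_matrix, classes.map({"a": "b", "b": "a"}), cs)
    assert np.allclose(res["p_value"], swapped["p_value"])
    assert np.allclose(res["statistic"], -swapped["statistic"])
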