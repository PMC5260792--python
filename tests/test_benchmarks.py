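import numpy as np
import pandas as pd
import pytest
from sklearn.naive_bayes import GaussianNB

from fishnet_kit import (
    ComplexSet,
    ValidationError,
    cross_validate,
    false_positive_eval,
    mean_pairwise_jaccard,
    naive_bayes_fit_predict,
    precision_recall_f,
    set_overlap,
    stability_resampling,
    stability_summary,
)


class TestPrecisionRecallF:
    def test_perfect_selection(self):
        truth = {"C1": True, "C2": True, "C3": False}
        s = precision_recall_f({"C1", "C2"}, truth)
        assert (s.precision, s.recall, s.f_score) == (1.0, 1.0, 1.0)

    def test_balanced_errors(self):
        truth = {f"T{i}": True for i in range(10)}
        truth.update({f"F{i}": False for i in range(10)})
        selected = {f"T{i}" for i in range(5)} | {f"F{i}" for i in range(5)}
        s = precision_recall_f(selected, truth)
        assert (s.tp, s.fp, s.fn) == (5, 5, 5)
        assert s.precision == s.recall == s.f_score == 0.5

    def test_empty_selection_convention(self):
        s = precision_recall_f(set(), {"C1": True})
        assert s.f_score == 0.0 and s.precision == 0.0

    def test_f_bounded_by_twice_min(self):
        rng = np.random.default_rng(0)
        truth = {f"C{i}": bool(rng.integers(2)) for i in range(30)}
        for _ in range(20):
            sel = {f"C{i}" for i in rng.choice(30, rng.integers(1, 20), replace=False)}
            s = precision_recall_f(sel, truth)
            assert s.f_score <= min(2 * s.precision, 2 * s.recall) + 1e-12

    def test_unknown_selected_id_rejected(self):
        with pytest.raises(ValidationError):
            precision_recall_f({"mystery"}, {"C1": True})


class TestSetOverlap:
    def test_identity_and_disjoint(self):
        assert set_overlap({"a", "b"}, {"a", "b"}, "jaccard") == 1.0
        assert set_overlap({"a", "b"}, {"a", "b"}, "min_normalized") == 1.0
        assert set_overlap({"a"}, {"b"}, "jaccard") == 0.0

    def test_arithmetic(self):
        t1, t2 = {"a", "b", "c", "d"}, {"a", "b", "c", "e"}
        assert set_overlap(t1, t2, "jaccard") == pytest.approx(0.6)
        assert set_overlap(t1, t2, "min_normalized") == pytest.approx(0.75)

    def test_jaccard_never_exceeds_min_normalized(self):
        rng = np.random.default_rng(1)
        universe = list(range(20))
        for _ in range(50):
            t1 = set(rng.choice(universe, rng.integers(0, 15), replace=False).tolist())
            t2 = set(rng.choice(universe, rng.integers(0, 15), replace=False).tolist())
            assert set_overlap(t1, t2, "jaccard") <= set_overlap(t1, t2, "min_normalized") + 1e-12

    def test_both_empty_is_one(self):
        assert set_overlap(set(), set(), "jaccard") == 1.0


def constant_method(selected_ids):
    def run(matrix, classes, complexes, **kw):
        return pd.DataFrame(
            {
                "complex_id": complexes.ids(),
                "method": "stub",
                "statistic": 0.0,
                "p_value": [0.0 if cid in selected_ids else 1.0 for cid in complexes.ids()],
                "direction": "none",
                "selected": [cid in selected_ids for cid in complexes.ids()],
            }
        )

    return run


def random_k_method(k, seed=0):
    rng = np.random.default_rng(seed)

    def run(matrix, classes, complexes, **kw):
        ids = complexes.ids()
        chosen = set(rng.choice(len(ids), k, replace=False).tolist())
        return pd.DataFrame(
            {
                "complex_id": ids,
                "method": "stub",
                "statistic": 0.0,
                "p_value": 1.0,
                "direction": "none",
                "selected": [i in chosen for i in range(len(ids))],
            }
        )

    return run


class TestStabilityResampling:
    def make_inputs(self, null_matrix):
        classes = pd.Series(["a"] * 6 + ["b"] * 6, index=null_matrix.columns)
        prot = list(null_matrix.index)
        cs = ComplexSet({f"C{k}": prot[5 * k : 5 * k + 5] for k in range(20)})
        return classes, cs

    def test_constant_method_perfect_stability(self, null_matrix):
        classes, cs = self.make_inputs(null_matrix)
        mats = stability_resampling(
            null_matrix, classes, cs, constant_method({"C1", "C5"}), sizes=[4], reps=10, seed=0
        )
        sm = mats[4]
        assert mean_pairwise_jaccard(sm.data) == 1.0
        col_sums = sm.data.sum(axis=0)
        assert set(col_sums.unique()) <= {0, 10}
        summary = stability_summary(sm)
        assert summary["selected_per_round"] == [2] * 10

    def test_random_ksets_expected_jaccard(self, null_matrix):
        classes, cs = self.make_inputs(null_matrix)
        k, N = 3, 20
        mats = stability_resampling(
            null_matrix, classes, cs, random_k_method(k, seed=4), sizes=[4], reps=120, seed=1
        )
        observed = mean_pairwise_jaccard(mats[4].data)
        # E[J] for two independent uniform k-subsets of N: E|I|/(2k - E|I|)
        # approximated by k/(2N - k) for k << N; allow generous MC slack
        expected = k / (2 * N - k)
        assert observed == pytest.approx(expected, abs=0.03)

    def test_single_rep_degenerate_but_well_formed(self, null_matrix):
        classes, cs = self.make_inputs(null_matrix)
        mats = stability_resampling(
            null_matrix, classes, cs, constant_method({"C1"}), sizes=[4], reps=1, seed=2
        )
        assert np.isnan(mean_pairwise_jaccard(mats[4].data))
        assert mats[4].data.shape == (1, 20)

    def test_oversized_resampling_rejected(self, null_matrix):
        classes, cs = self.make_inputs(null_matrix)
        with pytest.raises(ValidationError, match="size"):
            stability_resampling(null_matrix, classes, cs, constant_method(set()), sizes=[7], reps=2)


class TestNaiveBayes:
    def test_dominant_likelihood(self):
        train = np.array([[-10.0], [-9.0], [10.0], [9.0]])
        labels = ["lo", "lo", "hi", "hi"]
        assert naive_bayes_fit_predict(train, labels, np.array([[9.0]]))[0] == "hi"

    def test_equidistant_tie_breaks_lexicographically(self):
        train = np.array([[-1.0], [1.0]])
        labels = ["b", "a"]
        assert naive_bayes_fit_predict(train, labels, np.array([[0.0]]))[0] == "a"

    def test_training_point_classified_to_own_class(self):
        rng = np.random.default_rng(2)
        train = np.vstack([rng.normal(0, 1, (5, 3)), rng.normal(8, 1, (5, 3))])
        labels = ["a"] * 5 + ["b"] * 5
        preds = naive_bayes_fit_predict(train, labels, train)
        assert list(preds) == labels

    def test_matches_sklearn_gaussian_nb(self):
        rng = np.random.default_rng(3)
        train = np.vstack([rng.normal(0, 1, (20, 4)), rng.normal(1.5, 1.2, (20, 4))])
        labels = ["a"] * 20 + ["b"] * 20
        test = rng.normal(0.7, 1.5, (30, 4))
        ours = naive_bayes_fit_predict(train, labels, test)
        ref = GaussianNB().fit(train, labels).predict(test)
        assert (ours == ref).mean() == 1.0

    def test_constant_feature_skipped(self):
        train = np.array([[1.0, -5.0], [1.0, -4.0], [1.0, 5.0], [1.0, 4.0]])
        labels = ["a", "a", "b", "b"]
        preds = naive_bayes_fit_predict(train, labels, np.array([[1.0, 4.5], [1.0, -4.5]]))
        assert list(preds) == ["b", "a"]


class TestCrossValidate:
    def separable_inputs(self):
        rng = np.random.default_rng(4)
        cols = [f"A{i}" for i in range(8)] + [f"B{i}" for i in range(8)]
        rows = {}
        for g in range(12):
            base = rng.uniform(10, 100)
            shift = 50 + 10 * g if g < 6 else 0.0
            rows[f"G{g:02d}"] = np.concatenate(
                [base + shift + rng.normal(0, 1, 8), base + rng.normal(0, 1, 8)]
            )
        matrix = pd.DataFrame(rows).T
        matrix.columns = cols
        matrix = matrix - matrix.min().min() + 1.0
        classes = pd.Series(["a"] * 8 + ["b"] * 8, index=cols)
        cs = ComplexSet({"hot": [f"G{g:02d}" for g in range(6)],
                         "cold": [f"G{g:02d}" for g in range(6, 12)]})
        return matrix, classes, cs

    def test_informative_selection_gives_high_accuracy(self):
        matrix, classes, cs = self.separable_inputs()
        records = cross_validate(matrix, classes, cs, constant_method({"hot"}), reps=30, seed=5)
        assert records["accuracy"].mean() > 0.9
        assert not records["fallback"].any()

    def test_empty_selection_falls_back_to_majority(self):
        matrix, classes, cs = self.separable_inputs()
        records = cross_validate(matrix, classes, cs, constant_method(set()), reps=5, seed=6)
        assert records["fallback"].all()
        assert records["n_selected_complexes"].eq(0).all()

    def test_deterministic_under_seed(self):
        matrix, classes, cs = self.separable_inputs()
        r1 = cross_validate(matrix, classes, cs, constant_method({"hot"}), reps=10, seed=7)
        r2 = cross_validate(matrix, classes, cs, constant_method({"hot"}), reps=10, seed=7)
        assert r1.equals(r2)

    def test_too_few_samples_rejected(self):
        matrix, classes, cs = self.separable_inputs()
        small = matrix.iloc[:, [0, 1, 2, 8, 9, 10]]
        with pytest.raises(ValidationError):
            cross_validate(small, classes[small.columns], cs, constant_method({"hot"}), reps=2)


class TestFalsePositiveEval:
    def test_select_everything_rate_one(self, null_matrix):
        prot = list(null_matrix.index)
        cs = ComplexSet({f"C{k}": prot[4 * k : 4 * k + 4] for k in range(10)})
        rates = false_positive_eval(
            null_matrix, cs, constant_method(set(cs.ids())), reps=5, seed=8
        )
        assert (rates["rate"] == 1.0).all()

    def test_deterministic_under_seed(self, null_matrix):
        prot = list(null_matrix.index)
        cs = ComplexSet({f"C{k}": prot[4 * k : 4 * k + 4] for k in range(5)})
        r1 = false_positive_eval(null_matrix, cs, "ffishnet", reps=3, seed=9)
        r2 = false_positive_eval(null_matrix, cs, "ffishnet", reps=3, seed=9)
        assert r1.equals(r2)
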