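import numpy as np
import pytest

from readrank import ranker
from readrank.corpus_io import RatingRecord
from readrank.ranker import (
    PairwiseExample,
    generate_pairwise_examples,
    rank_documents,
    score,
    train,
    tune_c,
)

from oracles import qp_rank_svm


def _examples_from_diffs(diffs, rater="r1"):
    return [
        PairwiseExample(diff=np.asarray(d, dtype=float), rater_id=rater, harder_doc="h", easier_doc="e")
        for d in diffs
    ]


class TestGeneratePairwiseExamples:
    FEATS = {d: np.array([v], dtype=float) for d, v in {"A": 1.0, "B": 2.0, "C": 3.0}.items()}

    def _ratings(self, assignments, rater="r1"):
        # pair structure is irrelevant to example generation
        return [
            RatingRecord(rater, f"p{i // 2}", doc, rating)
            for i, (doc, rating) in enumerate(assignments.items())
        ]

    def test_equal_ratings_produce_no_example(self):
        ratings = self._ratings({"A": 2, "B": 5, "C": 5})
        examples = generate_pairwise_examples(ratings, self.FEATS)
        pairs = {(e.harder_doc, e.easier_doc) for e in examples}
        assert pairs == {("B", "A"), ("C", "A")}

    def test_all_equal_gives_zero_examples(self):
        ratings = self._ratings({"A": 4, "B": 4, "C": 4})
        assert generate_pairwise_examples(ratings, self.FEATS) == []

    def test_distinct_ratings_give_all_pairs(self):
        n = 6
        feats = {f"d{i}": np.array([float(i)]) for i in range(n)}
        ratings = [RatingRecord("r1", f"p{i//2}", f"d{i}", i + 1) for i in range(n)]
        examples = generate_pairwise_examples(ratings, feats)
        assert len(examples) == n * (n - 1) // 2

    def test_no_cross_rater_examples(self):
        feats = {"A": np.array([1.0]), "B": np.array([2.0])}
        ratings = [RatingRecord("r1", "p0", "A", 1), RatingRecord("r1", "p0", "B", 1),
                   RatingRecord("r2", "p0", "A", 9), RatingRecord("r2", "p0", "B", 1)]
        examples = generate_pairwise_examples(ratings, feats)
        assert {e.rater_id for e in examples} == {"r2"}

    def test_orientation_is_harder_minus_easier(self):
        feats = {"A": np.array([1.0]), "B": np.array([5.0])}
        ratings = [RatingRecord("r1", "p0", "A", 9), RatingRecord("r1", "p0", "B", 2)]
        (ex,) = generate_pairwise_examples(ratings, feats)
        assert ex.harder_doc == "A"
        np.testing.assert_array_equal(ex.diff, [-4.0])

    def test_missing_feature_is_hard_error(self):
        ratings = [RatingRecord("r1", "p0", "A", 1), RatingRecord("r1", "p0", "Z", 5)]
        with pytest.raises(KeyError, match="Z"):
            generate_pairwise_examples(ratings, {"A": np.array([1.0])})


class TestTrain:
    def test_1d_separable_analytic(self):
        # diffs all positive; at large C solution is w = 1/min(d)
        diffs = [[2.0], [0.5], [1.0]]
        model = train(_examples_from_diffs(diffs), c_tradeoff=1e4, standardize=False, tol=1e-10)
        assert model.weights[0] == pytest.approx(1 / 0.5, rel=1e-3)
        assert model.training_diagnostics["n_discordant_on_train"] == 0

    def test_matches_qp_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(4):
            n, p = int(rng.integers(4, 10)), int(rng.integers(1, 4))
            diffs = rng.normal(size=(n, p)) + 0.4  # mostly consistent orientation
            c = float(rng.choice([0.5, 1.0, 5.0]))
            model = train(_examples_from_diffs(diffs), c_tradeoff=c, standardize=False,
                          tol=1e-12, max_iter=2_000_000)
            w_oracle = qp_rank_svm(diffs, c)
            np.testing.assert_allclose(model.weights, w_oracle, atol=5e-4)

    def test_duplication_preserves_ranking(self):
        # duplication rescales the effective C; on separable data past the
        # margin threshold the solution (hence the ranking) is unchanged
        rng = np.random.default_rng(1)
        diffs = np.abs(rng.normal(size=(8, 3))) + 0.5
        m1 = train(_examples_from_diffs(diffs), c_tradeoff=100.0, standardize=False,
                   tol=1e-12, max_iter=2_000_000)
        m2 = train(_examples_from_diffs(np.vstack([diffs, diffs])), c_tradeoff=100.0,
                   standardize=False, tol=1e-12, max_iter=2_000_000)
        feats = {f"d{i}": rng.normal(size=3) for i in range(6)}
        assert rank_documents(m1, feats) == rank_documents(m2, feats)

    def test_antisymmetry_negated_diffs_give_negated_weights(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(size=(6, 2)) + 0.5
        m_pos = train(_examples_from_diffs(diffs), c_tradeoff=2.0, standardize=False, tol=1e-10)
        m_neg = train(_examples_from_diffs(-diffs), c_tradeoff=2.0, standardize=False, tol=1e-10)
        np.testing.assert_allclose(m_neg.weights, -m_pos.weights, atol=1e-5)

    def test_antisymmetric_encoding_equivalence(self):
        # the user-level two-class set {(d,+1),(-d,-1)} is, in the oriented
        # encoding, a plain duplication: solutions agree in direction on a
        # separable toy, and exactly against the QP oracle at matched C
        rng = np.random.default_rng(3)
        diffs = rng.normal(size=(5, 2)) + 0.9
        single = train(_examples_from_diffs(diffs), c_tradeoff=10.0, standardize=False, tol=1e-10)
        doubled = train(
            _examples_from_diffs(np.vstack([diffs, diffs])),
            c_tradeoff=5.0, standardize=False, tol=1e-10,
        )
        np.testing.assert_allclose(single.weights, doubled.weights, atol=1e-5)
        w_oracle = qp_rank_svm(diffs, 10.0)
        np.testing.assert_allclose(single.weights, w_oracle, atol=5e-4)

    def test_scale_invariance_of_ranking(self):
        # feature scaling by k is equivalent to rescaling C by k^2; past the
        # separability threshold w rescales by 1/k and the ranking is exact
        rng = np.random.default_rng(4)
        diffs = np.abs(rng.normal(size=(10, 3))) + 0.5
        feats = {f"d{i}": rng.normal(size=3) for i in range(8)}
        m1 = train(_examples_from_diffs(diffs), c_tradeoff=1000.0, standardize=False,
                   tol=1e-12, max_iter=2_000_000)
        k = 37.5
        m2 = train(_examples_from_diffs(np.asarray(diffs) * k), c_tradeoff=1000.0,
                   standardize=False, tol=1e-12, max_iter=2_000_000)
        np.testing.assert_allclose(m2.weights * k, m1.weights, rtol=1e-4, atol=1e-8)
        assert rank_documents(m1, feats) == rank_documents(m2, {d: x * k for d, x in feats.items()})

    def test_empty_examples_rejected(self):
        with pytest.raises(ValueError):
            train([])

    def test_all_zero_diffs_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            train(_examples_from_diffs([[0.0, 0.0]]))

    def test_diagnostics_populated(self):
        model = train(_examples_from_diffs([[1.0], [2.0]]), c_tradeoff=1.0, standardize=False)
        diag = model.training_diagnostics
        assert diag["n_examples"] == 2
        assert diag["total_slack"] >= 0.0


class TestScore:
    def test_zero_weights_score_zero(self):
        model = train(_examples_from_diffs([[1.0, 0.0]]), c_tradeoff=1.0, standardize=False)
        model.weights = np.zeros(2)
        assert score(model, np.array([3.0, 4.0])) == 0.0

    def test_linearity(self):
        model = train(_examples_from_diffs([[1.0, -0.5]]), c_tradeoff=1.0, standardize=False)
        xi, xj = np.array([2.0, 1.0]), np.array([0.5, 3.0])
        assert score(model, xi) - score(model, xj) == pytest.approx(
            float(model.weights @ (xi - xj))
        )

    def test_layout_mismatch_rejected(self):
        model = train(_examples_from_diffs([[1.0, 0.0]]), c_tradeoff=1.0, standardize=False)
        with pytest.raises(ValueError):
            score(model, np.array([1.0, 2.0, 3.0]))

    def test_1d_toy_scores_reproduce_planted_order(self):
        model = train(_examples_from_diffs([[1.0], [2.0]]), c_tradeoff=100.0, standardize=False)
        assert score(model, np.array([5.0])) > score(model, np.array([1.0]))


class TestRankDocuments:
    def test_identical_documents_tie_break_by_doc_id(self):
        model = train(_examples_from_diffs([[1.0]]), c_tradeoff=1.0, standardize=False)
        feats = {"b": np.array([1.0]), "a": np.array([1.0]), "c": np.array([1.0])}
        assert rank_documents(model, feats) == ["a", "b", "c"]

    def test_known_scores_order(self):
        model = train(_examples_from_diffs([[1.0]]), c_tradeoff=100.0, standardize=False)
        feats = {"low": np.array([1.1]), "high": np.array([3.2])}
        assert rank_documents(model, feats) == ["high", "low"]

    def test_input_order_irrelevant(self):
        model = train(_examples_from_diffs([[1.0]]), c_tradeoff=1.0, standardize=False)
        rng = np.random.default_rng(0)
        feats = {f"d{i}": rng.normal(size=1) for i in range(10)}
        shuffled = dict(reversed(list(feats.items())))
        assert rank_documents(model, feats) == rank_documents(model, shuffled)


class TestTuneC:
    def _setup(self):
        # planted 1-D study: feature = latent difficulty
        feats = {f"d{i}": np.array([float(i)]) for i in range(10)}
        train_ratings = [RatingRecord("r1", f"p{i//2}", f"d{i}", i + 1) for i in range(8)]
        dev_ratings = [RatingRecord("r9", f"p{i//2}", f"d{i}", i + 1) for i in range(10)]
        examples = generate_pairwise_examples(train_ratings, feats)
        return examples, dev_ratings, feats

    def test_single_value_grid(self):
        examples, dev, feats = self._setup()
        best, sweep = tune_c(examples, dev, feats, c_grid=(0.5,), standardize=False)
        assert best == 0.5 and set(sweep) == {0.5}

    def test_tie_prefers_smaller_c(self):
        examples, dev, feats = self._setup()
        best, sweep = tune_c(examples, dev, feats, c_grid=(10.0, 1.0), standardize=False)
        assert sweep[1.0] == sweep[10.0]  # separable: both perfect
        assert best == 1.0

    def test_selected_c_attains_max(self):
        examples, dev, feats = self._setup()
        best, sweep = tune_c(examples, dev, feats, c_grid=(1e-3, 1e-1, 1e1), standardize=False)
        assert sweep[best] == max(sweep.values())

    def test_empty_grid_or_dev_rejected(self):
        examples, dev, feats = self._setup()
        with pytest.raises(ValueError):
            tune_c(examples, dev, feats, c_grid=())
        with pytest.raises(ValueError):
            tune_c(examples, [], feats, c_grid=(1.0,))
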