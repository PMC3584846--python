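import numpy as np
import pandas as pd
import pytest

from structgo import (
    GeneOntology,
    StructuredLabel,
    SyntheticSpec,
    build_view_kernel,
    evaluate,
    identity_aware_folds,
    make_synthetic_dataset,
    make_toy_ontology,
    precision_at_recall,
    select_C,
    term_auc,
)
from structgo.errors import ValidationError
from structgo.evaluate import clusters_from_identity


def brute_force_auc(scores, truths):
    """All-pairs Mann-Whitney count, ties counted one half."""
    scores = np.asarray(scores, float)
    truths = np.asarray(truths, int)
    pos = scores[truths == 1]
    neg = scores[truths == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestTermAuc:
    def test_perfect_separation(self):
        assert term_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_interleaved_half(self):
        assert term_auc([0.9, 0.8, 0.2, 0.1], [1, 0, 0, 1]) == 0.5

    def test_all_ties_half(self):
        assert term_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            term_auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 20))
            scores = np.round(rng.standard_normal(n), 1)  # induce ties
            truths = rng.integers(0, 2, n)
            if truths.min() == truths.max():
                continue
            assert term_auc(scores, truths) == pytest.approx(
                brute_force_auc(scores, truths), abs=1e-12
            )


class TestPrecisionAtRecall:
    def test_top_hit_reaches_recall(self):
        assert precision_at_recall([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 1.0

    def test_top_negative_then_positive(self):
        assert precision_at_recall([0.9, 0.8, 0.7, 0.6], [0, 1, 0, 1]) == 0.5

    def test_perfect_ranking(self):
        assert precision_at_recall([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_ties_enter_together(self):
        # one threshold admits both the positive and a negative
        assert precision_at_recall([0.5, 0.5, 0.1], [1, 0, 0]) == 0.5

    def test_no_positives_rejected(self):
        with pytest.raises(ValidationError):
            precision_at_recall([0.5], [0])

    def test_promoting_a_positive_never_hurts(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            scores = rng.uniform(size=12)
            truths = rng.integers(0, 2, 12)
            if truths.sum() in (0, 12):
                continue
            base = precision_at_recall(scores, truths)
            improved = scores.copy()
            pos = np.flatnonzero(truths == 1)[0]
            improved[pos] = scores.max() + 1.0
            assert precision_at_recall(improved, truths) >= base


class TestEvaluate:
    def flat_go(self, n_terms):
        terms = [f"t{i}" for i in range(n_terms)]
        return GeneOntology(
            {"R": "MF", **{t: "MF" for t in terms}},
            {"R": set(), **{t: {"R"} for t in terms}},
        )

    def test_perfect_scores_give_macro_one(self):
        go = self.flat_go(3)
        vocab = go.vocabulary("MF")
        labels = [
            StructuredLabel({"t0"}, vocab),
            StructuredLabel({"t1"}, vocab),
            StructuredLabel({"t0", "t2"}, vocab),
        ]
        scores = pd.DataFrame(
            [y.indicator for y in labels],
            index=["p0", "p1", "p2"],
            columns=vocab,
        )
        report = evaluate(scores, labels, go)
        assert report.macro_auc == 1.0
        assert report.macro_p20r == 1.0

    def test_permuted_scores_are_null(self):
        """Scores independent of truth give macro AUC 0.5 +/- 0.05."""
        go = self.flat_go(20)
        vocab = go.vocabulary("MF")
        rng = np.random.default_rng(42)
        labels = [
            StructuredLabel(
                {vocab[int(i)] for i in rng.choice(20, 4, replace=False)},
                vocab,
            )
            for _ in range(200)
        ]
        scores = pd.DataFrame(
            rng.standard_normal((200, 20)),
            index=[f"p{i}" for i in range(200)],
            columns=vocab,
        )
        report = evaluate(scores, labels, go)
        assert report.macro_auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_terms_excluded_and_reported(self):
        go = self.flat_go(3)
        vocab = go.vocabulary("MF")
        labels = [
            StructuredLabel({"t0"}, vocab),
            StructuredLabel({"t0", "t1"}, vocab),
        ]
        scores = pd.DataFrame(
            np.zeros((2, 3)), index=["p0", "p1"], columns=vocab
        )
        report = evaluate(scores, labels, go)
        # t0 is always positive, t2 always negative -> both skipped
        assert set(report.skipped_terms) == {"t0", "t2"}
        assert set(report.per_term["term"]) == {"t1"}

    def test_per_depth_aggregation(self):
        go = GeneOntology(
            {"R": "MF", "s": "MF", "d": "MF"},
            {"R": set(), "s": {"R"}, "d": {"s"}},
        )
        vocab = go.vocabulary("MF")
        labels = [
            StructuredLabel({"s"}, vocab),
            StructuredLabel({"s", "d"}, vocab),
            StructuredLabel(set(), vocab),
        ]
        scores = pd.DataFrame(
            [y.indicator for y in labels],
            index=["p0", "p1", "p2"],
            columns=vocab,
        )
        report = evaluate(scores, labels, go)
        assert report.per_depth == {1: 1.0, 2: 1.0}


class TestFolds:
    def test_singletons_balanced(self):
        ids = [f"p{i}" for i in range(10)]
        folds = identity_aware_folds(ids, k=5, seed=0)
        sizes = pd.Series(folds).value_counts()
        assert sorted(sizes) == [2] * 5

    def test_cluster_atomicity(self):
        ids = [f"p{i}" for i in range(10)]
        clusters = {p: ("big" if i < 6 else p) for i, p in enumerate(ids)}
        folds = identity_aware_folds(ids, clusters, k=2, seed=1)
        big_folds = {folds[p] for i, p in enumerate(ids) if i < 6}
        assert len(big_folds) == 1

    def test_never_splits_any_cluster(self):
        rng = np.random.default_rng(3)
        ids = [f"p{i}" for i in range(50)]
        clusters = {p: int(rng.integers(0, 17)) for p in ids}
        folds = identity_aware_folds(ids, clusters, k=4, seed=3)
        for a in ids:
            for b in ids:
                if clusters[a] == clusters[b]:
                    assert folds[a] == folds[b]

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValidationError):
            identity_aware_folds(["a", "b"], {"a": 0, "b": 0}, k=2)

    def test_single_linkage_clusters_from_identity(self):
        ids = ["a", "b", "c", "d"]
        pairs = [("a", "b", 0.8), ("b", "c", 0.6), ("c", "d", 0.3)]
        clusters = clusters_from_identity(pairs, ids, threshold=0.5)
        assert clusters["a"] == clusters["b"] == clusters["c"]
        assert clusters["d"] != clusters["a"]


class TestSelectC:
    def make_fixture(self, flip_fraction):
        go = make_toy_ontology(10, seed=4)
        spec = SyntheticSpec(
            n_terms=10, n_proteins=36, label_vocabulary_size=3,
            view_noise=(0.0, 0.0), noise_sigma=1.2, seed=4,
        )
        views, labels, ids = make_synthetic_dataset(spec, go)
        rng = np.random.default_rng(4)
        from structgo import build_label_space

        space = build_label_space(labels)
        noisy = list(labels)
        n_flip = int(round(flip_fraction * len(ids)))
        for i in rng.choice(len(ids), size=n_flip, replace=False):
            others = [c for c in space.candidates if c != labels[i]]
            noisy[int(i)] = others[int(rng.integers(0, len(others)))]
        K = build_view_kernel([views[0]])
        return K, dict(zip(ids, noisy))

    def test_single_value_grid(self):
        K, labels = self.make_fixture(0.0)
        assert select_C(K, labels, [0.7], seed=0) == 0.7

    def test_label_noise_prefers_smaller_c(self):
        """With flipped training labels, a large C overfits the noise and
        loses inner-CV AUC to a smaller C."""
        K, labels = self.make_fixture(0.25)
        assert select_C(K, labels, [0.1, 100.0], seed=0) == 0.1

    def test_tie_breaks_to_smaller_c(self):
        # noise-free, easily separable: both C values reach AUC 1.0
        K, labels = self.make_fixture(0.0)
        assert select_C(K, labels, [0.5, 2.0], seed=0) == 0.5
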