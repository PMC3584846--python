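import numpy as np
import pandas as pd
import pytest

from structgo import (
    GeneOntology,
    StructuredLabel,
    TrainingProblem,
    build_label_space,
    build_view_kernel,
    make_worked_example,
)


@pytest.fixture
def chain_go():
    """Three-term chain: a (root) <- b <- c, one namespace."""
    return GeneOntology(
        {"a": "MF", "b": "MF", "c": "MF"},
        {"a": set(), "b": {"a"}, "c": {"b"}},
    )


@pytest.fixture
def diamond_go():
    """Diamond DAG: d is_a b, d is_a c, b is_a a, c is_a a."""
    return GeneOntology(
        {"a": "MF", "b": "MF", "c": "MF", "d": "MF"},
        {"a": set(), "b": {"a"}, "c": {"a"}, "d": {"b", "c"}},
    )


@pytest.fixture
def flat_go():
    """Root R with six leaf children; every subset of leaves is closed."""
    leaves = list("abcdef")
    return GeneOntology(
        {"R": "MF", **{t: "MF" for t in leaves}},
        {"R": set(), **{t: {"R"} for t in leaves}},
    )


@pytest.fixture
def worked():
    return make_worked_example()


def random_toy_problem(seed, n_max=5, cand_max=4, c_over_n=1.0):
    """A small random training problem with a normalized PSD kernel."""
    vocab = tuple("abc")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    pool = [
        StructuredLabel(t, vocab)
        for t in ({"a"}, {"b"}, {"a", "b"}, {"c"}, {"b", "c"})
    ]
    rng.shuffle(pool)
    candidates = pool[: int(rng.integers(2, cand_max + 1))]
    labels = [candidates[int(i)] for i in rng.integers(0, len(candidates), n)]
    X = rng.standard_normal((n, 3))
    K = build_view_kernel(
        [pd.DataFrame(X, index=[f"p{i}" for i in range(n)])]
    )
    return TrainingProblem(
        K, labels, build_label_space(candidates), c_over_n=c_over_n
    )


def random_closed_labels(go, rng, n, namespace=None, max_picks=3):
    """n random hierarchically consistent labels (possibly repeating)."""
    namespace = namespace or go.namespaces()[0]
    vocab = go.vocabulary(namespace)
    out = []
    for _ in range(n):
        k = int(rng.integers(1, min(max_picks, len(vocab)) + 1))
        picks = rng.choice(len(vocab), size=k, replace=False)
        out.append(
            StructuredLabel(go.close_label({vocab[int(p)] for p in picks}), vocab)
        )
    return out
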