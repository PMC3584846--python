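"""Synthetic ontologies, labels and multi-view features for testing.

The generator emulates the statistical structure the method assumes:
proteins carrying the same structured label share a feature prototype per
view, and different views carry *complementary* signal — each view has a
corrupted protein subset whose features are pure noise, and with
``complementary=True`` those subsets are disjoint across views, so the
summed multi-view compatibility can recover every protein from at least
one view.  The defaults describe a small but non-trivial study: 120
proteins, a 15-term single-namespace DAG, 6 distinct label sets, two
20-dimensional views with 30% corruption each and Gaussian feature noise
of σ = 0.5 around unit-scale prototypes.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .labels import StructuredLabel, build_label_space
from .ontology import GeneOntology

logger = logging.getLogger(__name__)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic benchmark."""

    n_terms: int = 15
    n_proteins: int = 120
    n_views: int = 2
    feature_dim: int = 20
    label_vocabulary_size: int = 6
    view_noise: tuple[float, ...] = (0.3, 0.3)
    complementary: bool = True
    noise_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.view_noise) != self.n_views:
            raise ValidationError(
                f"{len(self.view_noise)} corruption fractions for "
                f"{self.n_views} views"
            )
        if any(not 0.0 <= f <= 1.0 for f in self.view_noise):
            raise ValidationError("corruption fractions must lie in [0, 1]")
        if self.complementary and sum(self.view_noise) > 1.0 + 1e-12:
            raise ValidationError(
                "complementary corruption requires fractions summing to ≤ 1"
            )


def make_toy_ontology(
    n_terms: int, seed: int = 0, namespace: str = "MF"
) -> GeneOntology:
    """A random rooted DAG: term 0 is the root, each later term gets 1–2
    parents among earlier terms."""
    if n_terms < 2:
        raise ValidationError("need at least a root and one child")
    rng = np.random.default_rng(seed)
    ids = [f"T{i:04d}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {ids[0]: set()}
    for i in range(1, n_terms):
        n_par = 1 if i == 1 else int(rng.integers(1, 3))
        picks = rng.choice(i, size=min(n_par, i), replace=False)
        parents[ids[i]] = {ids[int(p)] for p in picks}
    return GeneOntology({t: namespace for t in ids}, parents)


def _draw_labels(
    go: GeneOntology,
    namespace: str,
    count: int,
    rng: np.random.Generator,
) -> list[StructuredLabel]:
    """``count`` distinct consistent labels from random term picks."""
    vocab = go.vocabulary(namespace)
    if not vocab:
        raise ValidationError("ontology has no non-root terms")
    seen: set[frozenset] = set()
    labels: list[StructuredLabel] = []
    attempts = 0
    while len(labels) < count:
        attempts += 1
        if attempts > 1000 * count:
            raise ValidationError(
                f"could not draw {count} distinct consistent labels from "
                f"{len(vocab)} terms"
            )
        n_pick = int(rng.integers(1, min(3, len(vocab)) + 1))
        picks = rng.choice(len(vocab), size=n_pick, replace=False)
        terms = go.close_label({vocab[int(p)] for p in picks})
        if terms and terms not in seen:
            seen.add(terms)
            labels.append(StructuredLabel(terms, vocab))
    return labels


def make_synthetic_dataset(
    spec: SyntheticSpec, go: GeneOntology
) -> tuple[list[pd.DataFrame], list[StructuredLabel], list[str]]:
    """Generate per-view feature tables and one structured label per protein.

    Per view, a protein's features are the sum of per-term prototype
    vectors of its label (prototypes fixed by the seed, standard normal
    scaled by 1/√|label|) plus Gaussian noise; corrupted proteins get pure
    standard-normal rows instead.  Returns (views, labels, protein ids).
    """
    rng = np.random.default_rng(spec.seed)
    namespace = go.namespaces()[0]
    vocab = go.vocabulary(namespace)
    label_pool = _draw_labels(go, namespace, spec.label_vocabulary_size, rng)
    assignment = rng.integers(0, len(label_pool), size=spec.n_proteins)
    # guarantee every label occurs so the candidate space has full support
    for j in range(min(len(label_pool), spec.n_proteins)):
        assignment[j] = j
    labels = [label_pool[int(a)] for a in assignment]
    ids = [f"P{i:04d}" for i in range(spec.n_proteins)]

    perm = rng.permutation(spec.n_proteins)
    corrupted: list[np.ndarray] = []
    offset = 0
    for frac in spec.view_noise:
        size = int(round(frac * spec.n_proteins))
        if spec.complementary:
            corrupted.append(perm[offset:offset + size])
            offset += size
        else:
            corrupted.append(
                rng.choice(spec.n_proteins, size=size, replace=False)
            )

    M = np.vstack([y.indicator for y in labels])  # (P × V)
    views: list[pd.DataFrame] = []
    for v in range(spec.n_views):
        protos = rng.standard_normal((len(vocab), spec.feature_dim))
        sizes = np.maximum(M.sum(axis=1), 1.0)
        X = (M @ protos) / np.sqrt(sizes)[:, None]
        X = X + spec.noise_sigma * rng.standard_normal(X.shape)
        noise_rows = rng.standard_normal((len(corrupted[v]), spec.feature_dim))
        X[corrupted[v], :] = noise_rows
        cols = [f"v{v}f{j}" for j in range(spec.feature_dim)]
        frame = pd.DataFrame(X, index=ids, columns=cols)
        frame.attrs["corrupted"] = sorted(int(i) for i in corrupted[v])
        views.append(frame)
    logger.info(
        "synthetic dataset: %d proteins, %d distinct labels, %d views, "
        "corrupted per view %r",
        spec.n_proteins, len(label_pool), spec.n_views,
        [len(c) for c in corrupted],
    )
    return views, labels, ids


@dataclass
class WorkedExample:
    """A tiny fixed dataset with hand-computed intermediate quantities."""

    go: GeneOntology
    features: pd.DataFrame
    labels: list[StructuredLabel]
    ids: list[str]
    # hand-computed: kernel-F1 losses between the three candidate labels,
    # indexed like `candidates`
    loss_matrix: np.ndarray
    candidates: list[StructuredLabel]


def make_worked_example() -> WorkedExample:
    """4 proteins, 3 candidate labels, hand-specified 2-D features.

    Ontology: root R with children a and b; c is a child of b; vocabulary
    (a, b, c).  Labels: {a}, {b}, {b,c}, {a}.  The loss matrix below is
    1 − F1 between the candidate term sets:

        Δ({a},{b}) = 1,  Δ({a},{b,c}) = 1,  Δ({b},{b,c}) = 1/3.
    """
    go = GeneOntology(
        {"R": "MF", "a": "MF", "b": "MF", "c": "MF"},
        {"R": set(), "a": {"R"}, "b": {"R"}, "c": {"b"}},
    )
    vocab = go.vocabulary("MF")
    y_a = StructuredLabel({"a"}, vocab)
    y_b = StructuredLabel({"b"}, vocab)
    y_bc = StructuredLabel({"b", "c"}, vocab)
    features = pd.DataFrame(
        [[2.0, 0.0], [0.0, 2.0], [1.0, 1.0], [2.0, 0.0]],
        index=["p1", "p2", "p3", "p4"],
        columns=["f1", "f2"],
    )
    loss = np.array(
        [
            [0.0, 1.0, 1.0],
            [1.0, 0.0, 1.0 / 3.0],
            [1.0, 1.0 / 3.0, 0.0],
        ]
    )
    return WorkedExample(
        go=go,
        features=features,
        labels=[y_a, y_b, y_bc, y_a],
        ids=["p1", "p2", "p3", "p4"],
        loss_matrix=loss,
        candidates=[y_a, y_b, y_bc],
    )
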