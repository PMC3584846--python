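"""Structured annotation labels and their output-space kernel.

A protein's annotation within one GO namespace is represented as a single
structured label: the full, ancestor-closed set of (non-root) terms.  The
output space uses a linear kernel between indicator vectors, so
``K_Y(y1, y2) = |y1 ∩ y2|``, and the training loss is the kernel F1 loss

    Δ(y, ŷ) = 1 − 2·K_Y(y, ŷ) / (K_Y(y, y) + K_Y(ŷ, ŷ)),

which for the linear kernel equals ``1 − F1(y, ŷ)``.

Inference is restricted to the candidate label sets observed in training
(:class:`LabelSpace`), which keeps the argmax over labels exact and focuses
predictions on biologically plausible term combinations.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .ontology import GeneOntology

logger = logging.getLogger(__name__)


class StructuredLabel:
    """An ancestor-closed, root-free set of GO terms over a fixed vocabulary.

    The vocabulary is the sorted tuple of non-root terms of one namespace;
    the ``indicator`` view is a binary vector in that order.
    """

    __slots__ = ("terms", "vocabulary", "_indicator", "_hash")

    def __init__(self, terms: Iterable[str], vocabulary: Sequence[str]) -> None:
        self.vocabulary: tuple[str, ...] = tuple(vocabulary)
        self.terms: frozenset[str] = frozenset(terms)
        unknown = self.terms - set(self.vocabulary)
        if unknown:
            raise ValidationError(
                f"label terms not in vocabulary: {sorted(unknown)!r}"
            )
        self._indicator = None
        self._hash = None

    @classmethod
    def from_terms(
        cls,
        go: GeneOntology,
        terms: Iterable[str],
        namespace: str | None = None,
    ) -> "StructuredLabel":
        """Build a label by closing ``terms`` under the ontology.

        ``namespace`` is inferred from the terms when omitted; it must be
        given explicitly for the empty label.
        """
        terms = set(terms)
        if namespace is None:
            if not terms:
                raise ValidationError(
                    "namespace must be given for an empty label"
                )
            namespace = go.namespace_of[next(iter(terms))]
        closed = go.close_label(terms)
        return cls(closed, go.vocabulary(namespace))

    @property
    def indicator(self) -> np.ndarray:
        """Binary vector over the vocabulary (float64, cached)."""
        if self._indicator is None:
            vec = np.zeros(len(self.vocabulary))
            pos = {t: i for i, t in enumerate(self.vocabulary)}
            for t in self.terms:
                vec[pos[t]] = 1.0
            self._indicator = vec
        return self._indicator

    def validate_consistent(self, go: GeneOntology) -> None:
        if not go.is_closed(self.terms):
            raise ValidationError(
                f"label {sorted(self.terms)!r} is not ancestor-closed"
            )

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, StructuredLabel)
            and self.vocabulary == other.vocabulary
            and self.terms == other.terms
        )

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash((self.vocabulary, self.terms))
        return self._hash

    def __repr__(self) -> str:
        return f"StructuredLabel({sorted(self.terms)!r})"


def _check_same_vocabulary(y1: StructuredLabel, y2: StructuredLabel) -> None:
    if y1.vocabulary != y2.vocabulary:
        raise ValidationError("labels are defined over different vocabularies")


def output_kernel(y1: StructuredLabel, y2: StructuredLabel) -> float:
    """Linear output-space kernel: dot product of indicators = |y1 ∩ y2|."""
    _check_same_vocabulary(y1, y2)
    return float(len(y1.terms & y2.terms))


def kernel_f1_loss(y: StructuredLabel, yhat: StructuredLabel) -> float:
    """Kernel F1 loss ``1 − 2·K(y,ŷ)/(K(y,y)+K(ŷ,ŷ))`` in [0, 1].

    Symmetric; zero iff the labels are equal (for non-empty labels).  Two
    empty labels are identical, so the loss is defined as 0 (logged).
    """
    _check_same_vocabulary(y, yhat)
    denom = len(y.terms) + len(yhat.terms)
    if denom == 0:
        logger.debug("kernel_f1_loss of two empty labels: defined as 0")
        return 0.0
    return 1.0 - 2.0 * len(y.terms & yhat.terms) / denom


class LabelSpace:
    """The candidate output space: distinct labels observed in training.

    Candidates keep first-occurrence order; the argmax tie-break used by
    inference ("earliest candidate wins") therefore depends on input order
    and is reproducible.  ``membership_index`` maps each term to the set of
    candidate positions whose label contains it, which drives per-term
    confidence scoring.
    """

    def __init__(self, candidates: Sequence[StructuredLabel]) -> None:
        if not candidates:
            raise ValidationError("label space needs at least one candidate")
        vocab = candidates[0].vocabulary
        seen: dict[frozenset, int] = {}
        for c in candidates:
            if c.vocabulary != vocab:
                raise ValidationError("candidates mix vocabularies")
            if c.terms in seen:
                raise ValidationError(
                    f"duplicate candidate {sorted(c.terms)!r}"
                )
            seen[c.terms] = len(seen)
        self.candidates: tuple[StructuredLabel, ...] = tuple(candidates)
        self.vocabulary = vocab
        self._index = seen
        self.membership_index: dict[str, frozenset[int]] = {}
        members: dict[str, set[int]] = {}
        for pos, c in enumerate(self.candidates):
            for t in c.terms:
                members.setdefault(t, set()).add(pos)
        self.membership_index = {t: frozenset(p) for t, p in members.items()}
        self._M: np.ndarray | None = None
        self._gram: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def __getitem__(self, pos: int) -> StructuredLabel:
        return self.candidates[pos]

    def index(self, label: StructuredLabel) -> int:
        """Position of ``label`` among candidates, or -1 if absent."""
        return self._index.get(label.terms, -1)

    @property
    def indicator_matrix(self) -> np.ndarray:
        """(n_candidates × vocabulary) binary matrix."""
        if self._M is None:
            self._M = np.vstack([c.indicator for c in self.candidates])
        return self._M

    @property
    def gram(self) -> np.ndarray:
        """Output-kernel Gram matrix between candidates."""
        if self._gram is None:
            M = self.indicator_matrix
            self._gram = M @ M.T
        return self._gram

    def ky(self, labels: Sequence[StructuredLabel]) -> np.ndarray:
        """Output-kernel values between ``labels`` (rows) and candidates."""
        if not labels:
            return np.zeros((0, len(self)))
        for y in labels:
            if y.vocabulary != self.vocabulary:
                raise ValidationError("label vocabulary mismatch")
        L = np.vstack([y.indicator for y in labels])
        return L @ self.indicator_matrix.T


def build_label_space(labels: Sequence[StructuredLabel]) -> LabelSpace:
    """Deduplicate ``labels`` (first-occurrence order) into a LabelSpace."""
    if not labels:
        raise ValidationError("cannot build a label space from no labels")
    distinct: list[StructuredLabel] = []
    seen: set[frozenset] = set()
    for y in labels:
        if y.terms not in seen:
            seen.add(y.terms)
            distinct.append(y)
    return LabelSpace(distinct)
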