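"""Multi-view and chain combination of classifiers; per-term confidences.

Two complementary views are supported: a *cross-species* view built from
sequence features (comparable across organisms) and a *species-specific*
view built from PPI, expression and literature co-mention kernels.  The
multi-view classifier trains one structured SVM per view and predicts by
the argmax of the *summed* compatibility functions

    h(x) = argmax_y  f_cross(x, y) + f_species(x, y).

The chain classifier instead feeds the cross-view predicted label of each
protein, as a binary indicator vector over GO terms, into the
species-specific view as an extra (normalized linear) kernel; the
species-specific prediction is then the final output.

Because the classifier scores whole label sets, per-term confidences are
extracted as the compatibility gap

    c_i(x) = max_{y: i ∈ y} f(x, y) − max_{y: i ∉ y} f(x, y):

positive exactly when term i belongs to the predicted label (for a unique
argmax).  Terms present in every candidate, or in none, cannot be scored
this way and are reported as unscorable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .kernels import KernelMatrix, build_view_kernel, linear_kernel, normalize_kernel, sum_kernels
from .labels import LabelSpace, StructuredLabel
from .ssvm import DualModel, TrainingProblem, argmax_earliest, train_ssvm

logger = logging.getLogger(__name__)


@dataclass
class ViewEnsemble:
    """A trained two-view combination (or a single view)."""

    cross_model: DualModel | None
    species_model: DualModel | None
    mode: str  # "multiview" | "chain" | "single"

    def __post_init__(self) -> None:
        if self.mode not in ("multiview", "chain", "single"):
            raise ValidationError(f"unknown ensemble mode {self.mode!r}")
        models = [m for m in (self.cross_model, self.species_model) if m is not None]
        if not models:
            raise ValidationError("ensemble has no models")
        vocab = models[0].space.vocabulary
        if any(m.space.vocabulary != vocab for m in models):
            raise ValidationError("ensemble models use different vocabularies")


def summed_scores(
    pairs: Sequence[tuple[DualModel, object]],
    space: LabelSpace,
) -> np.ndarray:
    """Candidate-score vector Σ_views f_v(x, ·) for one protein.

    ``pairs`` holds (model, kernel column) per available view; a view whose
    column is None is skipped with a warning (proteins missing from one
    view fall back to the other).
    """
    available = [(m, c) for m, c in pairs if c is not None]
    if not available:
        raise ValidationError("protein has a kernel column in no view")
    if len(available) < len(pairs):
        logger.warning(
            "protein missing from %d view(s); using the remaining view(s)",
            len(pairs) - len(available),
        )
    total = np.zeros(len(space))
    for model, col in available:
        total += model.score_matrix(model.compatibility_column(col), space)[0]
    return total


def predict_multiview(
    ens: ViewEnsemble,
    kx_cross_column,
    kx_species_column,
    space: LabelSpace,
) -> StructuredLabel:
    """Argmax of the summed cross- and species-view compatibilities."""
    scores = summed_scores(
        [(ens.cross_model, kx_cross_column), (ens.species_model, kx_species_column)],
        space,
    )
    return space[argmax_earliest(scores)]


def chain_features(
    cross_model: DualModel,
    kx_cross_columns,
    space: LabelSpace,
) -> pd.DataFrame:
    """Cross-view predictions as binary term features for the species view.

    ``kx_cross_columns`` maps protein id → kernel column against the
    cross-model's training proteins (or is a DataFrame with train ids as
    rows and proteins as columns).  Each protein's row is the indicator
    vector of its cross-view predicted label.
    """
    if isinstance(kx_cross_columns, pd.DataFrame):
        pids = [str(c) for c in kx_cross_columns.columns]
        cols = kx_cross_columns.to_numpy(dtype=float)
    else:
        pids = list(kx_cross_columns)
        cols = np.column_stack(
            [cross_model.compatibility_column(kx_cross_columns[p]) for p in pids]
        )
    F = cross_model.score_matrix(cols, space)
    picks = [argmax_earliest(row) for row in F]
    rows = space.indicator_matrix[picks]
    return pd.DataFrame(rows, index=pids, columns=list(space.vocabulary))


def confidence_scores(
    candidate_scores: np.ndarray,
    space: LabelSpace,
) -> tuple[dict[str, float], list[str]]:
    """Per-term confidence gaps from a vector of candidate compatibilities.

    Returns (term → cᵢ, unscorable terms).  A term is unscorable when every
    candidate contains it or none does.
    """
    scores = np.asarray(candidate_scores, dtype=float)
    if scores.shape != (len(space),):
        raise ValidationError(
            f"expected {len(space)} candidate scores, got {scores.shape}"
        )
    out: dict[str, float] = {}
    unscorable: list[str] = []
    n = len(space)
    for term in space.vocabulary:
        pos = space.membership_index.get(term)
        if not pos or len(pos) == n:
            unscorable.append(term)
            continue
        pos_idx = np.fromiter(pos, int)
        mask = np.zeros(n, bool)
        mask[pos_idx] = True
        out[term] = float(scores[mask].max() - scores[~mask].max())
    return out, unscorable


def score_matrix(
    pairs: Sequence[tuple[DualModel, np.ndarray]],
    protein_ids: Sequence[str],
    space: LabelSpace,
) -> pd.DataFrame:
    """Per-term confidence table (proteins × scorable terms).

    ``pairs`` holds (model, (n_train × P) kernel column block) per view;
    columns are aligned with ``protein_ids``.
    """
    total = np.zeros((len(protein_ids), len(space)))
    for model, block in pairs:
        total += model.score_matrix(np.asarray(block, dtype=float), space)
    rows = []
    scorable: list[str] | None = None
    for p in range(len(protein_ids)):
        conf, _ = confidence_scores(total[p], space)
        if scorable is None:
            scorable = sorted(conf)
        rows.append([conf[t] for t in scorable])
    return pd.DataFrame(rows, index=list(protein_ids), columns=scorable or [])


def train_chain(
    kx_cross: KernelMatrix,
    species_sources: Sequence,
    train_ids: Sequence[str],
    labels: Sequence[StructuredLabel],
    space: LabelSpace,
    *,
    c_over_n: float = 1.0,
    tolerance: float = 1e-4,
) -> ViewEnsemble:
    """Train the chain classifier.

    ``kx_cross`` and the species sources cover the full protein universe
    (training + prediction targets).  The cross model is trained on
    ``train_ids``; its predictions over *all* proteins become an indicator
    feature table whose normalized linear kernel is summed into the
    species-specific view; the species model trained on that summed kernel
    is the ensemble's final predictor.
    """
    all_ids = list(kx_cross.ids)
    cross_problem = TrainingProblem(
        kx_cross.subset(train_ids), list(labels), space,
        c_over_n=c_over_n, tolerance=tolerance,
    )
    cross_model = train_ssvm(cross_problem)
    cols = kx_cross.columns(list(train_ids), all_ids)
    feats = chain_features(
        cross_model, pd.DataFrame(cols, columns=all_ids), space
    )
    chain_kernel = normalize_kernel(linear_kernel(feats))
    species_kernel = build_view_kernel(
        list(species_sources) + [chain_kernel], ids=all_ids
    )
    species_problem = TrainingProblem(
        species_kernel.subset(train_ids), list(labels), space,
        c_over_n=c_over_n, tolerance=tolerance,
    )
    species_model = train_ssvm(species_problem)
    ens = ViewEnsemble(cross_model, species_model, "chain")
    ens.species_kernel = species_kernel  # full-universe kernel for prediction
    return ens
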