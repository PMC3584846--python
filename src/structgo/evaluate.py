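"""Term-level evaluation, identity-aware cross-validation, model selection.

Performance is measured per GO term from the per-term confidence scores:
area under the ROC curve (equivalently the Mann–Whitney statistic, ties
counted one half) and precision at 20% recall (P20R, the precision at the
first score threshold whose recall reaches the requested level; no
interpolation).  Macro averages are unweighted means over scorable terms,
and AUC is additionally aggregated by term depth (longest path to the
namespace root).  Terms with a single class among evaluated proteins are
skipped and reported.

Cross-validation folds respect sequence identity: proteins are grouped
into clusters (connected components of the >50%-identity graph, supplied
or derived from a pairwise identity table by single linkage) and whole
clusters are assigned to folds, so no two proteins with high identity end
up in different folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import ValidationError
from .kernels import KernelMatrix
from .labels import LabelSpace, StructuredLabel, build_label_space
from .ontology import GeneOntology
from .ssvm import TrainingProblem, train_ssvm
from .views import score_matrix

logger = logging.getLogger(__name__)


def term_auc(scores: Sequence[float], truths: Sequence[int]) -> float:
    """ROC AUC = fraction of (positive, negative) pairs ranked correctly,
    ties counted ½.  Requires both classes present."""
    truths = np.asarray(truths, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if truths.min() == truths.max():
        raise ValidationError("AUC undefined for single-class truths")
    return float(roc_auc_score(truths, scores))


def precision_at_recall(
    scores: Sequence[float],
    truths: Sequence[int],
    recall_level: float = 0.2,
) -> float:
    """Precision at the first threshold whose recall reaches ``recall_level``.

    Thresholds sweep from the highest score down; tied scores enter
    together.  Requires at least one positive.
    """
    truths = np.asarray(truths, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(truths.sum())
    if n_pos == 0:
        raise ValidationError("P20R undefined without positives")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truths[order]
    tp = np.cumsum(t)
    fp = np.cumsum(1 - t)
    # last index of each tied-score group
    group_end = np.flatnonzero(np.append(np.diff(s) != 0, True))
    for g in group_end:
        recall = tp[g] / n_pos
        if recall >= recall_level:
            return float(tp[g] / (tp[g] + fp[g]))
    return float(tp[-1] / (tp[-1] + fp[-1]))  # pragma: no cover - recall<1 impossible


@dataclass
class EvaluationReport:
    """Per-term and aggregate performance."""

    per_term: pd.DataFrame  # columns: term, namespace, depth, auc, p20r, n_pos
    macro_auc: float
    macro_p20r: float
    per_depth: dict[int, float]
    skipped_terms: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.per_term.to_csv(path, sep="\t", index=False)


def evaluate(
    score_table: pd.DataFrame,
    truth_labels: Sequence[StructuredLabel] | Mapping[str, StructuredLabel],
    ontology: GeneOntology,
) -> EvaluationReport:
    """Evaluate a proteins × terms confidence table against true labels.

    ``truth_labels`` is aligned with the table rows (or maps protein id to
    label).  NaN cells mark proteins unscored for a term and are excluded
    from that term's evaluation.  Single-class terms are skipped and listed
    in ``skipped_terms``.
    """
    if isinstance(truth_labels, Mapping):
        try:
            labels = [truth_labels[p] for p in score_table.index]
        except KeyError as exc:
            raise ValidationError(
                f"no truth label for protein {exc.args[0]!r}"
            ) from None
    else:
        if len(truth_labels) != len(score_table):
            raise ValidationError(
                f"{len(truth_labels)} truth labels for "
                f"{len(score_table)} score rows"
            )
        labels = list(truth_labels)
    rows = []
    skipped: list[str] = []
    for term in score_table.columns:
        if term not in ontology:
            raise ValidationError(f"score table term {term!r} not in ontology")
        col = score_table[term].to_numpy(dtype=float)
        mask = ~np.isnan(col)
        truth = np.array([int(term in y) for y in labels])[mask]
        col = col[mask]
        if len(col) == 0 or truth.min() == truth.max():
            skipped.append(term)
            continue
        rows.append(
            (
                term,
                ontology.namespace_of[term],
                ontology.term_depth(term),
                term_auc(col, truth),
                precision_at_recall(col, truth),
                int(truth.sum()),
            )
        )
    per_term = pd.DataFrame(
        rows, columns=["term", "namespace", "depth", "auc", "p20r", "n_pos"]
    )
    if skipped:
        logger.info("evaluate: %d single-class terms skipped", len(skipped))
    macro_auc = float(per_term["auc"].mean()) if len(per_term) else float("nan")
    macro_p20r = float(per_term["p20r"].mean()) if len(per_term) else float("nan")
    per_depth = (
        per_term.groupby("depth")["auc"].mean().to_dict() if len(per_term) else {}
    )
    return EvaluationReport(
        per_term=per_term,
        macro_auc=macro_auc,
        macro_p20r=macro_p20r,
        per_depth={int(k): float(v) for k, v in per_depth.items()},
        skipped_terms=skipped,
    )


# -- folds -------------------------------------------------------------------


def clusters_from_identity(
    pairs: Iterable[tuple[str, str, float]],
    ids: Sequence[str],
    threshold: float = 0.5,
) -> dict[str, int]:
    """Single-linkage clusters from pairwise identities above ``threshold``."""
    parent = {p: p for p in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, ident in pairs:
        if ident > threshold and a in parent and b in parent:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    roots = {p: find(p) for p in ids}
    numbering = {r: i for i, r in enumerate(dict.fromkeys(roots.values()))}
    return {p: numbering[r] for p, r in roots.items()}


def identity_aware_folds(
    ids: Sequence[str],
    clusters: Mapping[str, object] | None = None,
    k: int = 5,
    seed: int = 0,
) -> dict[str, int]:
    """Assign whole identity clusters to ``k`` folds, balancing sizes.

    Clusters are shuffled (seeded), then greedily assigned largest-first to
    the currently smallest fold; a cluster never spans folds.  ``clusters``
    defaults to singletons.
    """
    ids = [str(p) for p in ids]
    if clusters is None:
        clusters = {p: p for p in ids}
    missing = [p for p in ids if p not in clusters]
    if missing:
        raise ValidationError(
            f"proteins without a cluster assignment: {missing[:5]!r}"
        )
    groups: dict[object, list[str]] = {}
    for p in ids:
        groups.setdefault(clusters[p], []).append(p)
    if k > len(groups):
        raise ValidationError(
            f"cannot make {k} folds from {len(groups)} identity clusters"
        )
    rng = np.random.default_rng(seed)
    order = list(groups)
    rng.shuffle(order)
    order.sort(key=lambda g: -len(groups[g]))  # stable: keeps shuffle for ties
    fold_sizes = [0] * k
    assignment: dict[str, int] = {}
    for g in order:
        fold = int(np.argmin(fold_sizes))
        for p in groups[g]:
            assignment[p] = fold
        fold_sizes[fold] += len(groups[g])
    return assignment


# -- model selection and cross-validation ------------------------------------


def _fold_score_table(
    kernels: Sequence[KernelMatrix],
    labels: Mapping[str, StructuredLabel],
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    c_over_n: float,
    tolerance: float,
) -> pd.DataFrame:
    """Train one model per view kernel on ``train_ids``; confidence-score
    ``test_ids`` from the summed compatibilities."""
    train_labels = [labels[p] for p in train_ids]
    space = build_label_space(train_labels)
    pairs = []
    for K in kernels:
        problem = TrainingProblem(
            K.subset(train_ids), train_labels, space,
            c_over_n=c_over_n, tolerance=tolerance,
        )
        model = train_ssvm(problem)
        pairs.append((model, K.columns(list(train_ids), list(test_ids))))
    return score_matrix(pairs, list(test_ids), space)


def select_C(
    kx: KernelMatrix,
    labels: Mapping[str, StructuredLabel],
    c_over_n_grid: Sequence[float],
    inner_k: int = 4,
    seed: int = 0,
    clusters: Mapping[str, object] | None = None,
    ontology: GeneOntology | None = None,
    tolerance: float = 1e-4,
) -> float:
    """Nested cross-validation over the regularization grid.

    Picks the C/n value with the highest mean inner-fold macro AUC; ties go
    to the smaller value.  ``ontology`` is needed for depth bookkeeping in
    the inner evaluation reports (term skipping does not depend on it).
    """
    if not len(c_over_n_grid):
        raise ValidationError("empty C grid")
    ids = list(kx.ids)
    folds = identity_aware_folds(ids, clusters, k=inner_k, seed=seed)
    results: list[tuple[float, float]] = []
    for c in sorted(c_over_n_grid):
        aucs: list[float] = []
        for fold in range(inner_k):
            test = [p for p in ids if folds[p] == fold]
            train = [p for p in ids if folds[p] != fold]
            if not test or not train:
                raise ValidationError("degenerate inner fold")
            table = _fold_score_table(
                [kx], labels, train, test, c, tolerance
            )
            for term in table.columns:
                truth = np.array([int(term in labels[p]) for p in test])
                if truth.min() != truth.max():
                    aucs.append(term_auc(table[term].to_numpy(), truth))
        mean_auc = float(np.mean(aucs)) if aucs else float("nan")
        logger.info("select_C: C/n=%g inner macro AUC %.4f", c, mean_auc)
        results.append((c, mean_auc))
    best = max(results, key=lambda r: (np.nan_to_num(r[1], nan=-1.0), -r[0]))
    return best[0]


def cross_validate(
    view_kernels: Sequence[KernelMatrix],
    labels: Mapping[str, StructuredLabel],
    ontology: GeneOntology,
    k: int = 5,
    clusters: Mapping[str, object] | None = None,
    seed: int = 0,
    c_over_n: float = 1.0,
    c_grid: Sequence[float] | None = None,
    inner_k: int = 4,
    tolerance: float = 1e-4,
) -> tuple[EvaluationReport, dict[str, int]]:
    """Outer k-fold identity-aware CV with optional nested C selection.

    Each view kernel spans all annotated proteins; per fold, one model per
    view is trained on the training proteins and the held-out proteins are
    confidence-scored from the summed compatibilities.  The pooled score
    table is evaluated per term.
    """
    ids = [p for p in view_kernels[0].ids if p in labels]
    folds = identity_aware_folds(ids, clusters, k=k, seed=seed)
    tables: list[pd.DataFrame] = []
    for fold in range(k):
        test = [p for p in ids if folds[p] == fold]
        train = [p for p in ids if folds[p] != fold]
        c = c_over_n
        if c_grid:
            c = select_C(
                view_kernels[0].subset(train),
                labels,
                c_grid,
                inner_k=inner_k,
                seed=seed + fold + 1,
                clusters=clusters,
                ontology=ontology,
                tolerance=tolerance,
            )
            logger.info("fold %d: selected C/n=%g", fold, c)
        tables.append(
            _fold_score_table(view_kernels, labels, train, test, c, tolerance)
        )
    score_table = pd.concat(tables).reindex(ids)
    report = evaluate(score_table, {p: labels[p] for p in ids}, ontology)
    return report, folds
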