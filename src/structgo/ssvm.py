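"""Margin-rescaling structured SVM trained in the dual by working sets.

The model learns a compatibility function f(x, y) = wᵀψ(x, y) over joint
(protein, label) feature space; prediction is the argmax of f over the
candidate label space.  Training solves

    min_{w,ξ} ½‖w‖² + (C/n) Σᵢ ξᵢ
    s.t.  wᵀ(ψ(xᵢ,yᵢ) − ψ(xᵢ,y)) ≥ Δ(y,yᵢ) − ξᵢ   ∀i, ∀y ≠ yᵢ,   ξᵢ ≥ 0

in its dual, where everything is expressed through kernels: the joint
kernel is the product K_X(x₁,x₂)·K_Y(y₁,y₂), so with dual coefficients
α_{iy} the compatibility expands to

    f(x, y) = Σ_{(i,y')} α_{iy'} · K_X(xᵢ, x) · (K_Y(yᵢ, y) − K_Y(y', y)).

The dual is optimized by a working-set strategy: repeatedly find each
example's most violated margin constraint (the loss-augmented argmax over
candidates), add it when its violation exceeds the example's current slack
by more than a tolerance ε, and re-solve the restricted quadratic program
over the working set.  The restricted QP — maximize Σ α·Δ − ½ αᵀJα subject
to α ≥ 0 and Σ_y α_{iy} ≤ C/n per example — is solved by cyclic coordinate
ascent plus SMO-style pairwise transfers within an example's coefficient
group (needed because the per-example cap couples those coordinates).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numba as _numba
import numpy as np
import pandas as pd

from .errors import ValidationError
from .kernels import KernelMatrix
from .labels import LabelSpace, StructuredLabel

logger = logging.getLogger(__name__)

#: coefficients below this are pruned from the compatibility expansion
ALPHA_PRUNE = 1e-12
_DIAG_JITTER = 1e-10
#: score ties within this are resolved to the earliest candidate
TIE_TOL = 1e-9


def argmax_earliest(scores: np.ndarray, tol: float = TIE_TOL) -> int:
    """Earliest index whose score is within ``tol`` of the maximum.

    Dual solutions are only unique up to numerical tolerance, so exact
    score ties between candidates come back perturbed at the 1e-11 level;
    resolving ties within ``tol`` keeps the argmax reproducible across
    optimization paths.
    """
    scores = np.asarray(scores)
    return int(np.argmax(scores >= scores.max() - tol))


@dataclass
class TrainingProblem:
    """A training instance: kernel, aligned labels, candidate space, C.

    ``c_over_n`` is the per-example dual cap C/n (1.0 is the empirically
    best operating point for this model family).  ``tolerance`` is the
    working-set ε.
    """

    kx: KernelMatrix
    labels: Sequence[StructuredLabel]
    space: LabelSpace
    c_over_n: float = 1.0
    tolerance: float = 1e-4

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.kx):
            raise ValidationError(
                f"{len(self.labels)} labels for {len(self.kx)} kernel ids"
            )
        if self.c_over_n <= 0:
            raise ValidationError("c_over_n must be positive")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        self.true_idx = np.array(
            [self.space.index(y) for y in self.labels], dtype=int
        )
        if (self.true_idx < 0).any():
            missing = [i for i, s in enumerate(self.true_idx) if s < 0]
            raise ValidationError(
                f"training labels at positions {missing[:5]} are not in the "
                "candidate space"
            )
        G = self.space.gram
        sizes = np.diag(G)
        denom = sizes[self.true_idx][:, None] + sizes[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            L = 1.0 - 2.0 * G[self.true_idx, :] / denom
        # two empty labels are identical: loss 0
        self.loss = np.where(denom > 0, L, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class DualModel:
    """A trained structured SVM in dual form.

    ``constraints`` lists (example index, candidate index) pairs; ``alpha``
    holds the matching dual coefficients.  Together with the training labels
    and candidate space this reconstructs f exactly — the primal w is never
    materialized.
    """

    train_ids: tuple[str, ...]
    labels: tuple[StructuredLabel, ...]
    space: LabelSpace
    constraints: list[tuple[int, int]]
    alpha: np.ndarray
    c_over_n: float
    objective_trace: list[float] = field(default_factory=list)
    tolerance: float = 1e-4
    problem: TrainingProblem | None = None

    def active(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(example idx, candidate idx, α) of non-pruned constraints."""
        if not self.constraints:
            return (np.zeros(0, int), np.zeros(0, int), np.zeros(0))
        I = np.array([c[0] for c in self.constraints], dtype=int)
        S = np.array([c[1] for c in self.constraints], dtype=int)
        keep = self.alpha > ALPHA_PRUNE
        return I[keep], S[keep], self.alpha[keep]

    def _true_indices(self) -> np.ndarray:
        """Candidate-space positions of the training labels (cached)."""
        ti = getattr(self, "_ti_cache", None)
        if ti is None:
            ti = np.array([self.space.index(y) for y in self.labels])
            self._ti_cache = ti
        return ti

    def _difference_rows(
        self, I: np.ndarray, S: np.ndarray, space: LabelSpace
    ) -> np.ndarray:
        """Rows K_Y(yᵢ, ·) − K_Y(y', ·) over ``space`` candidates."""
        ti = self._true_indices()
        if (ti >= 0).all():
            M = self.space.indicator_matrix
            diff = M[ti[I]] - M[S]  # (m × V)
            return diff @ space.indicator_matrix.T
        true_labels = [self.labels[i] for i in I]
        cons_labels = [self.space[s] for s in S]
        return space.ky(true_labels) - space.ky(cons_labels)

    def score_matrix(
        self, columns: np.ndarray, space: LabelSpace | None = None
    ) -> np.ndarray:
        """Compatibility of each column (protein) with each candidate.

        ``columns`` is an (n_train × P) block of input-kernel values
        K_X(xᵢ, x); the result is (P × |space|).
        """
        space = space or self.space
        columns = np.asarray(columns, dtype=float)
        if columns.ndim == 1:
            columns = columns[:, None]
        if columns.shape[0] != len(self.train_ids):
            raise ValidationError(
                f"kernel columns have {columns.shape[0]} rows; model has "
                f"{len(self.train_ids)} training examples"
            )
        I, S, a = self.active()
        if len(a) == 0:
            return np.zeros((columns.shape[1], len(space)))
        D = self._difference_rows(I, S, space)  # (m × |space|)
        W = a[:, None] * columns[I, :]  # (m × P)
        return W.T @ D

    def compatibility_column(self, kx_column) -> np.ndarray:
        """Coerce a mapping/array of K_X(xᵢ, x) values into train-id order."""
        if isinstance(kx_column, Mapping):
            try:
                return np.array(
                    [float(kx_column[pid]) for pid in self.train_ids]
                )
            except KeyError as exc:
                raise KeyError(
                    f"kernel column missing training protein {exc.args[0]!r}"
                ) from None
        col = np.asarray(kx_column, dtype=float)
        if col.shape != (len(self.train_ids),):
            raise ValidationError(
                f"kernel column shape {col.shape} does not match "
                f"{len(self.train_ids)} training examples"
            )
        return col


def compatibility(model: DualModel, kx_column, y: StructuredLabel) -> float:
    """Dual-expanded compatibility f(x, y) for one protein and one label."""
    col = model.compatibility_column(kx_column)
    space = LabelSpace([y]) if model.space.index(y) < 0 else model.space
    if space is model.space:
        return float(model.score_matrix(col)[0, model.space.index(y)])
    return float(model.score_matrix(col, space)[0, 0])


def find_most_violated(model: DualModel, i: int) -> tuple[StructuredLabel, float]:
    """The loss-augmented argmax candidate for training example ``i``.

    Margin rescaling: ŷ = argmax_{y ≠ yᵢ} Δ(y, yᵢ) + f(xᵢ, y); the returned
    violation is Δ(ŷ, yᵢ) − (f(xᵢ, yᵢ) − f(xᵢ, ŷ)).  Ties break toward the
    earliest candidate.
    """
    problem = model.problem
    if problem is None:
        raise ValidationError("model is not attached to a training problem")
    f = model.score_matrix(problem.kx.values[:, i])[0]
    ti = problem.true_idx[i]
    augmented = problem.loss[i] + f
    augmented[ti] = -np.inf
    if np.all(np.isinf(augmented)):  # candidate space of size 1
        return problem.space[ti], -np.inf
    s = int(np.argmax(augmented))
    violation = problem.loss[i, s] - (f[ti] - f[s])
    return problem.space[s], violation


def _constraint_gram(
    problem: TrainingProblem, I: np.ndarray, S: np.ndarray
) -> np.ndarray:
    """Dual Gram J[c,d] = K_X(xᵢ,xⱼ)·(K_Y(yᵢ,yⱼ) − K_Y(yᵢ,y'_d)
    − K_Y(y'_c,yⱼ) + K_Y(y'_c,y'_d))."""
    G = problem.space.gram
    ti = problem.true_idx
    KX = problem.kx.values[np.ix_(I, I)]
    out = (
        G[np.ix_(ti[I], ti[I])]
        - G[np.ix_(ti[I], S)]
        - G[np.ix_(S, ti[I])]
        + G[np.ix_(S, S)]
    )
    return KX * out


def _solve_qp_smo(
    J: np.ndarray,
    b: np.ndarray,
    groups: np.ndarray,
    cap: float,
    start: np.ndarray | None = None,
    tol: float = 1e-10,
    max_sweeps: int = 20000,
) -> np.ndarray:
    """Maximize bᵀα − ½αᵀJα s.t. α ≥ 0 and Σ_{c∈group} α_c ≤ cap.

    Cyclic coordinate ascent handles the box and slack-capacity constraints;
    pairwise transfers inside each group handle the case where a group sits
    at its cap and mass must move between its coordinates.
    """
    m = len(b)
    alpha = np.zeros(m) if start is None else start.astype(float).copy()
    diag = J.diagonal().copy()
    degenerate = diag <= ALPHA_PRUNE
    if degenerate.any():
        logger.debug(
            "restricted QP: %d near-zero diagonal entries jittered",
            int(degenerate.sum()),
        )
        diag = diag + _DIAG_JITTER * degenerate
    members: dict[int, list[int]] = {}
    for c, g in enumerate(groups):
        members.setdefault(int(g), []).append(c)
    pairs = np.array(
        [
            (c, d)
            for idx in members.values()
            for a_i, c in enumerate(idx)
            for d in idx[a_i + 1:]
        ],
        dtype=np.int64,
    ).reshape(-1, 2)
    converged = _smo_sweeps(
        np.ascontiguousarray(J, dtype=np.float64),
        np.asarray(b, dtype=np.float64),
        np.asarray(groups, dtype=np.int64),
        float(cap),
        alpha,
        np.asarray(diag, dtype=np.float64),
        pairs,
        float(tol),
        int(max_sweeps),
    )
    if not converged:  # pragma: no cover - safety net
        logger.warning("restricted QP did not reach tolerance %g", tol)
    return alpha


@_numba.njit(cache=True)
def _smo_sweeps(J, b, groups, cap, alpha, diag, pairs, tol, max_sweeps):
    """Cyclic coordinate ascent + within-group pairwise transfers (in place)."""
    m = len(b)
    n_groups = int(groups.max()) + 1 if m else 1
    group_sum = np.zeros(n_groups)
    for c in range(m):
        group_sum[groups[c]] += alpha[c]
    grad = b - J @ alpha  # maintained incrementally
    for _ in range(max_sweeps):
        delta = 0.0
        for c in range(m):
            if alpha[c] == 0.0 and grad[c] <= 0.0:
                continue
            g = groups[c]
            new = alpha[c] + grad[c] / diag[c]
            room = cap - (group_sum[g] - alpha[c])
            if room < 0.0:
                room = 0.0
            if new < 0.0:
                new = 0.0
            elif new > room:
                new = room
            step = new - alpha[c]
            if step != 0.0:
                group_sum[g] += step
                alpha[c] = new
                for j in range(m):
                    grad[j] -= step * J[j, c]
                if abs(step) > delta:
                    delta = abs(step)
        for p in range(pairs.shape[0]):
            c, d = pairs[p, 0], pairs[p, 1]
            kappa = diag[c] + diag[d] - 2.0 * J[c, d]
            diff = grad[c] - grad[d]
            if kappa > 1e-12:
                t = diff / kappa
            elif diff > 0.0:
                t = np.inf
            elif diff < 0.0:
                t = -np.inf
            else:
                t = 0.0
            if t < -alpha[c]:
                t = -alpha[c]
            elif t > alpha[d]:
                t = alpha[d]
            if t != 0.0:
                alpha[c] += t
                alpha[d] -= t
                for j in range(m):
                    grad[j] -= t * (J[j, c] - J[j, d])
                if abs(t) > delta:
                    delta = abs(t)
        if delta < tol:
            return True
    return False


def solve_restricted_qp(
    problem: TrainingProblem,
    working_set: Sequence[tuple[int, int]],
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Solve the dual QP restricted to ``working_set`` constraints.

    ``working_set`` holds (example index, candidate index) pairs; returns
    the coefficient vector in the same order, feasible for α ≥ 0 and the
    per-example cap Σ_y α_{iy} ≤ C/n.
    """
    if not working_set:
        raise ValidationError("working set is empty")
    I = np.array([c[0] for c in working_set], dtype=int)
    S = np.array([c[1] for c in working_set], dtype=int)
    J = _constraint_gram(problem, I, S)
    b = problem.loss[I, S]
    return _solve_qp_smo(J, b, I, problem.c_over_n, start=start)


def dual_objective(
    problem: TrainingProblem,
    working_set: Sequence[tuple[int, int]],
    alpha: np.ndarray,
) -> float:
    if not working_set:
        return 0.0
    I = np.array([c[0] for c in working_set], dtype=int)
    S = np.array([c[1] for c in working_set], dtype=int)
    J = _constraint_gram(problem, I, S)
    b = problem.loss[I, S]
    return float(b @ alpha - 0.5 * alpha @ J @ alpha)


def _make_model(problem: TrainingProblem) -> DualModel:
    return DualModel(
        train_ids=tuple(problem.kx.ids),
        labels=tuple(problem.labels),
        space=problem.space,
        constraints=[],
        alpha=np.zeros(0),
        c_over_n=problem.c_over_n,
        objective_trace=[0.0],
        tolerance=problem.tolerance,
        problem=problem,
    )


def train_ssvm(problem: TrainingProblem, max_passes: int = 1000) -> DualModel:
    """Working-set training of the margin-rescaling structured SVM.

    For each example in turn, the most violated constraint is added to the
    working set whenever its violation exceeds the example's current slack
    ξᵢ by more than ε, and the restricted QP is re-solved (warm-started).
    Training stops when a full pass adds no constraint, i.e. no constraint
    outside the working set is violated more than the ones inside it, up to
    ε.  Deterministic given the problem.
    """
    model = _make_model(problem)
    n = problem.n
    eps = problem.tolerance
    in_ws: set[tuple[int, int]] = set()
    own: dict[int, list[int]] = {i: [] for i in range(n)}
    for pass_no in range(max_passes):
        added = 0
        for i in range(n):
            f = model.score_matrix(problem.kx.values[:, i])[0]
            ti = problem.true_idx[i]
            augmented = problem.loss[i] + f
            augmented[ti] = -np.inf
            if np.all(np.isinf(augmented)):  # candidate space of size 1
                continue
            s = int(np.argmax(augmented))
            violation = problem.loss[i, s] - (f[ti] - f[s])
            xi = 0.0
            if own[i]:
                xi = max(
                    0.0,
                    max(problem.loss[i, c] - (f[ti] - f[c]) for c in own[i]),
                )
            if violation > xi + eps and (i, s) not in in_ws:
                model.constraints.append((i, s))
                in_ws.add((i, s))
                own[i].append(s)
                start = np.append(model.alpha, 0.0)
                model.alpha = solve_restricted_qp(
                    problem, model.constraints, start=start
                )
                obj = dual_objective(problem, model.constraints, model.alpha)
                if obj < model.objective_trace[-1] - 1e-9:
                    logger.warning(
                        "dual objective decreased: %.12g -> %.12g",
                        model.objective_trace[-1], obj,
                    )
                model.objective_trace.append(obj)
                added += 1
        logger.info(
            "pass %d: %d constraints added, working set %d, objective %.6g",
            pass_no + 1, added, len(model.constraints),
            model.objective_trace[-1],
        )
        if added == 0:
            break
    else:
        warnings.warn(
            f"working-set training hit the pass cap ({max_passes}); "
            "returning the best model so far",
            RuntimeWarning,
        )
    _check_feasible(model)
    return model


def _example_slack(model: DualModel, i: int) -> float:
    """ξᵢ = max(0, max violation over example i's working-set constraints)."""
    problem = model.problem
    own = [s for (j, s) in model.constraints if j == i]
    if not own:
        return 0.0
    f = model.score_matrix(problem.kx.values[:, i])[0]
    ti = problem.true_idx[i]
    viol = [problem.loss[i, s] - (f[ti] - f[s]) for s in own]
    return max(0.0, max(viol))


def _check_feasible(model: DualModel) -> None:
    sums: dict[int, float] = {}
    for (i, _), a in zip(model.constraints, model.alpha):
        sums[i] = sums.get(i, 0.0) + a
    for i, total in sums.items():
        if total > model.c_over_n + 1e-8:
            raise ValidationError(
                f"dual infeasible: example {i} has Σα = {total:.3g} > C/n"
            )


def train_exhaustive(problem: TrainingProblem) -> DualModel:
    """Solve the dual with *all* margin constraints enumerated.

    Exponential in general; intended as the exact reference on small
    problems (the working-set path must match its objective and
    predictions).
    """
    model = _make_model(problem)
    ws = [
        (i, s)
        for i in range(problem.n)
        for s in range(len(problem.space))
        if s != problem.true_idx[i]
    ]
    if not ws:
        return model
    model.constraints = ws
    model.alpha = solve_restricted_qp(problem, ws)
    model.objective_trace.append(dual_objective(problem, ws, model.alpha))
    _check_feasible(model)
    return model


def predict(
    model: DualModel,
    columns,
    space: LabelSpace | None = None,
) -> list[StructuredLabel]:
    """Argmax-compatibility label for each protein.

    ``columns`` is an (n_train × P) array of input-kernel values, a single
    column, or a mapping protein → column.  Ties break to the earliest
    candidate, so a zero model predicts the first candidate everywhere.
    """
    space = space or model.space
    if len(space) == 0:
        raise ValidationError("empty candidate space")
    if isinstance(columns, Mapping):
        cols = np.column_stack(
            [model.compatibility_column(columns[p]) for p in columns]
        )
    else:
        cols = np.asarray(columns, dtype=float)
        if cols.ndim == 1:
            cols = cols[:, None]
    F = model.score_matrix(cols, space)
    return [space[argmax_earliest(row)] for row in F]
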