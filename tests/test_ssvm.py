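import numpy as np
import pytest

from structgo import (
    KernelMatrix,
    StructuredLabel,
    TrainingProblem,
    build_label_space,
    build_view_kernel,
    compatibility,
    find_most_violated,
    make_synthetic_dataset,
    make_toy_ontology,
    predict,
    solve_restricted_qp,
    train_exhaustive,
    train_ssvm,
    SyntheticSpec,
)
from structgo.errors import ValidationError
from structgo.ssvm import DualModel, dual_objective, _make_model

from conftest import random_toy_problem

VOCAB = tuple("abc")


def lab(*terms):
    return StructuredLabel(terms, VOCAB)


def toy_problem(kx_values, labels, candidates, ids=None, c_over_n=1.0):
    ids = ids or [f"p{i}" for i in range(len(labels))]
    return TrainingProblem(
        KernelMatrix(ids, np.asarray(kx_values, dtype=float)),
        labels,
        build_label_space(candidates),
        c_over_n=c_over_n,
    )


class TestCompatibility:
    def make_single_constraint_model(self):
        problem = toy_problem(
            [[1.0]], [lab("a")], [lab("a"), lab("b")], ids=["x0"]
        )
        model = _make_model(problem)
        model.constraints = [(0, 1)]  # candidate {b}
        model.alpha = np.array([1.0])
        return model

    def test_zero_model_scores_zero(self):
        problem = toy_problem([[1.0]], [lab("a")], [lab("a"), lab("b")])
        model = _make_model(problem)
        assert compatibility(model, {"p0": 1.0}, lab("a")) == 0.0
        assert compatibility(model, {"p0": 0.3}, lab("b", "c")) == 0.0

    def test_single_constraint_hand_expansion(self):
        model = self.make_single_constraint_model()
        # f(x, {a}) = 1 * K_X * (K_Y({a},{a}) - K_Y({b},{a})) = 1 - 0
        assert compatibility(model, {"x0": 1.0}, lab("a")) == pytest.approx(1.0)
        assert compatibility(model, {"x0": 1.0}, lab("b")) == pytest.approx(-1.0)

    def test_missing_kernel_entry(self):
        model = self.make_single_constraint_model()
        with pytest.raises(KeyError):
            compatibility(model, {"wrong": 1.0}, lab("a"))


class TestFindMostViolated:
    def test_zero_model_returns_max_loss_label(self):
        problem = toy_problem(
            np.eye(1), [lab("a")], [lab("a"), lab("a", "b"), lab("c")]
        )
        model = _make_model(problem)
        yhat, violation = find_most_violated(model, 0)
        assert yhat == lab("c")
        assert violation == pytest.approx(1.0)

    def test_single_candidate_space(self):
        problem = toy_problem(np.eye(2), [lab("a"), lab("a")], [lab("a")])
        model = train_ssvm(problem)
        assert model.constraints == []
        preds = predict(model, problem.kx.values)
        assert all(p == lab("a") for p in preds)

    def test_trained_model_has_no_large_violations(self):
        problem = toy_problem(
            np.eye(3),
            [lab("a"), lab("b"), lab("c")],
            [lab("a"), lab("b"), lab("c")],
        )
        model = train_ssvm(problem)
        for i in range(3):
            _, violation = find_most_violated(model, i)
            assert violation <= problem.tolerance + 1e-9


class TestRestrictedQP:
    def test_single_constraint_closed_form(self):
        # 1-D dual: maximize αΔ - α²g/2 under 0 ≤ α ≤ C/n -> α = min(C/n, Δ/g)
        problem = toy_problem(np.eye(1), [lab("a")], [lab("a"), lab("b")])
        alpha = solve_restricted_qp(problem, [(0, 1)])
        # Δ({b},{a}) = 1; self-Gram = K_X(0,0)·(1 - 0 - 0 + 1) = 2
        assert alpha == pytest.approx([0.5])

    def test_cap_binds_for_small_c(self):
        problem = toy_problem(
            np.eye(1), [lab("a")], [lab("a"), lab("b")], c_over_n=0.2
        )
        alpha = solve_restricted_qp(problem, [(0, 1)])
        assert alpha == pytest.approx([0.2])

    def test_empty_working_set_rejected(self):
        problem = toy_problem(np.eye(1), [lab("a")], [lab("a"), lab("b")])
        with pytest.raises(ValidationError):
            solve_restricted_qp(problem, [])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_scipy_slsqp(self, seed):
        """Independent general-purpose solver agrees on the dual optimum."""
        from scipy.optimize import minimize

        problem = random_toy_problem(seed)
        ws = [
            (i, s)
            for i in range(problem.n)
            for s in range(len(problem.space))
            if s != problem.true_idx[i]
        ]
        alpha = solve_restricted_qp(problem, ws)
        obj = dual_objective(problem, ws, alpha)

        from structgo.ssvm import _constraint_gram

        I = np.array([c[0] for c in ws])
        S = np.array([c[1] for c in ws])
        J = _constraint_gram(problem, I, S)
        b = problem.loss[I, S]

        def neg(a):
            return -(b @ a - 0.5 * a @ J @ a)

        cons = [
            {
                "type": "ineq",
                "fun": (lambda a, i=i: problem.c_over_n - a[I == i].sum()),
            }
            for i in set(I.tolist())
        ]
        res = minimize(
            neg,
            np.zeros(len(ws)),
            bounds=[(0, None)] * len(ws),
            constraints=cons,
            method="SLSQP",
            options={"ftol": 1e-12, "maxiter": 500},
        )
        assert obj >= -res.fun - 1e-6
        assert abs(obj - (-res.fun)) < 1e-5

    def test_feasibility_of_returned_coefficients(self):
        for seed in range(5):
            problem = random_toy_problem(seed + 100)
            ws = [
                (i, s)
                for i in range(problem.n)
                for s in range(len(problem.space))
                if s != problem.true_idx[i]
            ]
            alpha = solve_restricted_qp(problem, ws)
            assert np.all(alpha >= -1e-12)
            for i in range(problem.n):
                mask = np.array([c[0] == i for c in ws])
                assert alpha[mask].sum() <= problem.c_over_n + 1e-8


class TestTraining:
    def test_orthonormal_two_examples_zero_training_error(self):
        problem = toy_problem(
            np.eye(2), [lab("a"), lab("b")], [lab("a"), lab("b")]
        )
        model = train_ssvm(problem)
        preds = predict(model, problem.kx.values)
        assert preds == [lab("a"), lab("b")]
        oracle = train_exhaustive(problem)
        assert model.objective_trace[-1] == pytest.approx(
            oracle.objective_trace[-1], abs=1e-6
        )

    def test_four_example_matches_exhaustive_enumeration(self):
        problem = toy_problem(
            np.eye(4) + 0.1,
            [lab("a"), lab("b"), lab("a", "b"), lab("a")],
            [lab("a"), lab("b"), lab("a", "b")],
        )
        ws_model = train_ssvm(problem)
        full = train_exhaustive(problem)
        assert abs(
            ws_model.objective_trace[-1] - full.objective_trace[-1]
        ) <= 1e-6
        assert predict(ws_model, problem.kx.values) == predict(
            full, problem.kx.values
        )

    def test_objective_trace_non_decreasing(self):
        problem = random_toy_problem(11)
        model = train_ssvm(problem)
        trace = model.objective_trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_margin_feasibility_when_separable(self):
        problem = toy_problem(
            np.eye(3),
            [lab("a"), lab("b"), lab("c")],
            [lab("a"), lab("b"), lab("c")],
        )
        model = train_ssvm(problem)
        for i in range(3):
            f = model.score_matrix(problem.kx.values[:, i])[0]
            ti = problem.true_idx[i]
            for s in range(len(problem.space)):
                if s == ti:
                    continue
                assert f[ti] - f[s] >= problem.loss[i, s] - problem.tolerance - 1e-9

    def test_homogeneity_kernel_scale_against_c(self):
        """Scaling K_X by c and C by 1/c leaves predictions unchanged."""
        base = random_toy_problem(21)
        scaled = TrainingProblem(
            KernelMatrix(base.kx.ids, base.kx.values * 4.0, check=False),
            list(base.labels),
            base.space,
            c_over_n=base.c_over_n / 4.0,
        )
        p1 = predict(train_ssvm(base), base.kx.values)
        p2 = predict(train_ssvm(scaled), scaled.kx.values)
        assert p1 == p2

    def test_dual_cap_invariant(self):
        problem = random_toy_problem(31)
        model = train_ssvm(problem)
        sums = {}
        for (i, _), a in zip(model.constraints, model.alpha):
            sums[i] = sums.get(i, 0.0) + a
        assert all(v <= problem.c_over_n + 1e-8 for v in sums.values())

    def test_predicted_labels_are_hierarchically_consistent(self):
        go = make_toy_ontology(12, seed=9)
        views, labels, ids = make_synthetic_dataset(
            SyntheticSpec(
                n_terms=12, n_proteins=20, label_vocabulary_size=4,
                view_noise=(0.2, 0.2), seed=9,
            ),
            go,
        )
        space = build_label_space(labels)
        K = build_view_kernel([views[0]])
        model = train_ssvm(TrainingProblem(K, labels, space))
        for y in predict(model, K.values):
            assert go.is_closed(y.terms)


class TestPredict:
    def test_zero_model_predicts_first_candidate(self):
        problem = toy_problem(
            np.eye(2), [lab("a"), lab("b")], [lab("b"), lab("a")]
        )
        model = _make_model(problem)
        preds = predict(model, problem.kx.values)
        assert preds == [lab("b"), lab("b")]

    def test_duplicate_of_training_protein_gets_its_label(self):
        problem = toy_problem(
            np.eye(3),
            [lab("a"), lab("b"), lab("c")],
            [lab("a"), lab("b"), lab("c")],
        )
        model = train_ssvm(problem)
        # a new protein with the same kernel column as training example 1
        col = problem.kx.values[:, 1]
        assert predict(model, col)[0] == lab("b")


def test_serialization_reconstructs_compatibility(tmp_path):
    from structgo.io import load_model, save_model

    problem = random_toy_problem(77)
    model = train_ssvm(problem)
    path = tmp_path / "model.json"
    save_model(model, path)
    back = load_model(path)
    rng = np.random.default_rng(0)
    for _ in range(10):
        col = rng.standard_normal(problem.n)
        y = problem.space[int(rng.integers(0, len(problem.space)))]
        assert compatibility(back, col, y) == pytest.approx(
            compatibility(model, col, y), abs=1e-12
        )
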