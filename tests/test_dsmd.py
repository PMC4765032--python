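"""Doubly stochastic decomposition: reconstruction, objective, solver,
discretization."""

import numpy as np
import pytest
import scipy.sparse as sp

import cofuse
from cofuse import (
    ComplexSet,
    Membership,
    ProteinIndex,
    discretize,
    filter_min_size,
    fit,
    laplacian_penalty,
    objective,
    reconstruct,
)
from conftest import random_membership, random_symmetric


def dense_objective_oracle(W, theta, lam):
    """Brute-force objective evaluation: dense reconstruction, explicit
    0*log(0) handling, pairwise-form regularizer."""
    W = np.asarray(W.todense() if sp.issparse(W) else W, dtype=float)
    n, K = theta.shape
    s = theta.sum(axis=0)
    What = np.zeros((n, n))
    for k in range(K):
        if s[k] > 1e-12:
            What += np.outer(theta[:, k], theta[:, k]) / s[k]
    J = 0.0
    for i in range(n):
        for j in range(n):
            if W[i, j] > 0:
                if What[i, j] <= 0:
                    return float("inf")
                J -= W[i, j] * np.log(What[i, j])
            J += What[i, j]
    R = 0.0
    for i in range(n):
        for j in range(n):
            R += 0.5 * W[i, j] * np.sum((theta[i] - theta[j]) ** 2)
    return J + lam * R


class TestReconstruct:
    def test_uniform_single_complex(self):
        What = reconstruct(np.ones((5, 1)))
        np.testing.assert_allclose(What, np.full((5, 5), 0.2), atol=1e-14)

    def test_identity_memberships(self):
        What = reconstruct(np.eye(6))
        np.testing.assert_allclose(What, np.eye(6), atol=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_doubly_stochastic(self, seed):
        rng = np.random.default_rng(seed)
        theta = random_membership(int(rng.integers(3, 40)), int(rng.integers(1, 8)), rng)
        What = reconstruct(theta)
        np.testing.assert_allclose(What, What.T, atol=1e-12)
        np.testing.assert_allclose(What.sum(axis=0), 1.0, atol=1e-10)
        np.testing.assert_allclose(What.sum(), theta.shape[0], atol=1e-8)

    def test_rejects_off_simplex(self):
        with pytest.raises(ValueError):
            reconstruct(np.full((3, 2), 0.4))


class TestObjective:
    def test_single_complex_closed_form(self):
        rng = np.random.default_rng(0)
        W = random_symmetric(8, 0.5, rng)
        J = objective(W, np.ones((8, 1)), lambda_=5.0)
        # uniform reconstruction 1/N; identical rows kill the regularizer
        assert J == pytest.approx(np.log(8) * W.sum() + 8, rel=1e-12)

    def test_lambda_zero_is_bare_divergence(self):
        rng = np.random.default_rng(1)
        W = random_symmetric(10, 0.4, rng)
        theta = random_membership(10, 3, rng)
        assert objective(W, theta, 0.0) == pytest.approx(
            dense_objective_oracle(W, theta, 0.0), rel=1e-10
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        W = random_symmetric(n, 0.5, rng)
        theta = random_membership(n, int(rng.integers(1, 6)), rng)
        lam = float(rng.choice([0.0, 1.0, 32.0]))
        assert objective(W, theta, lam) == pytest.approx(
            dense_objective_oracle(W, theta, lam), rel=1e-8
        )


class TestLaplacianPenalty:
    def test_identical_rows_vanish(self):
        rng = np.random.default_rng(2)
        W = random_symmetric(7, 0.5, rng)
        theta = np.tile(random_membership(1, 4, rng), (7, 1))
        assert laplacian_penalty(W, theta) == pytest.approx(0.0, abs=1e-12)

    def test_two_protein_hand_value(self):
        W = sp.csr_matrix(np.array([[0, 1.0], [1.0, 0]]))
        theta = np.eye(2)
        assert laplacian_penalty(W, theta) == pytest.approx(2.0)
        assert laplacian_penalty(W, theta, method="pairwise") == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_trace_and_pairwise_forms_agree(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        W = random_symmetric(n, 0.5, rng)
        theta = rng.uniform(size=(n, int(rng.integers(1, 6))))
        assert laplacian_penalty(W, theta, "trace") == pytest.approx(
            laplacian_penalty(W, theta, "pairwise"), abs=1e-10, rel=1e-10
        )


class TestFit:
    def _planted_blocks(self, n=30, blocks=3):
        size = n // blocks
        W = np.zeros((n, n))
        for b in range(blocks):
            W[b * size:(b + 1) * size, b * size:(b + 1) * size] = 1.0
        np.fill_diagonal(W, 0)
        index = ProteinIndex([f"P{i:02d}" for i in range(n)])
        truth = [
            frozenset(f"P{i:02d}" for i in range(b * size, (b + 1) * size))
            for b in range(blocks)
        ]
        return sp.csr_matrix(W), index, truth

    def test_recovers_planted_blocks(self):
        W, index, truth = self._planted_blocks()
        theta, trace = fit(W, K=5, lambda_=4.0, max_iter=200, seed=0)
        found = filter_min_size(discretize(theta, index), 3)
        assert found.as_sets() == set(truth)

    def test_single_feasible_point_constant_objective(self):
        rng = np.random.default_rng(3)
        W = random_symmetric(10, 0.5, rng)
        _, trace = fit(W, K=1, lambda_=0.0, max_iter=20, seed=1)
        obj = np.array(trace.objective_per_iter)
        np.testing.assert_allclose(obj, obj[0], rtol=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        W = random_symmetric(25, 0.3, rng)
        t1, tr1 = fit(W, K=4, lambda_=1.0, max_iter=50, seed=7)
        t2, tr2 = fit(W, K=4, lambda_=1.0, max_iter=50, seed=7)
        assert tr1.objective_per_iter == tr2.objective_per_iter
        np.testing.assert_array_equal(t1.theta, t2.theta)
        t3, tr3 = fit(W, K=4, lambda_=1.0, max_iter=50, seed=8)
        obj = np.array(tr3.objective_per_iter)
        assert np.all(np.diff(obj) <= np.abs(obj[:-1]) * 1e-9 + 1e-15)

    @pytest.mark.parametrize("lam", [0.0, 1.0, 32.0])
    def test_monotone_and_feasible(self, lam):
        rng = np.random.default_rng(int(lam) + 10)
        W = random_symmetric(40, 0.2, rng)
        theta, trace = fit(W, K=6, lambda_=lam, max_iter=100, seed=2)
        obj = np.array(trace.objective_per_iter)
        assert np.all(np.diff(obj) <= np.abs(obj[:-1]) * 1e-9 + 1e-15)
        assert theta.theta.min() >= 0
        np.testing.assert_allclose(theta.theta.sum(axis=1), 1.0, atol=1e-10)

    def test_solver_objective_matches_reported(self):
        """The trace's final value equals the public objective evaluation."""
        rng = np.random.default_rng(5)
        W = random_symmetric(20, 0.4, rng)
        theta, trace = fit(W, K=3, lambda_=2.0, max_iter=60, seed=3)
        assert trace.objective_per_iter[-1] == pytest.approx(
            objective(W, theta, 2.0), rel=1e-8
        )

    def test_input_validation(self):
        rng = np.random.default_rng(6)
        W = random_symmetric(5, 0.5, rng)
        with pytest.raises(ValueError):
            fit(W, K=0)
        with pytest.raises(ValueError):
            fit(-W, K=2)

    def test_lambda_shrinks_columns_on_clean_blocks(self):
        """Stronger graph regularization never inflates the complex count
        on the clean planted-block fixture (median over 5 seeds)."""
        W, index, _ = self._planted_blocks()
        counts = {lam: [] for lam in (0.0, 32.0)}
        for seed in range(5):
            for lam in counts:
                theta, _ = fit(W, K=10, lambda_=lam, max_iter=200, seed=seed)
                counts[lam].append(len(discretize(theta, index)))
        assert np.median(counts[32.0]) <= np.median(counts[0.0])


class TestDiscretize:
    def _single_row(self, row):
        index = ProteinIndex(["x"])
        return discretize(Membership(np.array([row])), index)

    def test_gap_rule_single_assignment(self):
        cs = self._single_row([0.5, 0.3, 0.15, 0.05])
        assert cs.complexes == [frozenset({"x"})]

    def test_gap_rule_overlap(self):
        cs = self._single_row([0.4, 0.4, 0.2])
        assert cs.complexes == [frozenset({"x"}), frozenset({"x"})]

    def test_uniform_row_tie_break(self):
        cs = self._single_row([0.25] * 4)
        assert cs.complexes == [frozenset({"x"})]

    def test_k_equals_one_assigns_everything(self):
        index = ProteinIndex(["a", "b"])
        cs = discretize(Membership(np.ones((2, 1))), index)
        assert cs.complexes == [frozenset({"a", "b"})]

    def test_empty_columns_dropped(self):
        index = ProteinIndex(["a", "b"])
        theta = np.array([[0.9, 0.1, 0.0], [0.8, 0.2, 0.0]])
        cs = discretize(Membership(theta), index)
        assert len(cs) == 1


class TestFilterMinSize:
    def test_examples(self):
        cs = ComplexSet([frozenset("abc"), frozenset("de")])
        assert filter_min_size(cs, 3).complexes == [frozenset("abc")]
        assert filter_min_size(cs, 1).complexes == cs.complexes
        assert filter_min_size(ComplexSet([frozenset("ab"), frozenset("cd")]), 3).complexes == []
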