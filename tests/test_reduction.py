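"""DBMR factorization: entropy functional, heuristic fit vs exhaustive oracle."""

import numpy as np
import pytest

from latentmap import (
    ContingencyTable,
    compose_transition,
    exhaustive_reduced_model,
    fit_reduced_model,
    model_entropy,
    parameter_count,
)

from conftest import random_table

IDENTITY_HALF = ContingencyTable(C=np.eye(2) / 2, n_pairs=100)
FLAT = ContingencyTable(C=np.full((2, 2), 0.25), n_pairs=100)


def conditional_cross_entropy(C):
    """Independent double-loop oracle: -sum_ij C_ij log(C_ij / colsum_i)."""
    n = C.shape[0]
    colsum = C.sum(axis=0)
    S = 0.0
    for i in range(n):
        for j in range(n):
            if C[j, i] > 0:
                S -= C[j, i] * np.log(C[j, i] / colsum[i])
    return S


class TestModelEntropy:
    def test_perfect_model_has_zero_entropy(self):
        model = fit_reduced_model(IDENTITY_HALF, 2)
        assert model_entropy(IDENTITY_HALF, model) == pytest.approx(0.0, abs=1e-14)

    def test_uniform_model_gives_log2(self):
        model = fit_reduced_model(FLAT, 1)
        assert model_entropy(FLAT, model) == pytest.approx(np.log(2), abs=1e-12)

    def test_full_model_matches_loop_oracle(self, rng):
        table = random_table(rng, 3)
        model = fit_reduced_model(table, 3)
        expected = conditional_cross_entropy(table.C)
        assert model.S == pytest.approx(expected, abs=1e-12)
        assert model_entropy(table, model) == pytest.approx(expected, abs=1e-12)

    def test_unsupported_transition_gives_infinity(self):
        model = fit_reduced_model(IDENTITY_HALF, 2)
        off_diag = ContingencyTable(C=np.array([[0.0, 0.5], [0.5, 0.0]]),
                                    n_pairs=100)
        assert model_entropy(off_diag, model) == np.inf

    def test_dimension_mismatch_rejected(self):
        model = fit_reduced_model(IDENTITY_HALF, 1)
        with pytest.raises(ValueError):
            model_entropy(random_table(np.random.default_rng(0), 3), model)


class TestFit:
    def test_identity_table_exact_two_state_fit(self):
        model = fit_reduced_model(IDENTITY_HALF, 2)
        assert np.allclose(model.gamma, np.eye(2))
        assert np.allclose(model.lamb, np.eye(2))
        assert model.S == pytest.approx(0.0, abs=1e-14)

    def test_single_state_is_marginal(self):
        model = fit_reduced_model(FLAT, 1)
        assert np.allclose(model.lamb[:, 0], [0.5, 0.5])
        assert model.S == pytest.approx(np.log(2), abs=1e-12)

    def test_parameter_count_formula(self):
        for n in range(1, 6):
            for K in range(1, n + 1):
                model = fit_reduced_model(
                    ContingencyTable(C=np.eye(n) / n, n_pairs=100), K)
                assert model.V == (n - 1) * K + n * (K - 1) == parameter_count(n, K)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fit_reduced_model(FLAT, 3)
        with pytest.raises(ValueError):
            fit_reduced_model(FLAT, 0)

    def test_capped_when_initial_states_missing(self):
        # category 2 never occurs as an initial state: only 2 usable columns
        C = np.array([[0.3, 0.0, 0.2],
                      [0.2, 0.0, 0.1],
                      [0.1, 0.0, 0.1]])
        table = ContingencyTable(C=C, n_pairs=100)
        model = fit_reduced_model(table, 3)
        assert model.capped
        assert model.K == 2

    def test_support_of_observed_transitions(self, rng):
        # every observed transition must get positive model probability
        for s in range(5):
            table = random_table(rng, 5, sparsity=0.4)
            for K in range(1, 6):
                model = fit_reduced_model(table, K)
                P = model.lamb @ model.gamma
                assert np.all(P[table.C > 0] > 0)
                assert np.isfinite(model.S)

    @pytest.mark.parametrize("n,K", [(4, 2), (4, 3), (5, 2), (5, 3), (5, 4)])
    def test_heuristic_matches_exhaustive_optimum(self, rng, n, K):
        for _ in range(15):
            table = random_table(rng, n)
            S_fit = fit_reduced_model(table, K).S
            S_opt = exhaustive_reduced_model(table, K).S
            assert S_fit >= S_opt - 1e-12  # never better than the global optimum
            assert S_fit == pytest.approx(S_opt, abs=1e-9)


class TestExhaustive:
    def test_zero_entropy_perfect_partition(self):
        assert exhaustive_reduced_model(IDENTITY_HALF, 2).S == pytest.approx(0.0,
                                                                             abs=1e-14)

    def test_full_k_equals_conditional_cross_entropy(self, rng):
        table = random_table(rng, 4)
        model = exhaustive_reduced_model(table, 4)
        assert model.S == pytest.approx(conditional_cross_entropy(table.C), abs=1e-12)

    def test_single_block_closed_form(self, rng):
        table = random_table(rng, 4)
        model = exhaustive_reduced_model(table, 1)
        marg = table.C.sum(axis=1)
        expected = -np.sum(table.C.sum(axis=1) * np.log(marg))
        assert model.S == pytest.approx(expected, abs=1e-12)

    def test_entropy_nonincreasing_in_k(self, rng):
        for _ in range(10):
            table = random_table(rng, 4)
            S = [exhaustive_reduced_model(table, K).S for K in range(1, 5)]
            assert np.all(np.diff(S) <= 1e-12)

    def test_large_alphabet_guarded(self):
        table = ContingencyTable(C=np.eye(11) / 11, n_pairs=1000)
        with pytest.raises(ValueError):
            exhaustive_reduced_model(table, 2)


class TestPermutationInvariance:
    def test_entropies_invariant_under_relabeling(self, rng):
        for _ in range(5):
            table = random_table(rng, 4)
            perm = rng.permutation(4)
            permuted = ContingencyTable(C=table.C[np.ix_(perm, perm)],
                                        n_pairs=table.n_pairs)
            for K in range(1, 5):
                assert fit_reduced_model(table, K).S == pytest.approx(
                    fit_reduced_model(permuted, K).S, abs=1e-9)


class TestCompose:
    def test_identity_composition(self):
        model = fit_reduced_model(IDENTITY_HALF, 2)
        assert np.allclose(compose_transition(model).Lambda, np.eye(2))

    def test_rank_one_composition(self):
        model = fit_reduced_model(
            ContingencyTable(C=np.array([[0.15, 0.15], [0.35, 0.35]]), n_pairs=100), 1)
        L = compose_transition(model).Lambda
        assert np.allclose(L[:, 0], [0.3, 0.7])
        assert np.allclose(L[:, 0], L[:, 1])

    def test_columns_stochastic_for_random_models(self, rng):
        for _ in range(10):
            table = random_table(rng, 5)
            K = int(rng.integers(1, 6))
            L = compose_transition(fit_reduced_model(table, K)).Lambda
            assert np.allclose(L.sum(axis=0), 1.0, atol=1e-12)
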