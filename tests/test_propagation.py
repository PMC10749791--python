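"""GCN propagation along meta-graphs, checked against a dense transcription.

The oracle below re-states the state update in straight-line dense numpy
-- explicit degree normalization, explicit sum over incoming slots, exact
Gaussian GELU -- independently of the package's sparse/cached code paths.
"""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.special import ndtr

from metadti.hetnet import RelationMatrix, normalize_relation
from metadti.metagraph import IDENTITY, NULL, MetaGraph, all_slots
from metadti.propagation import (
    PropagationWeights,
    aggregate_state,
    backward,
    forward_cached,
    gelu,
    mixture_backward_alpha,
    mixture_forward,
    propagate_relation,
    run_metagraph,
)


def dense_oracle(H0, selections, W, raw_R):
    """Straight-line dense evaluation of the propagation recursion."""
    T = max(t for (_, t) in selections)
    states = [np.asarray(H0, float)]
    for t in range(1, T + 1):
        total = np.zeros_like(states[0])
        for i in range(t):
            mode = selections[(i, t)]
            if mode == NULL:
                continue
            if mode == IDENTITY:
                total = total + states[i]
            else:
                R = raw_R[mode]
                r_tilde = R + np.eye(R.shape[0])
                d_r = np.diag(1.0 / np.sqrt(r_tilde.sum(axis=1)))
                d_c = np.diag(1.0 / np.sqrt(r_tilde.sum(axis=0)))
                total = total + d_r @ r_tilde @ d_c @ states[i] @ W[(i, t)]
        states.append(total * ndtr(total))
    return states


def random_instance(rng):
    n = int(rng.integers(4, 21))
    d = int(rng.integers(2, 9))
    T = int(rng.integers(1, 4))
    names = [f"r{k}" for k in range(int(rng.integers(1, 4)))]
    raw = {m: (rng.random((n, n)) < 0.3).astype(float) for m in names}
    relations = {
        m: normalize_relation(RelationMatrix(m, sp.csr_matrix(R), n))
        for m, R in raw.items()
    }
    selections = {}
    weights = {}
    for i, t in all_slots(T):
        mode = rng.choice(names + [IDENTITY, NULL])
        if (i, t) == (t - 1, t) and mode == NULL:
            mode = names[0]  # chain slots never carry NULL
        selections[(i, t)] = mode
        if mode not in (IDENTITY, NULL):
            weights[(i, t)] = rng.normal(size=(d, d)) * 0.5
    H0 = rng.normal(size=(n, d))
    return H0, selections, PropagationWeights(W=weights), relations, raw


class TestSingleSlot:
    def test_identity_passes_state_through_unchanged(self):
        H = np.random.default_rng(0).normal(size=(4, 3))
        np.testing.assert_array_equal(propagate_relation(H, IDENTITY), H)

    def test_null_contributes_zero(self):
        H = np.ones((4, 3))
        np.testing.assert_array_equal(
            propagate_relation(H, NULL), np.zeros((4, 3))
        )

    def test_identity_and_null_reject_matrices(self):
        H = np.ones((2, 2))
        with pytest.raises(ValueError):
            propagate_relation(H, IDENTITY, W=np.eye(2))

    def test_real_relation_matches_dense_formula(self):
        rng = np.random.default_rng(1)
        R = np.zeros((3, 3))
        R[1, 0] = R[2, 1] = 1.0  # 3-node chain
        rel = normalize_relation(RelationMatrix("c", sp.csr_matrix(R), 3))
        H = np.eye(3)
        out = propagate_relation(H, "c", rel, np.eye(3))
        r_tilde = R + np.eye(3)
        d_r = np.diag(1.0 / np.sqrt(r_tilde.sum(axis=1)))
        d_c = np.diag(1.0 / np.sqrt(r_tilde.sum(axis=0)))
        np.testing.assert_allclose(out, d_r @ r_tilde @ d_c @ H, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        rel = normalize_relation(
            RelationMatrix("x", sp.csr_matrix((3, 3)), 3)
        )
        with pytest.raises(ValueError):
            propagate_relation(np.ones((3, 4)), "x", rel, np.eye(3))


class TestAggregation:
    def test_gelu_of_zero_is_zero(self):
        out = aggregate_state([np.zeros((3, 2))])
        np.testing.assert_array_equal(out, np.zeros((3, 2)))

    def test_gelu_of_ones_is_phi_of_one(self):
        out = aggregate_state([np.ones((2, 2))])
        np.testing.assert_allclose(out, np.full((2, 2), ndtr(1.0)), atol=1e-12)
        assert abs(out[0, 0] - 0.841345) < 1e-6

    def test_sum_is_commutative(self):
        rng = np.random.default_rng(0)
        A, B = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        np.testing.assert_array_equal(
            aggregate_state([A, B]), aggregate_state([B, A])
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_state([])

    def test_exact_gelu_not_tanh_approximation(self):
        x = np.linspace(-3, 3, 101)
        tanh_gelu = 0.5 * x * (
            1 + np.tanh(np.sqrt(2 / np.pi) * (x + 0.044715 * x**3))
        )
        exact = gelu(x)
        np.testing.assert_allclose(exact, x * ndtr(x), atol=1e-15)
        assert np.max(np.abs(exact - tanh_gelu)) > 1e-5  # distinguishable
        assert np.max(np.abs(exact - tanh_gelu)) < 1e-3


class TestRunMetagraph:
    def test_single_identity_slot_is_gelu_of_h0(self):
        H0 = np.random.default_rng(0).normal(size=(5, 3))
        mg = MetaGraph(T=1, role="drug", selected={(0, 1): IDENTITY})
        seq = run_metagraph(H0, mg, PropagationWeights(), {})
        np.testing.assert_allclose(seq.final, gelu(H0), atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        H0, sel, weights, relations, raw = random_instance(rng)
        T = max(t for (_, t) in sel)
        mg = MetaGraph(T=T, role="drug", selected=sel)
        seq = run_metagraph(H0, mg, weights, relations)
        oracle = dense_oracle(H0, sel, weights.W, raw)
        for got, want in zip(seq.states, oracle):
            np.testing.assert_allclose(got, want, atol=1e-8)

    def test_metapath_degeneracy(self):
        """All skip slots NULL reduces the meta-graph to sequential
        single-relation propagation (a meta-path)."""
        rng = np.random.default_rng(5)
        n, d = 8, 4
        raw = {"a": (rng.random((n, n)) < 0.4).astype(float),
               "b": (rng.random((n, n)) < 0.4).astype(float)}
        relations = {
            m: normalize_relation(RelationMatrix(m, sp.csr_matrix(R), n))
            for m, R in raw.items()
        }
        W = {(0, 1): rng.normal(size=(d, d)), (1, 2): rng.normal(size=(d, d))}
        sel = {(0, 1): "a", (1, 2): "b", (0, 2): NULL}
        H0 = rng.normal(size=(n, d))
        seq = run_metagraph(
            H0, MetaGraph(T=2, role="drug", selected=sel),
            PropagationWeights(W=W), relations,
        )
        h1 = gelu(relations["a"].normalized @ H0 @ W[(0, 1)])
        h2 = gelu(relations["b"].normalized @ h1 @ W[(1, 2)])
        np.testing.assert_allclose(seq.final, h2, atol=1e-10)

    def test_missing_weight_is_an_error(self):
        H0 = np.ones((3, 2))
        sel = {(0, 1): "a"}
        rel = {"a": normalize_relation(RelationMatrix("a", sp.csr_matrix((3, 3)), 3))}
        with pytest.raises(ValueError, match="weight"):
            run_metagraph(
                H0, MetaGraph(T=1, role="drug", selected=sel),
                PropagationWeights(), rel,
            )

    def test_finiteness_for_large_inputs(self):
        rng = np.random.default_rng(2)
        H0, sel, weights, relations, _ = random_instance(rng)
        seq = run_metagraph(
            H0 * 1e3,
            MetaGraph(T=max(t for _, t in sel), role="drug", selected=sel),
            weights, relations,
        )
        assert all(np.all(np.isfinite(s)) for s in seq.states)


class TestGradients:
    def loss_of(self, H0, sel, weights, relations):
        seq, cache = forward_cached(H0, sel, weights, relations)
        return 0.5 * float(np.sum(seq.final**2)), cache, seq

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_weight_gradients_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        H0, sel, weights, relations, _ = random_instance(rng)
        if not weights.W:
            pytest.skip("instance has no real-relation slots")
        loss, cache, seq = self.loss_of(H0, sel, weights, relations)
        grad_W, _ = backward(seq.final, cache, weights, relations)
        eps = 1e-6
        for slot, G in grad_W.items():
            idx = (0, 0)
            w0 = weights.W[slot][idx]
            weights.W[slot][idx] = w0 + eps
            lp, _, _ = self.loss_of(H0, sel, weights, relations)
            weights.W[slot][idx] = w0 - eps
            lm, _, _ = self.loss_of(H0, sel, weights, relations)
            weights.W[slot][idx] = w0
            fd = (lp - lm) / (2 * eps)
            assert abs(G[idx] - fd) < 1e-4 * max(1.0, abs(fd))

    def test_mixture_alpha_gradients_match_finite_differences(self, na_catalog):
        from metadti.metagraph import SignificanceTensor

        rng = np.random.default_rng(4)
        n, d, T = 8, 3, 2
        raw = {
            m: (rng.random((n, n)) < 0.4).astype(float)
            for m in na_catalog.real_relations()
        }
        relations = {
            m: normalize_relation(RelationMatrix(m, sp.csr_matrix(R), n))
            for m, R in raw.items()
        }
        sig = SignificanceTensor.initialize(T, "drug", na_catalog, rng)
        weights = PropagationWeights.initialize_full(T, d, rng)
        H0 = rng.normal(size=(n, d))

        def loss():
            states, cache = mixture_forward(H0, sig, weights, relations)
            return 0.5 * float(np.sum(states[-1] ** 2)), states, cache

        base, states, cache = loss()
        grads = mixture_backward_alpha(states[-1], cache, sig, weights, relations)
        eps = 1e-6
        for slot in sig.alpha:
            for k in range(min(3, len(sig.alpha[slot]))):
                a0 = sig.alpha[slot][k]
                sig.alpha[slot][k] = a0 + eps
                lp, _, _ = loss()
                sig.alpha[slot][k] = a0 - eps
                lm, _, _ = loss()
                sig.alpha[slot][k] = a0
                fd = (lp - lm) / (2 * eps)
                assert abs(grads[slot][k] - fd) < 1e-4 * max(1.0, abs(fd))
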