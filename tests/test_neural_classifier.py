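import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from enhkit import (
    LabeledDataset,
    attention_pool,
    bilstm_encode,
    lstm_step,
)
from enhkit.kmer_embedding import EmbeddingConfig
from enhkit.neural_classifier import (
    AttentionBiLstm,
    ClassifierConfig,
    EnhancerClassifier,
    LstmParams,
    LstmState,
    NeuralConfig,
    zero_state,
)
from enhkit.sequence_io import ConfigError


def scalar_lstm_step_oracle(x, prev_h, prev_c, params):
    """Naive per-element reference: every gate computed scalar by scalar."""
    hdim = params.hidden
    concat = list(prev_h) + list(x)

    def gate(offset, squash):
        out = []
        for j in range(hdim):
            z = params.b[offset + j]
            for i, v in enumerate(concat):
                z += v * params.w[i, offset + j]
            out.append(squash(z))
        return out

    sig = lambda z: 1.0 / (1.0 + math.exp(-z))
    f = gate(0, sig)
    i = gate(hdim, sig)
    g = gate(2 * hdim, math.tanh)
    o = gate(3 * hdim, sig)
    c = [fj * cj + ij * gj for fj, cj, ij, gj in zip(f, prev_c, i, g)]
    h = [oj * math.tanh(cj) for oj, cj in zip(o, c)]
    return np.array(c), np.array(h)


def random_params(d, hdim, seed):
    return LstmParams.initialize(d, hdim, np.random.default_rng(seed))


class TestLstmStep:
    def test_zero_weights_halve_cell_state(self):
        # sigma(0) = 0.5 and tanh(0) = 0: C_t = 0.5*C_{t-1}, h_t = 0.5*tanh(0.5*C)
        hdim = 4
        params = LstmParams(np.zeros((hdim + 3, 4 * hdim)), np.zeros(4 * hdim), hdim)
        c_prev = np.array([1.0, -2.0, 0.5, 0.0])
        state = lstm_step(np.ones(3), LstmState(c_prev, np.zeros(hdim)), params)
        np.testing.assert_allclose(state.c, 0.5 * c_prev)
        np.testing.assert_allclose(state.h, 0.5 * np.tanh(0.5 * c_prev))

    @settings(max_examples=40, deadline=None)
    @given(
        x=hnp.arrays(float, 3, elements=st.floats(-50, 50)),
        h=hnp.arrays(float, 5, elements=st.floats(-0.99, 0.99)),
        c=hnp.arrays(float, 5, elements=st.floats(-20, 20)),
        seed=st.integers(0, 50),
    )
    def test_gate_ranges_hold_for_any_input(self, x, h, c, seed):
        params = random_params(3, 5, seed)
        state = lstm_step(x, LstmState(c, h), params)
        assert np.all(np.abs(state.h) < 1)  # h = o*tanh(C), o in (0,1)
        assert np.all(np.isfinite(state.c))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scalar_reference(self, seed):
        rng = np.random.default_rng(200 + seed)
        d, hdim = 4, 6
        params = random_params(d, hdim, seed)
        x = rng.normal(size=d)
        h_prev = rng.normal(size=hdim) * 0.5
        c_prev = rng.normal(size=hdim)
        state = lstm_step(x, LstmState(c_prev, h_prev), params)
        c_ref, h_ref = scalar_lstm_step_oracle(x, h_prev, c_prev, params)
        np.testing.assert_allclose(state.c, c_ref, atol=1e-10)
        np.testing.assert_allclose(state.h, h_ref, atol=1e-10)

    def test_shape_mismatch_reported(self):
        params = random_params(3, 5, 0)
        with pytest.raises(ConfigError, match="input size"):
            lstm_step(np.ones(4), zero_state(5), params)
        with pytest.raises(ConfigError, match="state"):
            lstm_step(np.ones(3), zero_state(4), params)

    def test_named_gate_slices(self):
        params = random_params(3, 5, 1)
        w, b = params.gate("output")
        np.testing.assert_array_equal(w, params.w[:, 15:20])
        np.testing.assert_array_equal(b, params.b[15:20])
        with pytest.raises(ConfigError, match="unknown gate"):
            params.gate("peephole")


class TestBilstmEncode:
    def test_single_step_is_sum_of_directions(self):
        fwd, bwd = random_params(3, 4, 0), random_params(3, 4, 1)
        x = np.array([[0.3, -0.2, 1.0]])
        out = bilstm_encode(x, fwd, bwd)
        expected = (
            lstm_step(x[0], zero_state(4), fwd).h
            + lstm_step(x[0], zero_state(4), bwd).h
        )
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_palindromic_input_with_tied_params_is_reversal_symmetric(self):
        params = random_params(3, 4, 2)
        rng = np.random.default_rng(3)
        half = rng.normal(size=(5, 3))
        x = np.vstack([half, half[::-1]])  # palindromic in time
        out = bilstm_encode(x, params, params)
        np.testing.assert_allclose(out, out[::-1], atol=1e-12)

    def test_matches_manual_step_composition(self):
        fwd, bwd = random_params(2, 3, 4), random_params(2, 3, 5)
        rng = np.random.default_rng(6)
        x = rng.normal(size=(7, 2))
        out = bilstm_encode(x, fwd, bwd)
        state = zero_state(3)
        h_f = []
        for t in range(7):
            state = lstm_step(x[t], state, fwd)
            h_f.append(state.h)
        state = zero_state(3)
        h_b = [None] * 7
        for t in range(6, -1, -1):
            state = lstm_step(x[t], state, bwd)
            h_b[t] = state.h
        expected = np.array(h_f) + np.array(h_b)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_output_width_independent_of_length(self):
        fwd, bwd = random_params(3, 6, 7), random_params(3, 6, 8)
        for t_len in (1, 4, 20):
            out = bilstm_encode(np.zeros((t_len, 3)), fwd, bwd)
            assert out.shape == (t_len, 6)

    def test_empty_input_rejected(self):
        fwd, bwd = random_params(3, 4, 0), random_params(3, 4, 1)
        with pytest.raises(ConfigError):
            bilstm_encode(np.zeros((0, 3)), fwd, bwd)


class TestAttentionPool:
    def test_identical_states_give_uniform_weights_and_identity_context(self):
        v = np.array([0.5, -1.0, 2.0])
        ctx = attention_pool(np.tile(v, (6, 1)))
        np.testing.assert_allclose(ctx.weights, np.full(6, 1 / 6))
        np.testing.assert_allclose(ctx.context, v)

    @settings(max_examples=30, deadline=None)
    @given(h=hnp.arrays(float, (7, 4), elements=st.floats(-5, 5)))
    def test_weights_normalized_and_context_in_convex_hull(self, h):
        ctx = attention_pool(h)
        assert ctx.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(ctx.weights >= 0)
        lo, hi = h.min(axis=0), h.max(axis=0)
        assert np.all(ctx.context >= lo - 1e-12) and np.all(ctx.context <= hi + 1e-12)

    def test_weight_order_follows_similarity_to_query(self):
        q_dir = np.array([1.0, 0.0])
        h = np.vstack([3.0 * q_dir, 1.0 * q_dir])  # both along the mean query
        ctx = attention_pool(h)
        assert ctx.weights[0] > ctx.weights[1]


class TestTraining:
    def _toy_problem(self, n=40, t_len=6, d=3, seed=0):
        # positive examples have a planted direction in their first rows
        rng = np.random.default_rng(seed)
        x = rng.normal(scale=0.3, size=(n, t_len, d))
        y = np.array([1.0, 0.0] * (n // 2))
        x[y == 1, :2, 0] += 2.0
        return x, y

    def test_gradients_match_finite_differences(self):
        net = AttentionBiLstm(NeuralConfig(hidden=4, seed=0))
        rng = np.random.default_rng(1)
        net.fwd = random_params(3, 4, 2)
        net.bwd = random_params(3, 4, 3)
        net.w_out = rng.normal(size=4) * 0.2
        net.b_out = 0.1
        x = rng.normal(size=(3, 5, 3))
        y = np.array([1.0, 0.0, 1.0])
        _, grads = net._loss_and_grads(x, y)
        params = [net.fwd.w, net.fwd.b, net.bwd.w, net.bwd.b, net.w_out]
        eps = 1e-6
        rng_idx = np.random.default_rng(4)
        for p, g in zip(params, grads):
            flat = p.reshape(-1)
            for idx in rng_idx.choice(flat.size, size=min(6, flat.size), replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                lp, _ = net._loss_and_grads(x, y)
                flat[idx] = old - eps
                lm, _ = net._loss_and_grads(x, y)
                flat[idx] = old
                assert g.reshape(-1)[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-7)

    def test_loss_decreases_on_separable_toy_task(self):
        x, y = self._toy_problem(seed=5)
        net = AttentionBiLstm(
            NeuralConfig(hidden=8, epochs=15, batch_size=8, seed=0, patience=20)
        ).fit(x, y)
        assert net.loss_history[-1] < net.loss_history[0]
        scores = net.decision_scores(x)
        assert np.isfinite(scores).all()
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_single_class_training_rejected(self):
        x, y = self._toy_problem()
        with pytest.raises(ConfigError, match="both classes"):
            AttentionBiLstm(NeuralConfig(hidden=4)).fit(x, np.ones_like(y))

    def test_classifier_pipeline_contract(self, benchmark_shaped_dataset):
        # tiny end-to-end fit: finite scores, labels in the label set
        strong = [i for i, lab in enumerate(benchmark_shaped_dataset.labels)
                  if lab == "strong_enhancer"][:20]
        weak = [i for i, lab in enumerate(benchmark_shaped_dataset.labels)
                if lab == "weak_enhancer"][:20]
        subset = benchmark_shaped_dataset.subset(strong + weak)
        cfg = ClassifierConfig(
            embedding=EmbeddingConfig(dimension=8, epochs=2, min_count=1, seed=0),
            neural=NeuralConfig(hidden=8, epochs=3, seed=0),
        )
        clf = EnhancerClassifier(cfg).fit(subset)
        labels = clf.predict(subset.sequences[:10])
        scores = clf.predict_scores(subset.sequences[:10])
        assert set(labels) <= {"strong_enhancer", "weak_enhancer"}
        assert np.isfinite(scores).all()

    def test_classifier_requires_both_classes(self, benchmark_shaped_dataset):
        keep = [i for i, lab in enumerate(benchmark_shaped_dataset.labels)
                if lab == "strong_enhancer"][:20]
        with pytest.raises(ConfigError, match="strong and weak"):
            EnhancerClassifier().fit(benchmark_shaped_dataset.subset(keep))
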