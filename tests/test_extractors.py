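"""Closed-form and structural checks of the two feature-extraction branches."""

import numpy as np
import pytest

from mifnn.autodiff import Tensor
from mifnn.extractors import (
    AttentionParams,
    DimensionMismatch,
    EmptySequence,
    ExtractorConfig,
    LSTMParams,
    ShapeMismatch,
    attention_pool,
    attention_weights,
    avg_pool_2d,
    bilstm,
    conv2d_same,
    init_attention_params,
    init_lstm_params,
    init_mdifen_params,
    init_mffen_params,
    lstm_step,
    mdifen_forward,
    mdifen_forward_batch,
    mean_pool_1d,
    mffen_forward,
    mffen_forward_batch,
)


def _zero_lstm(input_dim, hidden):
    z = lambda shape: Tensor(np.zeros(shape), requires_grad=True)
    return LSTMParams(
        *(x for _ in range(4) for x in (z((hidden, hidden)), z((hidden, input_dim)), z(hidden))),
        hidden_dim=hidden,
    )


class TestLSTMStep:
    def test_zero_parameters_zero_state(self, float64):
        p = _zero_lstm(3, 2)
        m, c = lstm_step(np.ones(3), (np.zeros(2), np.zeros(2)), p)
        # i=o=f=sigmoid(0)=1/2, candidate=tanh(0)=0 => m=0, c=0.5*tanh(0)=0
        np.testing.assert_array_equal(m.data, 0.0)
        np.testing.assert_array_equal(c.data, 0.0)

    def test_saturated_forget_gate_preserves_memory(self, float64):
        p = _zero_lstm(3, 2)
        p.b_f.data[...] = 20.0   # forget gate ~ 1
        p.b_i.data[...] = -20.0  # input gate ~ 0
        m_prev = np.array([0.7, -1.2])
        m, _ = lstm_step(np.ones(3), (m_prev, np.zeros(2)), p)
        assert np.abs(m.data - m_prev).max() < 1e-8

    def test_hand_computed_two_dim_step(self, float64):
        rng = np.random.default_rng(11)
        p = init_lstm_params(rng, input_dim=2, hidden_dim=2)
        x = np.array([0.3, -0.8])
        m_prev = np.array([0.1, 0.2])
        c_prev = np.array([-0.4, 0.5])
        m, c = lstm_step(x, (m_prev, c_prev), p)
        sig = lambda v: 1 / (1 + np.exp(-v))
        gate = lambda W, U, b: W.data @ c_prev + U.data @ x + b.data
        i = sig(gate(p.W_i, p.U_i, p.b_i))
        mt = np.tanh(gate(p.W_m, p.U_m, p.b_m))
        o = sig(gate(p.W_o, p.U_o, p.b_o))
        f = sig(gate(p.W_f, p.U_f, p.b_f))
        m_want = f * m_prev + i * mt
        np.testing.assert_allclose(m.data, m_want, rtol=1e-12)
        np.testing.assert_allclose(c.data, o * np.tanh(m_want), rtol=1e-12)

    def test_dimension_mismatch(self, float64):
        p = _zero_lstm(3, 2)
        with pytest.raises(DimensionMismatch):
            lstm_step(np.ones(5), (np.zeros(2), np.zeros(2)), p)


class TestBiLSTM:
    def test_output_dimension_is_twice_hidden(self, float64, rng):
        fwd = init_lstm_params(rng, 3, 4)
        bwd = init_lstm_params(rng, 3, 4)
        out = bilstm(rng.normal(size=(5, 3)), fwd, bwd)
        assert out.shape == (5, 8)

    def test_length_one_sequence_same_input_both_directions(self, float64, rng):
        fwd = init_lstm_params(rng, 3, 4)
        out = bilstm(rng.normal(size=(1, 3)), fwd, fwd)
        np.testing.assert_allclose(out.data[0, :4], out.data[0, 4:], rtol=1e-12)

    def test_reversal_symmetry(self, float64, rng):
        fwd = init_lstm_params(rng, 3, 4)
        bwd = init_lstm_params(rng, 3, 4)
        seq = rng.normal(size=(6, 3))
        base = bilstm(seq, fwd, bwd).data
        flipped = bilstm(seq[::-1], bwd, fwd).data
        # reversing time and swapping direction parameters swaps the halves
        np.testing.assert_allclose(flipped[::-1, 4:], base[:, :4], rtol=1e-10)
        np.testing.assert_allclose(flipped[::-1, :4], base[:, 4:], rtol=1e-10)

    def test_empty_sequence_rejected(self, float64, rng):
        fwd = init_lstm_params(rng, 3, 4)
        with pytest.raises(EmptySequence):
            bilstm(np.zeros((0, 3)), fwd, fwd)


class TestAttention:
    def test_weights_are_probability_distribution(self, float64, rng):
        p = init_attention_params(rng, state_dim=5, attention_dim=3)
        alpha = attention_weights(rng.normal(size=(4, 7, 5)), p).data
        assert np.all(alpha >= 0)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-12)

    def test_identical_states_give_uniform_weights(self, float64, rng):
        p = init_attention_params(rng, state_dim=5, attention_dim=3)
        state = rng.normal(size=5)
        states = np.tile(state, (6, 1))
        alpha = attention_weights(states, p).data
        np.testing.assert_allclose(alpha, 1 / 6, atol=1e-12)
        pooled = attention_pool(states, p).data
        np.testing.assert_allclose(pooled, state, atol=1e-12)

    def test_hand_computed_softmax_quarters(self, float64):
        # scores (0, ln 3) => weights (1/4, 3/4); engineered with a 1-d state
        p = AttentionParams(
            W_w=Tensor(np.array([[1.0]])),
            b_w=Tensor(np.array([0.0])),
            eta_w=Tensor(np.array([2.0])),
        )
        c2 = np.arctanh(np.log(3.0) / 2.0)
        states = np.array([[0.0], [c2]])
        alpha = attention_weights(states, p).data
        np.testing.assert_allclose(alpha, [0.25, 0.75], rtol=1e-12)
        pooled = attention_pool(states, p).data
        np.testing.assert_allclose(pooled, 0.75 * c2, rtol=1e-12)


class TestMDIFEN:
    def test_output_length_is_twice_lstm_hidden(self, float64, rng):
        cfg = ExtractorConfig(embed_dim=2, conv1d_channels=3, lstm_hidden=5, attention_dim=4)
        p = init_mdifen_params(rng, cfg)
        feat = mdifen_forward(rng.normal(size=300), p)
        assert feat.values.shape == (10,) and feat.branch == "mdifen"

    def test_eval_mode_deterministic(self, float64, rng):
        p = init_mdifen_params(rng, ExtractorConfig(lstm_hidden=4, embed_dim=2,
                                                    conv1d_channels=3, attention_dim=4))
        x = rng.normal(size=300)
        a = mdifen_forward(x, p, mode="eval").values
        b = mdifen_forward(x, p, mode="eval").values
        np.testing.assert_array_equal(a, b)

    def test_zero_input_zero_biases_gives_zero_feature(self, float64, rng):
        p = init_mdifen_params(rng, ExtractorConfig(lstm_hidden=4, embed_dim=2,
                                                    conv1d_channels=3, attention_dim=4))
        p.embed_b.data[...] = 0.0
        feat = mdifen_forward(np.zeros(300), p)
        np.testing.assert_allclose(feat.values, 0.0, atol=1e-12)

    def test_gradients_flow_through_whole_branch(self, float64, rng):
        # finite-difference check of d loss / d (a few parameters) through
        # embedding, convolution, pooling, bi-LSTM and attention
        cfg = ExtractorConfig(embed_dim=2, conv1d_channels=2, conv1d_kernel=3,
                              lstm_hidden=3, attention_dim=2)
        p = init_mdifen_params(rng, cfg)
        x = Tensor(rng.normal(size=(2, 8)))

        def loss_value():
            return float(mdifen_forward_batch(x, p, "eval").tanh().sum().data)

        out = mdifen_forward_batch(x, p, "eval").tanh().sum()
        out.backward()
        eps = 1e-6
        checked = 0
        for t in [p.embed_w, p.conv_W, p.lstm_fwd.W_f, p.lstm_bwd.U_i, p.attention.eta_w]:
            flat = t.data.reshape(-1)
            gflat = t.grad.reshape(-1)
            for i in np.linspace(0, flat.size - 1, 3).astype(int):
                orig = flat[i]
                flat[i] = orig + eps
                hi = loss_value()
                flat[i] = orig - eps
                lo = loss_value()
                flat[i] = orig
                num = (hi - lo) / (2 * eps)
                assert num == pytest.approx(gflat[i], rel=1e-4, abs=1e-8)
                checked += 1
        assert checked == 15


class TestMFFEN:
    def test_spatial_sizes_follow_same_pad_pool_arithmetic(self, float64, rng):
        cfg = ExtractorConfig(mffen_channels=(3, 5), branch_dim=7)
        p = init_mffen_params(rng, cfg)
        x = Tensor(rng.normal(size=(2, 32, 64, 1)))
        h1 = conv2d_same(x, p.conv1_W, p.conv1_b)
        assert h1.shape == (2, 32, 64, 3)  # SAME conv preserves spatial size
        h1p = avg_pool_2d(h1)
        assert h1p.shape == (2, 16, 32, 3)
        h2p = avg_pool_2d(conv2d_same(h1p, p.conv2_W, p.conv2_b))
        assert h2p.shape == (2, 8, 16, 5)
        feat = mffen_forward(rng.normal(size=(32, 64)), p)
        assert feat.values.shape == (7,) and feat.branch == "mffen"

    def test_zero_matrix_zero_biases_gives_zero_feature(self, float64, rng):
        p = init_mffen_params(rng, ExtractorConfig(mffen_channels=(2, 3), branch_dim=4))
        feat = mffen_forward(np.zeros((32, 64)), p)
        np.testing.assert_allclose(feat.values, 0.0, atol=1e-12)

    def test_flatten_is_row_major(self, float64):
        x = Tensor(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_array_equal(x.reshape(1, -1).data, [[1.0, 2.0, 3.0, 4.0]])

    def test_wrong_shape_rejected(self, float64, rng):
        p = init_mffen_params(rng)
        with pytest.raises(ShapeMismatch):
            mffen_forward(np.zeros((16, 64)), p)

    def test_eval_mode_deterministic(self, float64, rng):
        p = init_mffen_params(rng, ExtractorConfig(mffen_channels=(2, 3), branch_dim=4))
        x = (rng.random((32, 64)) < 0.2).astype(float)
        np.testing.assert_array_equal(
            mffen_forward(x, p).values, mffen_forward(x, p).values
        )


class TestPooling:
    def test_mean_pool_1d_halves_length(self, float64, rng):
        x = Tensor(rng.normal(size=(2, 10, 3)))
        out = mean_pool_1d(x, 2)
        assert out.shape == (2, 5, 3)
        np.testing.assert_allclose(out.data[:, 0], x.data[:, 0:2].mean(axis=1), rtol=1e-12)

    def test_train_dropout_requires_rng(self, float64, rng):
        p = init_mdifen_params(rng, ExtractorConfig(lstm_hidden=3, embed_dim=2,
                                                    conv1d_channels=2, attention_dim=2))
        with pytest.raises(ValueError):
            mdifen_forward_batch(Tensor(np.zeros((1, 8))), p, "train", None)
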