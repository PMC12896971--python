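"""Quartet classifier: cell-level scalar oracles, sequence plumbing,
attention properties, forward contracts."""

import numpy as np
import pytest

from quadrasense.quartet import (
    AttentionParams,
    GRUParams,
    LSTMParams,
    Quartet,
    QuartetConfig,
    gru_cell,
    lstm_cell,
    quartet_forward,
    self_attention,
    train_quartet,
    vector_to_sequence,
)


class TestVectorToSequence:
    def test_exact_split(self):
        seq = vector_to_sequence(np.arange(8.0), 4)
        assert seq.shape == (4, 2)
        np.testing.assert_array_equal(seq[0], [0, 1])

    def test_padding_rule(self):
        seq = vector_to_sequence(np.arange(7.0), 4)
        assert seq.shape == (4, 2)
        assert seq[3, 1] == 0.0  # last frame ends in one zero

    def test_single_frame(self):
        v = np.arange(5.0)
        np.testing.assert_array_equal(vector_to_sequence(v, 1)[0], v)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            vector_to_sequence(np.arange(3.0), 4)


def _zero_gru(h, d):
    return GRUParams(Wq=np.zeros((h, h + d)), Wu=np.zeros((h, h + d)),
                     Wv=np.zeros((h, h + d)), bq=np.zeros(h), bu=np.zeros(h),
                     bv=np.zeros(h))


class TestGRUCell:
    def test_zero_weights_v_prev_one(self):
        out = gru_cell(np.array([0.0]), np.array([1.0]), _zero_gru(1, 1))
        assert out[0] == pytest.approx(0.5)  # q = u = 0.5, v_hat = 0

    def test_zero_state_stays_zero(self):
        out = gru_cell(np.array([0.0]), np.array([0.0]), _zero_gru(1, 1))
        assert out[0] == 0.0

    def test_scalar_hand_oracle(self):
        """1-unit GRU with weights (0.5, -0.25, 1.0), input x=1, v=-1,
        evaluated by hand."""
        w = lambda v: np.full((1, 2), v)
        p = GRUParams(Wq=w(0.5), Wu=w(-0.25), Wv=w(1.0),
                      bq=np.zeros(1), bu=np.zeros(1), bv=np.zeros(1))
        x, v = np.array([1.0]), np.array([-1.0])
        sig = lambda z: 1 / (1 + np.exp(-z))
        q = sig(0.5 * (v[0] + x[0]))
        u = sig(-0.25 * (v[0] + x[0]))
        vhat = np.tanh(1.0 * (u * v[0] + x[0]))
        expected = (1 - q) * v[0] + q * vhat
        assert gru_cell(x, v, p)[0] == pytest.approx(expected, abs=1e-12)

    def test_convex_combination_property(self, rng):
        """v_t lies elementwise between v_prev and the candidate state."""
        h, d = 4, 3
        p = GRUParams(*[rng.normal(size=(h, h + d)) for _ in range(3)],
                      *[rng.normal(size=h) for _ in range(3)])
        x, v = rng.normal(size=d), rng.normal(size=h)
        vx = np.concatenate([v, x])
        sig = lambda z: 1 / (1 + np.exp(-z))
        u = sig(p.Wu @ vx + p.bu)
        vhat = np.tanh(p.Wv @ np.concatenate([u * v, x]) + p.bv)
        out = gru_cell(x, v, p)
        lo, hi = np.minimum(v, vhat), np.maximum(v, vhat)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)


class TestLSTMCell:
    def test_zero_weights_zero_cell(self):
        p = LSTMParams(Wi=np.zeros((1, 2)), Wf=np.zeros((1, 2)),
                       Wo=np.zeros((1, 3)), Wc=np.zeros((1, 2)))
        h, c = lstm_cell(np.array([0.0]), np.array([0.0]), np.array([0.0]), p)
        assert h[0] == 0.0 and c[0] == 0.0

    def test_zero_weights_carried_cell(self):
        p = LSTMParams(Wi=np.zeros((1, 2)), Wf=np.zeros((1, 2)),
                       Wo=np.zeros((1, 3)), Wc=np.zeros((1, 2)))
        h, c = lstm_cell(np.array([0.0]), np.array([0.0]), np.array([2.0]), p)
        assert c[0] == pytest.approx(1.0)             # f = 0.5
        assert h[0] == pytest.approx(0.5 * np.tanh(1.0), abs=1e-12)

    def test_memory_carry_with_forced_gates(self):
        """f -> 1 and i -> 0 (via large +/- weights on a constant input)
        carries the cell state through unchanged."""
        big = 50.0
        p = LSTMParams(Wi=np.full((1, 2), -big), Wf=np.full((1, 2), big),
                       Wo=np.zeros((1, 3)), Wc=np.zeros((1, 2)))
        c_prev = np.array([0.73])
        _, c = lstm_cell(np.array([1.0]), np.array([1.0]), c_prev, p)
        assert c[0] == pytest.approx(0.73, abs=1e-9)


class TestSelfAttention:
    def test_identical_frames_uniform_weights(self):
        y = np.tile(np.array([1.0, 2.0]), (5, 1))
        p = AttentionParams(WQ1=np.eye(2), WK1=np.eye(2), WV1=np.eye(2))
        _, w = self_attention(y, p)
        np.testing.assert_allclose(w, 0.2, atol=1e-12)

    def test_single_frame(self):
        y = np.array([[3.0]])
        p = AttentionParams(WQ1=np.array([[2.0]]), WK1=np.array([[1.0]]),
                            WV1=np.array([[0.5]]))
        out, w = self_attention(y, p)
        assert w[0, 0] == 1.0
        assert out[0, 0] == pytest.approx(1.5)

    def test_two_frame_scalar_oracle(self):
        p = AttentionParams(WQ1=np.array([[1.0]]), WK1=np.array([[1.0]]),
                            WV1=np.array([[1.0]]))
        y = np.array([[1.0], [2.0]])
        out, w = self_attention(y, p)
        scores = np.array([[1.0, 2.0], [2.0, 4.0]])
        expw = np.exp(scores) / np.exp(scores).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(w, expw, atol=1e-12)
        np.testing.assert_allclose(out, expw @ y, atol=1e-12)

    def test_rows_sum_to_one_and_permutation_equivariance(self, rng):
        y = rng.normal(size=(6, 3))
        p = AttentionParams(WQ1=rng.normal(size=(3, 3)),
                            WK1=rng.normal(size=(3, 3)),
                            WV1=rng.normal(size=(3, 3)))
        out, w = self_attention(y, p)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)
        perm = rng.permutation(6)
        out_p, _ = self_attention(y[perm], p)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-9)


class TestQuartetForward:
    def test_probabilities_sum_to_one(self, rng):
        cfg = QuartetConfig(use_patch=False, seq_len=4, seed=0)
        model = Quartet(cfg, feature_dim=20)
        probs = quartet_forward(model, rng.normal(size=(5, 20)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_head_gives_uniform(self, rng):
        cfg = QuartetConfig(use_patch=False, seq_len=4, seed=0)
        model = Quartet(cfg, feature_dim=16)
        model.params["fc2_w"].data[:] = 0
        model.params["fc2_b"].data[:] = 0
        probs = quartet_forward(model, rng.normal(size=(3, 16)))
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)

    def test_inference_deterministic(self, rng):
        cfg = QuartetConfig(use_patch=False, seq_len=4, seed=1)
        model = Quartet(cfg, feature_dim=12)
        x = rng.normal(size=(2, 12))
        np.testing.assert_array_equal(quartet_forward(model, x),
                                      quartet_forward(model, x))

    def test_palindromic_bilstm_symmetry(self):
        """With shared direction weights, a palindromic sequence gives
        equal forward and backward final states."""
        cfg = QuartetConfig(use_patch=False, seq_len=4, lstm_hidden=3, seed=2)
        model = Quartet(cfg, feature_dim=8)
        for k in ("Wi", "Wf", "Wo", "Wc"):
            model.params[f"lstm_bwd_{k}"].data = \
                model.params[f"lstm_fwd_{k}"].data.copy()
        import quadrasense.nn as nn
        frames_arr = np.array([[1.0, 2.0], [3.0, 4.0], [3.0, 4.0], [1.0, 2.0]])
        frames = [nn.constant(np.tile(f, (1, 1))) for f in frames_arr]
        out = model._bilstm_branch(frames).data[0]
        h = cfg.lstm_hidden
        np.testing.assert_allclose(out[:h], out[h:], atol=1e-12)


class TestTrainQuartet:
    def test_zero_epochs_returns_initial(self, rng):
        X = rng.normal(size=(10, 12))
        y = np.array([0, 1] * 5)
        cfg = QuartetConfig(use_patch=False, epochs=0, seed=0)
        model, hist = train_quartet(X, y, cfg)
        assert hist["loss"] == []

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(8, 12))
        with pytest.raises(ValueError):
            train_quartet(X, np.zeros(8, dtype=int),
                          QuartetConfig(use_patch=False, epochs=1))

    def test_patience_zero_stops_quickly(self, rng):
        X = rng.normal(size=(16, 12))
        y = np.array([0, 1] * 8)
        cfg = QuartetConfig(use_patch=False, epochs=50, lr=0.0,
                            early_stopping_patience=0, seed=0)
        _, hist = train_quartet(X, y, cfg)
        assert len(hist["loss"]) <= 2  # lr=0: no improvement after epoch 1
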