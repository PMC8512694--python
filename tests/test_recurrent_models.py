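import math

import numpy as np
import pytest

from ecghorizon.recurrent_models import (
    GruParams,
    HorizonClassifier,
    LstmParams,
    PowerSigmoidParams,
    RnnParams,
    TrainConfig,
    gru_step,
    lstm_step,
    make_sequences,
    power_sigmoid,
    rnn_step,
    train,
)

# --------------------------------------------------------------------------
# Independent scalar oracles: plain-python loops over the defining equations
# --------------------------------------------------------------------------


def psig_scalar(x, alpha, beta):
    if abs(x) >= 1:
        return x ** alpha
    return ((1 + math.exp(-beta)) * (1 - math.exp(-beta * x))) / (
        (1 - math.exp(-beta)) * (1 + math.exp(-beta * x)))


def sig_scalar(x):
    return 1.0 / (1.0 + math.exp(-x))


def matvec(W, v):
    return [sum(W[i][j] * v[j] for j in range(len(v))) for i in range(len(W))]


def rnn_oracle(x, h_prev, p):
    a = [ai + bi + ci for ai, bi, ci in zip(
        matvec(p.W_ih, x), matvec(p.W_h, h_prev), p.b_h)]
    h = [psig_scalar(v, p.act_h.alpha, p.act_h.beta) for v in a]
    pre = [min(1.0, max(-1.0, v + b)) for v, b in zip(matvec(p.W_ho, h), p.b_o)]
    y = [psig_scalar(v, p.act_o.alpha, p.act_o.beta) for v in pre]
    return h, y


def gru_oracle(x, h_prev, p):
    z = list(h_prev) + list(x)
    u = [sig_scalar(v) for v in matvec(p.W_u, z)]
    r = [sig_scalar(v) for v in matvec(p.W_r, z)]
    zc = [ri * hi for ri, hi in zip(r, h_prev)] + list(x)
    hhat = [math.tanh(v) for v in matvec(p.W_hhat, zc)]
    return [(1 - ui) * hi + ui * ci for ui, hi, ci in zip(u, h_prev, hhat)]


def lstm_oracle(x, h_prev, C_prev, p):
    i = [sig_scalar(a + b) for a, b in zip(matvec(p.w_ix, x), matvec(p.w_ih, h_prev))]
    f = [sig_scalar(a + b) for a, b in zip(matvec(p.w_fx, x), matvec(p.w_fh, h_prev))]
    o = [sig_scalar(a + b) for a, b in zip(matvec(p.w_ox, x), matvec(p.w_oh, h_prev))]
    g = [math.tanh(a + b) for a, b in zip(matvec(p.w_cx, x), matvec(p.w_ch, h_prev))]
    C = [fi * ci + ii * gi for fi, ci, ii, gi in zip(f, C_prev, i, g)]
    h = [oi * math.tanh(ci) for oi, ci in zip(o, C)]
    return h, C


# --------------------------------------------------------------------------
# Power-sigmoid
# --------------------------------------------------------------------------


class TestPowerSigmoid:
    @pytest.mark.parametrize("alpha,beta", [(3, 3.0), (5, 4.0), (7, 2.5)])
    def test_boundary_continuity_and_unit_values(self, alpha, beta):
        p = PowerSigmoidParams(alpha, beta)
        assert power_sigmoid(1.0, p) == pytest.approx(1.0)
        assert power_sigmoid(-1.0, p) == pytest.approx(-1.0)
        eps = 1e-8
        assert power_sigmoid(1 - eps, p) == pytest.approx(1.0, abs=1e-5)
        assert power_sigmoid(-1 + eps, p) == pytest.approx(-1.0, abs=1e-5)

    def test_polynomial_branch(self):
        assert power_sigmoid(2.0, PowerSigmoidParams(3, 3.0)) == pytest.approx(8.0)

    def test_inner_branch_matches_direct_formula(self):
        p = PowerSigmoidParams(3, 3.0)
        expected = ((1 + math.exp(-3)) * (1 - math.exp(-1.5))) / (
            (1 - math.exp(-3)) * (1 + math.exp(-1.5)))
        assert power_sigmoid(0.5, p) == pytest.approx(expected, rel=1e-12)

    def test_odd_and_strictly_increasing(self):
        p = PowerSigmoidParams(5, 3.5)
        grid = np.linspace(-2.5, 2.5, 2001)
        y = power_sigmoid(grid, p)
        np.testing.assert_allclose(y, -power_sigmoid(-grid, p), atol=1e-12)
        assert np.all(np.diff(y) > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PowerSigmoidParams(alpha=4, beta=3.0)  # even alpha breaks oddness
        with pytest.raises(ValueError):
            PowerSigmoidParams(alpha=1, beta=3.0)
        with pytest.raises(ValueError):
            PowerSigmoidParams(alpha=3, beta=2.0)


# --------------------------------------------------------------------------
# Cell steps vs scalar expansion
# --------------------------------------------------------------------------


def rand_mat(rng, r, c):
    return rng.normal(0, 0.6, size=(r, c))


class TestCellSteps:
    @pytest.mark.parametrize("seed", range(5))
    def test_rnn_step_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        H, D = 2, 3
        p = RnnParams(rand_mat(rng, H, D), rand_mat(rng, H, H),
                      rand_mat(rng, H, H), rng.normal(size=H), rng.normal(size=H))
        x, h_prev = rng.normal(size=D), rng.normal(size=H)
        h, y = rnn_step(x, h_prev, p)
        ho, yo = rnn_oracle(list(x), list(h_prev), p)
        np.testing.assert_allclose(h, ho, atol=1e-10)
        np.testing.assert_allclose(y, yo, atol=1e-10)

    def test_rnn_zero_weights_give_zero(self):
        H, D = 2, 3
        p = RnnParams(np.zeros((H, D)), np.zeros((H, H)), np.zeros((H, H)),
                      np.zeros(H), np.zeros(H))
        h, y = rnn_step(np.ones(D), np.ones(H), p)
        np.testing.assert_allclose(h, 0.0, atol=1e-12)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_rnn_no_recurrence_when_W_h_zero(self):
        rng = np.random.default_rng(0)
        H, D = 3, 4
        p = RnnParams(rand_mat(rng, H, D), np.zeros((H, H)), rand_mat(rng, H, H),
                      rng.normal(size=H), rng.normal(size=H))
        x = rng.normal(size=D)
        h1, _ = rnn_step(x, rng.normal(size=H), p)
        h2, _ = rnn_step(x, rng.normal(size=H), p)
        np.testing.assert_allclose(h1, h2, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_gru_step_matches_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        H, D = 2, 3
        p = GruParams(rand_mat(rng, H, H + D), rand_mat(rng, H, H + D),
                      rand_mat(rng, H, H + D))
        x, h_prev = rng.normal(size=D), rng.normal(size=H)
        np.testing.assert_allclose(gru_step(x, h_prev, p),
                                   gru_oracle(list(x), list(h_prev), p), atol=1e-10)

    def test_gru_update_gate_limits(self):
        rng = np.random.default_rng(1)
        H, D = 3, 2
        big = 60.0
        x, h_prev = rng.normal(size=D), rng.normal(size=H)
        # u -> 0: h unchanged
        p0 = GruParams(np.full((H, H + D), -big), rand_mat(rng, H, H + D),
                       rand_mat(rng, H, H + D))
        np.testing.assert_allclose(gru_step(x, h_prev, p0), h_prev, atol=1e-9)
        # u -> 1: h equals the candidate
        p1 = GruParams(np.full((H, H + D), big), rand_mat(rng, H, H + D),
                       rand_mat(rng, H, H + D))
        z = np.concatenate([h_prev, x])
        r = 1 / (1 + np.exp(-(p1.W_r @ z)))
        expect = np.tanh(p1.W_hhat @ np.concatenate([r * h_prev, x]))
        np.testing.assert_allclose(gru_step(x, h_prev, p1), expect, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_lstm_step_matches_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        H, D = 2, 3
        mats = {n: rand_mat(rng, H, D if n.endswith("x") else H)
                for n in ("w_ix", "w_ih", "w_fx", "w_fh", "w_ox", "w_oh",
                          "w_cx", "w_ch")}
        p = LstmParams(**mats)
        x, h_prev, C_prev = rng.normal(size=D), rng.normal(size=H), rng.normal(size=H)
        h, C = lstm_step(x, h_prev, C_prev, p)
        ho, Co = lstm_oracle(list(x), list(h_prev), list(C_prev), p)
        np.testing.assert_allclose(h, ho, atol=1e-10)
        np.testing.assert_allclose(C, Co, atol=1e-10)

    def test_lstm_forget_one_input_zero_preserves_cell(self):
        rng = np.random.default_rng(2)
        H, D = 3, 2
        big = 60.0
        mats = dict(
            w_ix=np.full((H, D), -big), w_ih=np.zeros((H, H)),       # i -> 0
            w_fx=np.full((H, D), big), w_fh=np.zeros((H, H)),        # f -> 1
            w_ox=rand_mat(rng, H, D), w_oh=rand_mat(rng, H, H),
            w_cx=rand_mat(rng, H, D), w_ch=rand_mat(rng, H, H),
        )
        x = np.ones(D)
        C_prev = rng.normal(size=H)
        _, C = lstm_step(x, rng.normal(size=H), C_prev, LstmParams(**mats))
        np.testing.assert_allclose(C, C_prev, atol=1e-9)

    def test_lstm_output_gate_zero_silences_h(self):
        rng = np.random.default_rng(3)
        H, D = 3, 2
        mats = dict(
            w_ix=rand_mat(rng, H, D), w_ih=rand_mat(rng, H, H),
            w_fx=rand_mat(rng, H, D), w_fh=rand_mat(rng, H, H),
            w_ox=np.full((H, D), -60.0), w_oh=np.zeros((H, H)),
            w_cx=rand_mat(rng, H, D), w_ch=rand_mat(rng, H, H),
        )
        h, _ = lstm_step(np.ones(D), rng.normal(size=H), rng.normal(size=H),
                         LstmParams(**mats))
        np.testing.assert_allclose(h, 0.0, atol=1e-9)

    def test_gate_outputs_bounded(self):
        rng = np.random.default_rng(4)
        H, D = 4, 5
        z = np.concatenate([rng.normal(size=H), rng.normal(size=D)])
        for _ in range(20):
            W = rng.normal(0, 3, size=(H, H + D))
            u = 1 / (1 + np.exp(-(W @ z)))
            assert np.all((u > 0) & (u < 1))


# --------------------------------------------------------------------------
# Classifier: gradients, training, prediction
# --------------------------------------------------------------------------


class TestGradients:
    @pytest.mark.parametrize("cell", ["rnn", "gru", "lstm"])
    def test_analytic_gradients_match_finite_differences(self, cell):
        rng = np.random.default_rng(11)
        cfg = TrainConfig(hidden_size=4, window=3, seed=1)
        m = HorizonClassifier(cell, n_horizons=2, input_size=5, config=cfg)
        X = rng.normal(size=(3, 3, 5)) * 0.5
        Y = rng.integers(0, 3, size=(3, 2))
        _, grads = m.loss_and_grads(X, Y)
        eps = 1e-6
        for name in m.params:
            flat = m.params[name].ravel()
            for k in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                lp, _ = m.loss_and_grads(X, Y)
                flat[k] = orig - eps
                lm, _ = m.loss_and_grads(X, Y)
                flat[k] = orig
                fd = (lp - lm) / (2 * eps)
                assert grads[name].ravel()[k] == pytest.approx(fd, abs=2e-5), (
                    f"{cell}.{name}[{k}]")


class TestTraining:
    @pytest.mark.parametrize("cell", ["rnn", "gru", "lstm"])
    def test_separable_fixture_reaches_95pct(self, separable_samples, cell):
        cfg = TrainConfig(hidden_size=8, window=2, epochs=60, learning_rate=0.1,
                          batch_size=32, seed=0)
        m = HorizonClassifier(cell, 1, 20, cfg).fit(separable_samples)
        X, Y = make_sequences(separable_samples, 2)
        acc = (m.predict_scores(X).argmax(axis=2) == Y).mean()
        assert acc >= 0.95

    def test_same_seed_identical_parameters(self, separable_samples):
        cfg = TrainConfig(hidden_size=6, window=2, epochs=5, learning_rate=0.05,
                          seed=3)
        m1 = HorizonClassifier("gru", 1, 20, cfg).fit(separable_samples)
        m2 = HorizonClassifier("gru", 1, 20, cfg).fit(separable_samples)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_zero_epochs_leaves_params_unchanged(self, separable_samples):
        cfg = TrainConfig(hidden_size=6, window=2, epochs=0, seed=3)
        m = HorizonClassifier("lstm", 1, 20, cfg)
        before = {k: v.copy() for k, v in m.params.items()}
        m.fit(separable_samples)
        for k in before:
            np.testing.assert_array_equal(m.params[k], before[k])

    def test_loss_trace_decreases_on_smoothed_window(self, separable_samples):
        cfg = TrainConfig(hidden_size=8, window=2, epochs=30, learning_rate=0.1,
                          batch_size=32, seed=0)
        m = HorizonClassifier("rnn", 1, 20, cfg).fit(separable_samples)
        trace = np.array(m.loss_trace)
        assert trace[-5:].mean() < trace[:5].mean()

    def test_single_class_warns_but_trains(self, separable_samples):
        only0 = [s for s in separable_samples if s.labels[0] == 0]
        cfg = TrainConfig(hidden_size=4, window=2, epochs=1, seed=0)
        with pytest.warns(UserWarning, match="single class"):
            HorizonClassifier("gru", 1, 20, cfg).fit(only0)

    def test_train_wrapper_reconfigures(self, separable_samples):
        m = HorizonClassifier("gru", 1, 20)
        cfg = TrainConfig(hidden_size=4, window=2, epochs=2, seed=9)
        out = train(m, separable_samples, cfg)
        assert out is m and m.config.hidden_size == 4


class TestPrediction:
    def test_scores_normalize_and_ties_break_low(self, separable_samples):
        cfg = TrainConfig(hidden_size=4, window=2, epochs=0, seed=0)
        m = HorizonClassifier("gru", 1, 20, cfg).fit(separable_samples[:10])
        # force uniform logits on every head
        m.params["W_out"][:] = 0.0
        m.params["b_out"][:] = 0.0
        pred, scores = m.predict(np.zeros(20))
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(pred, [0])  # uniform -> lowest class id

    def test_untrained_model_refuses_to_predict(self):
        m = HorizonClassifier("rnn", 1, 20)
        with pytest.raises(RuntimeError, match="not trained"):
            m.predict(np.zeros(20))

    def test_window_padding_repeats_earliest_sample(self, separable_samples):
        X, _ = make_sequences(separable_samples[:1], window=4)
        # single sample per record: all four window steps identical
        assert X.shape == (1, 4, 20)
        for t in range(1, 4):
            np.testing.assert_array_equal(X[0, t], X[0, 0])
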