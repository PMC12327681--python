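"""Gradient and behaviour checks for the NumPy autograd toolkit."""

import numpy as np
import pytest

import msmce.nn as nn
from msmce.nn import Tensor


def fd_check(make_loss, named_params, eps=1e-5, tol=1e-6):
    """Norm-level finite-difference agreement for every parameter tensor."""
    loss = make_loss()
    for _, p in named_params:
        p.zero_grad()
    loss.backward()
    for name, p in named_params:
        flat = p.data.ravel()
        fd = np.empty(flat.size)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            lp = make_loss().data.item()
            flat[i] = orig - eps
            lm = make_loss().data.item()
            flat[i] = orig
            fd[i] = (lp - lm) / (2 * eps)
        an = p.grad.ravel()
        err = np.linalg.norm(fd - an) / max(np.linalg.norm(an),
                                            np.linalg.norm(fd), 1.0)
        assert err < tol, f"{name}: fd mismatch {err:.2e}"


class TestAutogradOps:
    def test_add_mul_broadcast(self, rng):
        a = nn.Parameter(rng.normal(size=(3, 4)))
        b = nn.Parameter(rng.normal(size=(4,)))
        r = Tensor(rng.normal(size=(3, 4)))
        fd_check(lambda: ((a * b + b) * r).sum(), [("a", a), ("b", b)])

    def test_matmul_batched(self, rng):
        a = nn.Parameter(rng.normal(size=(2, 3, 4)))
        b = nn.Parameter(rng.normal(size=(2, 4, 5)))
        r = Tensor(rng.normal(size=(2, 3, 5)))
        fd_check(lambda: ((a @ b) * r).sum(), [("a", a), ("b", b)])

    def test_elementwise_chain(self, rng):
        x = nn.Parameter(rng.normal(size=(4, 3)) + 3.0)
        r = Tensor(rng.normal(size=(4, 3)))
        fd_check(lambda: ((x.log() + x.exp().pow(0.1)).tanh() * r).sum(), [("x", x)])

    def test_softmax_rows_sum_to_one(self, rng):
        x = Tensor(rng.normal(size=(5, 7)) * 10)
        assert np.allclose(x.softmax(axis=-1).data.sum(axis=-1), 1.0)

    def test_logsumexp_matches_scipy(self, rng):
        from scipy.special import logsumexp
        x = rng.normal(size=(4, 6)) * 5
        ours = Tensor(x).logsumexp(axis=1, keepdims=True).data
        assert np.allclose(ours, logsumexp(x, axis=1, keepdims=True))

    def test_getitem_gradient(self, rng):
        x = nn.Parameter(rng.normal(size=(4, 5)))
        r = Tensor(rng.normal(size=(4,)))
        idx = np.array([0, 2, 1, 4])
        fd_check(lambda: (x[np.arange(4), idx] * r).sum(), [("x", x)])

    def test_concat_gradient(self, rng):
        a = nn.Parameter(rng.normal(size=(2, 3)))
        b = nn.Parameter(rng.normal(size=(2, 2)))
        r = Tensor(rng.normal(size=(2, 5)))
        fd_check(lambda: (nn.concat([a, b], axis=1) * r).sum(),
                 [("a", a), ("b", b)])

    def test_backward_frees_graph(self, rng):
        x = nn.Parameter(rng.normal(size=(3,)))
        loss = (x * x).sum()
        loss.backward()
        assert loss._backward is None and loss._prev == ()

    def test_no_grad_builds_no_graph(self, rng):
        x = nn.Parameter(rng.normal(size=(3,)))
        with nn.no_grad():
            y = (x * 2).sum()
        assert not y.requires_grad


class TestLayers:
    def test_linear_gradients(self, rng):
        lin = nn.Linear(5, 3, rng)
        X = Tensor(rng.normal(size=(4, 5)))
        r = Tensor(rng.normal(size=(4, 3)))
        fd_check(lambda: (lin(X) * r).sum(), list(lin.named_parameters()))

    def test_linear_shape_error(self, rng):
        with pytest.raises(ValueError, match="expected last dim 5"):
            nn.Linear(5, 3, rng)(Tensor(np.zeros((2, 4))))

    def test_layernorm_constant_row_is_beta(self, rng):
        ln = nn.LayerNorm(6)
        out = ln(Tensor(np.full((2, 6), 3.7)))
        assert np.allclose(out.data, 0.0, atol=1e-6)  # beta starts at 0

    def test_layernorm_gradients(self, rng):
        ln = nn.LayerNorm(5)
        ln.gamma.data[:] = rng.normal(size=5)
        X = Tensor(rng.normal(size=(4, 5)))
        r = Tensor(rng.normal(size=(4, 5)))
        fd_check(lambda: (ln(X) * r).sum(), list(ln.named_parameters()))

    def test_conv1d_gradients(self, rng):
        conv = nn.Conv1d(2, 3, 3, rng, padding=1)
        X = Tensor(rng.normal(size=(2, 2, 7)))
        r = Tensor(rng.normal(size=(2, 3, 7)))
        fd_check(lambda: (conv(X) * r).sum(), list(conv.named_parameters()))

    def test_conv1d_input_gradient(self, rng):
        conv = nn.Conv1d(2, 3, 3, rng, padding=1)
        x = nn.Parameter(rng.normal(size=(2, 2, 7)))
        r = Tensor(rng.normal(size=(2, 3, 7)))
        fd_check(lambda: (conv(x) * r).sum(), [("x", x)])

    def test_conv1d_same_length(self, rng):
        for L in (7, 64, 1024):
            conv = nn.Conv1d(1, 2, 3, rng, padding=1)
            out = conv(Tensor(np.zeros((1, 1, L))))
            assert out.shape == (1, 2, L)

    def test_batchnorm_gradients(self, rng):
        bn = nn.BatchNorm1d(3)
        bn.gamma.data[:] = rng.normal(size=3)
        x = nn.Parameter(rng.normal(size=(2, 3, 5)))
        r = Tensor(rng.normal(size=(2, 3, 5)))
        fd_check(lambda: (bn(x) * r).sum(),
                 [("x", x)] + list(bn.named_parameters()))

    def test_batchnorm_train_vs_eval(self, rng):
        bn = nn.BatchNorm1d(3)
        X = rng.normal(size=(8, 3, 5))
        for _ in range(30):
            bn(Tensor(rng.normal(size=(8, 3, 5))))
        bn.eval()
        out1 = bn(Tensor(X)).data
        out2 = bn(Tensor(X)).data
        assert np.array_equal(out1, out2)  # eval uses frozen running stats

    def test_batchnorm_single_sample_train_raises(self):
        bn = nn.BatchNorm1d(3)
        with pytest.raises(ValueError, match="batch"):
            bn(Tensor(np.zeros((1, 3, 1))))

    def test_dropout_eval_identity(self, rng):
        drop = nn.Dropout(0.5, rng)
        drop.eval()
        X = rng.normal(size=(4, 5))
        assert np.array_equal(drop(Tensor(X)).data, X)

    def test_dropout_preserves_expectation(self):
        rng = np.random.default_rng(0)
        drop = nn.Dropout(0.3, rng)
        X = np.ones((200, 200))
        out = drop(Tensor(X)).data
        assert out.mean() == pytest.approx(1.0, abs=0.02)

    def test_lstm_gradients(self, rng):
        lstm = nn.LSTM(3, 4, rng)
        X = Tensor(rng.normal(size=(2, 5, 3)))
        r = Tensor(rng.normal(size=(2, 4)))
        fd_check(lambda: (lstm(X) * r).sum(), list(lstm.named_parameters()))

    def test_attention_gradients(self, rng):
        att = nn.MultiHeadSelfAttention(8, 2, rng)
        X = Tensor(rng.normal(size=(2, 4, 8)))
        r = Tensor(rng.normal(size=(2, 4, 8)))
        fd_check(lambda: (att(X) * r).sum(), list(att.named_parameters()))

    def test_transformer_layer_gradients(self, rng):
        layer = nn.TransformerEncoderLayer(8, 2, 16, 0.0, rng)
        X = Tensor(rng.normal(size=(2, 4, 8)))
        r = Tensor(rng.normal(size=(2, 4, 8)))
        fd_check(lambda: (layer(X) * r).sum(), list(layer.named_parameters()),
                 tol=1e-5)

    def test_state_dict_round_trip(self, rng):
        m1 = nn.Sequential(nn.Linear(4, 8, rng), nn.ReLU(), nn.Linear(8, 2, rng))
        m2 = nn.Sequential(nn.Linear(4, 8, rng), nn.ReLU(), nn.Linear(8, 2, rng))
        m2.load_state_dict(m1.state_dict())
        X = Tensor(rng.normal(size=(3, 4)))
        assert np.array_equal(m1(X).data, m2(X).data)


class TestCrossEntropy:
    def test_uniform_logits_log_k(self):
        logits = Tensor(np.zeros((4, 3)))
        loss = nn.cross_entropy(logits, np.array([0, 1, 2, 0]))
        assert loss.data == pytest.approx(np.log(3))

    def test_matches_manual_weighted(self, rng):
        logits_data = rng.normal(size=(6, 3))
        y = np.array([0, 1, 2, 0, 1, 2])
        w = np.array([0.5, 1.0, 2.0])
        loss = nn.cross_entropy(Tensor(logits_data), y, w).data
        # independent computation
        e = np.exp(logits_data - logits_data.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        nll = -np.log(p[np.arange(6), y])
        expected = (w[y] * nll).sum() / w[y].sum()
        assert loss == pytest.approx(expected, rel=1e-12)

    def test_gradients(self, rng):
        lin = nn.Linear(4, 3, rng)
        X = Tensor(rng.normal(size=(5, 4)))
        y = np.array([0, 1, 2, 1, 0])
        w = np.array([1.0, 2.0, 0.5])
        fd_check(lambda: nn.cross_entropy(lin(X), y, w),
                 list(lin.named_parameters()))


class TestAdam:
    def test_quadratic_convergence(self):
        x = nn.Parameter(np.array([5.0, -3.0]))
        opt = nn.Adam([x], lr=0.1)
        for _ in range(300):
            loss = (x * x).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(x.data).max() < 1e-3

    def test_weight_decay_shrinks_unused_param(self):
        x = nn.Parameter(np.array([1.0]))
        y = nn.Parameter(np.array([1.0]))
        opt = nn.Adam([x, y], lr=0.01, weight_decay=0.1)
        for _ in range(50):
            loss = ((x - 1.0) ** 2).sum()  # y only sees decay
            opt.zero_grad()
            loss.backward()
            y.grad = np.zeros_like(y.data)
            opt.step()
        assert y.data[0] < 1.0


class TestPlateauScheduler:
    def test_decays_after_patience_exceeded(self):
        opt = nn.Adam([nn.Parameter(np.zeros(1))], lr=1e-3)
        sched = nn.ReduceLROnPlateau(opt, factor=0.1, patience=5)
        sched.step(1.0)             # initial best
        for _ in range(5):
            sched.step(1.0)         # 5 stagnant epochs: not yet
        assert opt.lr == pytest.approx(1e-3)
        sched.step(1.0)             # 6th stagnant epoch triggers decay
        assert opt.lr == pytest.approx(1e-4)

    def test_improvement_resets_counter(self):
        opt = nn.Adam([nn.Parameter(np.zeros(1))], lr=1e-3)
        sched = nn.ReduceLROnPlateau(opt, factor=0.1, patience=2)
        for v in [1.0, 1.0, 1.0, 0.5, 1.0, 1.0]:
            sched.step(v)
        assert opt.lr == pytest.approx(1e-3)
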