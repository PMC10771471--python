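"""Encoder, predictors, losses: closed forms, oracles, and gradient checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemst import (
    ExpressionMatrix,
    SpatialCoords,
    cross_mapping,
    gaussian_adjacency,
    intra_adjacency,
    mmd,
    row_cross_entropy,
    total_loss,
    two_step_adjacency,
)
from stemst.data_model import LOGNORM, RAW
from stemst.model import (
    EncoderConfig,
    MLPEncoder,
    _mmd_with_grad,
    _row_softmax,
    encode,
    extract_loss_and_grad,
    sparsity_dropout_rate,
    trans_loss_and_grad,
)


def _em(values, layer=RAW):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{j}" for j in range(values.shape[1])],
        [f"r{i}" for i in range(values.shape[0])],
        layer,
    )


def _random_stochastic(rng, n, m=None):
    w = rng.random((n, m or n)) + 1e-3
    return w / w.sum(axis=1, keepdims=True)


class TestSparsityDropout:
    def test_forced_by_medians(self, rng):
        sc = np.zeros((5, 4000))
        sc[:, :1000] = 1.0  # every cell detects 1000 genes
        stm = np.zeros((5, 4000))
        stm[:, :4000] = 1.0  # every spot detects 4000
        assert sparsity_dropout_rate(_em(sc), _em(stm)) == pytest.approx(0.75)

    def test_equal_medians_zero(self, rng):
        x = rng.poisson(2.0, size=(10, 50)).astype(float)
        assert sparsity_dropout_rate(_em(x), _em(x.copy())) == 0.0

    def test_denser_sc_clamps_to_zero_with_warning(self):
        sc = np.ones((4, 100))
        stm = np.zeros((4, 100))
        stm[:, :10] = 1.0
        with pytest.warns(UserWarning, match="clamping"):
            assert sparsity_dropout_rate(_em(sc), _em(stm)) == 0.0

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            sparsity_dropout_rate(_em(np.zeros((3, 5))), _em(np.ones((3, 5))))


class TestEncoder:
    def test_identical_rows_identical_embeddings(self, rng):
        enc = MLPEncoder(EncoderConfig(n_genes=6, hidden_sizes=(8,), latent_dim=3))
        x = np.tile(rng.normal(size=(1, 6)), (4, 1))
        z, _ = enc.forward(x)
        assert np.allclose(z, z[0])

    def test_untrained_output_finite(self, rng):
        enc = MLPEncoder(EncoderConfig(n_genes=10, seed=7))
        z, _ = enc.forward(rng.normal(size=(5, 10)) * 100)
        assert np.all(np.isfinite(z))

    def test_seeded_dropout_mask_reproducible(self, rng):
        enc = MLPEncoder(EncoderConfig(n_genes=12, hidden_sizes=(6,), latent_dim=4))
        x = rng.normal(size=(8, 12))
        z1, _ = enc.forward(x, dropout_rate=0.5, dropout_rng=np.random.default_rng(9))
        z2, _ = enc.forward(x, dropout_rate=0.5, dropout_rng=np.random.default_rng(9))
        assert np.array_equal(z1, z2)

    def test_gene_count_mismatch_errors(self, rng):
        enc = MLPEncoder(EncoderConfig(n_genes=5))
        with pytest.raises(ValueError):
            enc.forward(rng.normal(size=(2, 6)))

    def test_encode_requires_lognorm(self, rng):
        enc = MLPEncoder(EncoderConfig(n_genes=3))
        with pytest.raises(ValueError):
            encode(_em(np.ones((2, 3)), layer=RAW), enc)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = EncoderConfig(n_genes=6, hidden_sizes=(5,), latent_dim=3, seed=2)
        enc = MLPEncoder(cfg)
        enc.save(tmp_path / "ckpt.npz")
        back = MLPEncoder.load(tmp_path / "ckpt.npz", cfg)
        x = rng.normal(size=(3, 6))
        assert np.array_equal(enc.forward(x)[0], back.forward(x)[0])


class TestPredictors:
    def test_intra_uniform_for_zero_embeddings(self):
        s = intra_adjacency(np.zeros((4, 3)))
        assert np.allclose(s, 0.25)

    def test_intra_orthonormal_closed_form(self):
        z = np.eye(2)
        s = intra_adjacency(z)
        e = np.e
        assert s[0, 0] == pytest.approx(e / (e + 1))
        assert s[0, 1] == pytest.approx(1 / (e + 1))

    def test_intra_matches_bruteforce_softmax(self, rng):
        z = rng.normal(size=(6, 5))
        g = z @ z.T
        expected = np.exp(g) / np.exp(g).sum(axis=1, keepdims=True)
        assert np.allclose(intra_adjacency(z), expected, atol=1e-10)

    def test_cross_uniform_for_zero_embeddings(self):
        c, c_hat = cross_mapping(np.zeros((3, 2)), np.zeros((5, 2)))
        assert np.allclose(c, 1 / 5) and np.allclose(c_hat, 1 / 3)

    def test_cross_matching_embedding_wins(self):
        z_st = np.eye(4) * 3.0
        z_sc = z_st[[2]]
        c, _ = cross_mapping(z_sc, z_st)
        assert np.argmax(c[0]) == 2

    def test_cross_matches_bruteforce_softmax(self, rng):
        z_sc, z_st = rng.normal(size=(4, 7)), rng.normal(size=(5, 7))
        b = z_sc @ z_st.T
        c, c_hat = cross_mapping(z_sc, z_st)
        assert np.allclose(c, np.exp(b) / np.exp(b).sum(1, keepdims=True), atol=1e-10)
        bt = b.T
        assert np.allclose(
            c_hat, np.exp(bt) / np.exp(bt).sum(1, keepdims=True), atol=1e-10
        )

    def test_cross_dim_mismatch(self, rng):
        with pytest.raises(ValueError):
            cross_mapping(rng.normal(size=(3, 4)), rng.normal(size=(3, 5)))

    def test_two_step_uniform(self):
        c = np.full((4, 3), 1 / 3)
        c_hat = np.full((3, 4), 1 / 4)
        assert np.allclose(two_step_adjacency(c, c_hat), 1 / 3)

    def test_two_step_permutation_identity(self):
        perm = np.eye(4)[[2, 0, 3, 1]]
        assert np.allclose(two_step_adjacency(perm, perm.T), np.eye(4))

    def test_two_step_matches_product_oracle(self, rng):
        c = _random_stochastic(rng, 4, 3)
        c_hat = _random_stochastic(rng, 3, 4)
        s = two_step_adjacency(c, c_hat)
        assert np.allclose(s, c_hat @ c, atol=1e-12)
        assert np.max(np.abs(s.sum(axis=1) - 1)) < 1e-12

    def test_permutation_equivariance_of_mapping(self, rng):
        z_sc, z_st = rng.normal(size=(5, 3)), rng.normal(size=(4, 3))
        perm = np.random.default_rng(0).permutation(5)
        c, c_hat = cross_mapping(z_sc, z_st)
        cp, cp_hat = cross_mapping(z_sc[perm], z_st)
        assert np.allclose(cp, c[perm], atol=1e-12)
        assert np.allclose(cp_hat, c_hat[:, perm], atol=1e-12)

    @given(seed=st.integers(0, 500), n=st.integers(2, 8), scale=st.floats(0.1, 30.0))
    @settings(max_examples=40, deadline=None)
    def test_predictors_row_stochastic_for_arbitrary_embeddings(self, seed, n, scale):
        g = np.random.default_rng(seed)
        z_st = g.normal(size=(n, 4)) * scale
        z_sc = g.normal(size=(n + 1, 4)) * scale
        s = intra_adjacency(z_st)
        c, c_hat = cross_mapping(z_sc, z_st)
        s_hat = two_step_adjacency(c, c_hat)
        for m in (s, c, c_hat, s_hat):
            assert np.max(np.abs(m.sum(axis=1) - 1.0)) < 1e-8
            assert (m >= 0).all()


class TestRowCrossEntropy:
    def test_uniform_prediction_gives_log_n(self, rng):
        n = 7
        truth = _random_stochastic(rng, n)
        pred = np.full((n, n), 1.0 / n)
        assert row_cross_entropy(pred, truth) == pytest.approx(np.log(n))

    def test_loss_vanishes_for_sharp_match(self):
        eps = 1e-9
        truth = np.eye(3)
        pred = np.eye(3) * (1 - 2 * eps) + eps
        assert row_cross_entropy(pred, truth) < 1e-8

    def test_gibbs_inequality_against_random_predictions(self, rng):
        truth = _random_stochastic(rng, 5)
        base = row_cross_entropy(truth, truth)
        for _ in range(200):
            p = _random_stochastic(rng, 5)
            assert row_cross_entropy(p, truth) >= base - 1e-12

    def test_nonpositive_prediction_rejected(self):
        truth = np.full((2, 2), 0.5)
        with pytest.raises(ValueError):
            row_cross_entropy(np.array([[1.0, 0.0], [0.5, 0.5]]), truth)


class TestMMD:
    def test_identical_batches_zero(self, rng):
        z = rng.normal(size=(10, 4))
        assert abs(mmd(z, z.copy())) < 1e-9

    def test_separated_distributions_exceed_null(self):
        g = np.random.default_rng(42)
        a = g.normal(size=(100, 5))
        b = g.normal(size=(100, 5))
        shifted = g.normal(size=(100, 5)) + 5.0
        assert mmd(a, shifted) > mmd(a, b)
        assert mmd(a, shifted) > 0.1

    def test_linear_kernel_closed_form(self):
        a = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 3.0]])
        b = np.array([[1.0, 1.0], [3.0, 1.0], [2.0, 4.0]])
        diff = a.mean(axis=0) - b.mean(axis=0)
        assert mmd(a, b, kernel="linear") == pytest.approx(diff @ diff)

    def test_symmetry_and_translation_invariance(self, rng):
        a, b = rng.normal(size=(8, 3)), rng.normal(size=(12, 3))
        assert mmd(a, b) == pytest.approx(mmd(b, a), abs=1e-12)
        shift = np.array([10.0, -4.0, 2.0])
        assert mmd(a + shift, b + shift) == pytest.approx(mmd(a, b), abs=1e-12)

    def test_small_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            mmd(rng.normal(size=(1, 3)), rng.normal(size=(5, 3)))


class TestTotalLoss:
    def test_arithmetic(self):
        rec = total_loss(1.0, 0.2, 0.5, alpha=0.5, beta=1.0)
        assert rec.total == pytest.approx(1.6)

    def test_beta_zero_ignores_trans(self):
        a = total_loss(1.0, 0.2, 0.5, alpha=0.5, beta=0.0)
        b = total_loss(1.0, 0.2, 99.0, alpha=0.5, beta=0.0)
        assert a.total == b.total

    def test_default_alpha_is_half(self):
        import inspect

        assert inspect.signature(total_loss).parameters["alpha"].default == 0.5


class TestLossGradients:
    """Analytic gradients of the three losses vs central finite differences."""

    def _fd(self, f, arr, eps=1e-6):
        num = np.zeros_like(arr)
        for idx in np.ndindex(arr.shape):
            p, m = arr.copy(), arr.copy()
            p[idx] += eps
            m[idx] -= eps
            num[idx] = (f(p) - f(m)) / (2 * eps)
        return num

    def test_extract_gradient(self, rng):
        z = rng.normal(size=(5, 3))
        s = _random_stochastic(rng, 5)
        _, g = extract_loss_and_grad(z, s)
        num = self._fd(lambda a: extract_loss_and_grad(a, s)[0], z)
        assert np.abs(g - num).max() < 1e-6

    def test_trans_gradients(self, rng):
        z_sc, z_st = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
        s = _random_stochastic(rng, 5)
        _, g_sc, g_st, _, _ = trans_loss_and_grad(z_sc, z_st, s)
        num_sc = self._fd(lambda a: trans_loss_and_grad(a, z_st, s)[0], z_sc)
        num_st = self._fd(lambda a: trans_loss_and_grad(z_sc, a, s)[0], z_st)
        assert np.abs(g_sc - num_sc).max() < 1e-6
        assert np.abs(g_st - num_st).max() < 1e-6

    def test_mmd_gradients_with_frozen_bandwidth(self, rng, monkeypatch):
        import stemst.model as model_mod

        a, b = rng.normal(size=(5, 3)), rng.normal(size=(7, 3)) + 1.0
        med = model_mod._median_heuristic(a, b)
        monkeypatch.setattr(model_mod, "_median_heuristic", lambda *args: med)
        _, ga, gb = _mmd_with_grad(a, b)
        num_a = self._fd(lambda x: _mmd_with_grad(x, b, want_grad=False)[0], a)
        num_b = self._fd(lambda x: _mmd_with_grad(a, x, want_grad=False)[0], b)
        assert np.abs(ga - num_a).max() < 1e-6
        assert np.abs(gb - num_b).max() < 1e-6

    def test_encoder_parameter_and_input_gradients(self, rng):
        enc = MLPEncoder(EncoderConfig(n_genes=6, hidden_sizes=(5,), latent_dim=3, seed=1))
        x = rng.normal(size=(4, 6))

        def loss():
            z, _ = enc.forward(x)
            return float((z**2).sum())

        z, cache = enc.forward(x)
        grads = enc.backward(cache, 2 * z)
        eps = 1e-6
        for li in range(2):
            w = enc.weights[li]
            num = np.zeros_like(w)
            for idx in np.ndindex(w.shape):
                w[idx] += eps
                lp = loss()
                w[idx] -= 2 * eps
                lm = loss()
                w[idx] += eps
                num[idx] = (lp - lm) / (2 * eps)
            assert np.abs(grads["weights"][li] - num).max() < 1e-5
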