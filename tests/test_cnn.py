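"""CNN engine and estimators: architecture conformance, learning sanity checks."""

import numpy as np
import pytest

from palmdas import nn
from palmdas.cnn import (
    ImageCNNClassifier,
    build_model,
    default_spec,
    layer_output_shapes,
)


def shape_oracle(h, w, kh, kw):
    """Valid-convolution output shape, by hand."""
    return h - kh + 1, w - kw + 1


class TestArchitectureConformance:
    def test_temporal_first_conv_shape(self):
        assert shape_oracle(10, 500, 3, 50) == (8, 451)
        assert layer_output_shapes(default_spec("temporal"))[0] == (8, 451, 16)

    def test_spectral_first_conv_shape(self):
        assert shape_oracle(10, 250, 3, 5) == (8, 246)
        assert layer_output_shapes(default_spec("spectral"))[0] == (8, 246, 32)

    @pytest.mark.parametrize("branch", ["temporal", "spectral"])
    def test_forward_pass_shapes_match_arithmetic(self, branch):
        """Every layer's activation shape equals the shape-arithmetic chain."""
        spec = default_spec(branch)
        model = build_model(spec, seed=0)
        h, w = spec.input_shape
        x = np.zeros((2, h, w, 1), dtype=np.float32)
        expected = layer_output_shapes(spec)
        # replay the conv/pool/flatten/dense chain layer by layer
        conv_pool = [s for s in expected if len(s) == 3]
        acts = []
        for layer in model.layers:
            x = layer.forward(x)
            if isinstance(layer, (nn.Conv2D, nn.MaxPool2x2)):
                acts.append(x.shape[1:])
        assert acts == conv_pool
        assert x.shape == (2, 1)  # single sigmoid output node

    def test_both_branches_second_conv_is_3x3_32(self):
        for branch in ("temporal", "spectral"):
            spec = default_spec(branch)
            kind, filters, kernel, stride, act = spec.layers[2]
            assert (kind, filters, kernel, stride) == ("conv", 32, (3, 3), (1, 1))

    def test_dense_head_is_50_then_1(self):
        spec = default_spec("temporal")
        assert spec.layers[-2][:2] == ("dense", 50)
        assert spec.layers[-1][:2] == ("dense", 1)

    def test_build_deterministic_from_seed(self):
        a = build_model(default_spec("spectral"), seed=7)
        b = build_model(default_spec("spectral"), seed=7)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa, pb)
        c = build_model(default_spec("spectral"), seed=8)
        assert any(not np.array_equal(pa, pc) for pa, pc in zip(a.params(), c.params()))

    def test_kernel_taller_than_input_rejected(self):
        with pytest.raises(ValueError):
            nn.Conv2D(3, 5, 1, 4, np.random.default_rng(0)).output_shape(2, 4)

    def test_unknown_branch_rejected(self):
        with pytest.raises(ValueError):
            default_spec("wavelet")


def _toy_spectral_set(n, seed):
    """Separable toy task: infested = energy in the 100-800 Hz bins,
    healthy = near silence; 10x250 spectral-image geometry."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 0.05, size=(n, 10, 250)).astype(np.float32)
    y = np.array(["healthy", "infested"] * (n // 2))[:n]
    band = slice(10, 80)
    for i in range(n):
        if y[i] == "infested":
            x[i, :, band] += rng.uniform(0.4, 1.0, size=(10, 70))
    return x, y


class TestTraining:
    def test_separable_toy_task_learned_quickly(self):
        """A linearly separable energy contrast is learned to >=95% within
        10 epochs (a logistic fit on band energy also separates it)."""
        x, y = _toy_spectral_set(240, seed=0)
        xv, yv = _toy_spectral_set(80, seed=1)
        clf = ImageCNNClassifier(branch="spectral", epochs=10, batch_size=32,
                                 random_state=0).fit(x, y, X_val=xv, y_val=yv)
        assert max(clf.history_["val_acc"]) >= 0.95
        # cross-check separability with an independent linear oracle
        from sklearn.linear_model import LogisticRegression
        feat = x[:, :, 10:80].mean(axis=(1, 2)).reshape(-1, 1)
        featv = xv[:, :, 10:80].mean(axis=(1, 2)).reshape(-1, 1)
        lr = LogisticRegression().fit(feat, y)
        assert lr.score(featv, yv) >= 0.95

    def test_shuffled_labels_stay_at_chance(self):
        x, y = _toy_spectral_set(200, seed=2)
        rng = np.random.default_rng(3)
        y_shuffled = rng.permutation(y)
        xv, yv = _toy_spectral_set(100, seed=4)
        yv = rng.permutation(yv)
        clf = ImageCNNClassifier(branch="spectral", epochs=3, batch_size=32,
                                 patience=None, random_state=0).fit(
                                     x, y_shuffled, X_val=xv, y_val=yv)
        assert abs(max(clf.history_["val_acc"]) - 0.5) <= 0.1

    def test_single_batch_overfit(self):
        """Capacity sanity: 8 examples are memorized to 100% train accuracy."""
        x, y = _toy_spectral_set(8, seed=5)
        clf = ImageCNNClassifier(branch="spectral", epochs=30, batch_size=8,
                                 patience=None, random_state=0).fit(
                                     x, y, X_val=x, y_val=y)
        assert clf.history_["train_acc"][-1] == 1.0

    def test_predictions_are_probabilities_and_consistent(self):
        x, y = _toy_spectral_set(64, seed=6)
        clf = ImageCNNClassifier(branch="spectral", epochs=2,
                                 random_state=0).fit(x, y)
        p = clf.predict_proba(x)
        assert p.shape == (64, 2)
        assert np.all((p >= 0) & (p <= 1))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, rtol=1e-6)
        # duplicated inputs give identical outputs
        dup = np.repeat(x[:4], 3, axis=0)
        pd_ = clf.predict_proba(dup)[:, 1].reshape(4, 3)
        assert np.all(pd_ == pd_[:, :1])
        assert set(clf.predict(x)) <= {"healthy", "infested"}
        assert list(clf.classes_) == ["healthy", "infested"]

    def test_trained_model_rejects_silent_image(self):
        x, y = _toy_spectral_set(120, seed=7)
        clf = ImageCNNClassifier(branch="spectral", epochs=6,
                                 random_state=0).fit(x, y)
        silent = np.zeros((1, 10, 250), dtype=np.float32)
        assert clf.predict_proba(silent)[0, 1] < 0.5

    def test_shape_mismatch_rejected(self):
        x, y = _toy_spectral_set(16, seed=8)
        clf = ImageCNNClassifier(branch="spectral", epochs=1, random_state=0).fit(x, y)
        with pytest.raises(ValueError, match="expects"):
            clf.predict(np.zeros((2, 10, 500), dtype=np.float32))
        with pytest.raises(ValueError, match="expects"):
            ImageCNNClassifier(branch="temporal", epochs=1).fit(x, y)

    def test_fit_reproducible_from_random_state(self):
        x, y = _toy_spectral_set(64, seed=9)
        a = ImageCNNClassifier(branch="spectral", epochs=2, random_state=3).fit(x, y)
        b = ImageCNNClassifier(branch="spectral", epochs=2, random_state=3).fit(x, y)
        assert a.history_ == b.history_
        np.testing.assert_array_equal(a.predict_proba(x), b.predict_proba(x))

    def test_sklearn_params_roundtrip(self):
        clf = ImageCNNClassifier(branch="temporal", epochs=4)
        params = clf.get_params()
        assert params["branch"] == "temporal"
        clone = ImageCNNClassifier(**params)
        assert clone.get_params() == params


class TestEngine:
    def test_conv_gemm_matches_direct_convolution(self):
        """im2col/GEMM convolution equals a naive nested-loop computation."""
        rng = np.random.default_rng(0)
        conv = nn.Conv2D(2, 3, 2, 4, rng)
        x = rng.standard_normal((3, 5, 7, 2)).astype(np.float32)
        out = conv.forward(x)
        w = conv.w.reshape(2, 3, 2, 4)
        naive = np.zeros_like(out)
        for i in range(4):
            for j in range(5):
                patch = x[:, i:i + 2, j:j + 3, :]
                naive[:, i, j, :] = np.einsum("nhwc,hwcf->nf", patch, w) + conv.b
        np.testing.assert_allclose(out, naive, rtol=1e-5)

    def test_maxpool_forward_backward(self):
        pool = nn.MaxPool2x2()
        x = np.arange(16, dtype=np.float32).reshape(1, 4, 4, 1)
        out = pool.forward(x)
        np.testing.assert_array_equal(out[0, :, :, 0], [[5, 7], [13, 15]])
        dx = pool.backward(np.ones_like(out))
        assert dx.sum() == 4  # gradient routed only to the maxima
        assert dx[0, 1, 1, 0] == 1 and dx[0, 0, 0, 0] == 0

    def test_dense_gradient_check(self):
        """Analytic gradients match central finite differences."""
        rng = np.random.default_rng(1)
        layer = nn.Dense(6, 3, rng)
        x = rng.standard_normal((4, 6)).astype(np.float32)
        dout = rng.standard_normal((4, 3)).astype(np.float32)
        layer.forward(x)
        layer.backward(dout)
        eps = 1e-3
        for idx in [(0, 0), (3, 2)]:
            w0 = layer.w[idx]
            layer.w[idx] = w0 + eps
            up = float((layer.forward(x) * dout).sum())
            layer.w[idx] = w0 - eps
            down = float((layer.forward(x) * dout).sum())
            layer.w[idx] = w0
            np.testing.assert_allclose(layer.dw[idx], (up - down) / (2 * eps), rtol=2e-2)

    def test_bce_loss_and_gradient(self):
        z = np.array([0.0, 4.0, -4.0])
        y = np.array([1.0, 1.0, 0.0])
        loss, grad = nn.bce_with_logits(z, y)
        assert loss == pytest.approx(
            (np.log(2) + np.log1p(np.exp(-4)) + np.log1p(np.exp(-4))) / 3)
        np.testing.assert_allclose(grad, (nn.sigmoid(z) - y) / 3, rtol=1e-6)

    def test_nonfinite_loss_aborts_training(self):
        # a divergent optimizer step drives the next batch's loss non-finite
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 10, 250)).astype(np.float32)
        y = np.array(["healthy", "infested"] * 4)
        with pytest.raises(RuntimeError, match="non-finite"):
            ImageCNNClassifier(branch="spectral", epochs=2, batch_size=4,
                               learning_rate=np.inf, random_state=0).fit(x, y)
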