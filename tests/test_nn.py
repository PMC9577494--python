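import numpy as np
import pytest

import emofuse as ef
from emofuse.exceptions import InvalidParameterError, ShapeError
from emofuse.nn import (ArchitectureSpec, BatchNormState, BranchConfig,
                        ConvBlockSpec, MIDCNN, _softmax, small_architecture)


def conv_bruteforce(x, w, b, stride):
    """Nested-loop same-padding cross-correlation oracle; x (L, C), w (F, C, K)."""
    L, C = x.shape
    F, _, K = w.shape
    out_len = -(-L // stride)
    pad_total = max((out_len - 1) * stride + K - L, 0)
    left = pad_total // 2
    xp = np.zeros((L + pad_total, C))
    xp[left:left + L] = x
    out = np.zeros((out_len, F))
    for f in range(F):
        for j in range(out_len):
            acc = 0.0
            for c in range(C):
                for k in range(K):
                    acc += w[f, c, k] * xp[j * stride + k, c]
            out[j, f] = acc + b[f]
    return out


class TestConv:
    def test_identity_kernel(self):
        x = np.random.default_rng(0).normal(size=16)
        w = np.zeros(3)
        w[1] = 1.0
        assert np.allclose(ef.conv1d_forward(x, w, 0.0), x)

    def test_hand_convolution(self):
        out = ef.conv1d_forward(np.array([1.0, 2, 3, 4]), np.array([1.0, 1, 1]), 0.0)
        assert np.allclose(out, [3, 6, 9, 7])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        L, C, F, K = rng.integers(5, 20), rng.integers(1, 4), rng.integers(1, 5), rng.integers(1, 7)
        stride = int(rng.integers(1, 4))
        x = rng.normal(size=(L, C))
        w = rng.normal(size=(F, C, K))
        b = rng.normal(size=F)
        ours = ef.conv1d_forward(x, w, b, stride=stride)
        assert np.allclose(ours, conv_bruteforce(x, w, b, stride), atol=1e-12)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            ef.conv1d_forward(np.zeros((10, 2)), np.zeros((1, 3, 4)), np.zeros(1))


class TestRelu:
    def test_values(self):
        assert np.array_equal(ef.relu(np.array([-1.0, 0.0, 2.0])), [0, 0, 2])

    def test_all_negative(self):
        assert np.all(ef.relu(-np.ones(5)) == 0)

    def test_idempotent(self):
        x = np.random.default_rng(1).normal(size=50)
        assert np.array_equal(ef.relu(ef.relu(x)), ef.relu(x))


class TestBatchNorm:
    def test_standardization_contract(self):
        rng = np.random.default_rng(2)
        x = rng.normal(5.0, 3.0, size=(64, 10))
        st = BatchNormState.create(10)
        y = ef.batch_norm(x, st, training=True)
        assert np.allclose(y.mean(axis=0), 0.0, atol=1e-5)
        assert np.allclose(y.std(axis=0), 1.0, atol=1e-3)

    def test_constant_feature_guarded(self):
        x = np.full((32, 4), 7.0)
        st = BatchNormState.create(4)
        y = ef.batch_norm(x, st, training=True)
        assert np.allclose(y, 0.0)

    def test_affine_parameters(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(256, 3))
        st = BatchNormState.create(3)
        st.gamma[:] = 2.0
        st.beta[:] = 3.0
        y = ef.batch_norm(x, st, training=True)
        assert np.allclose(y.mean(axis=0), 3.0, atol=1e-6)
        assert np.allclose(y.std(axis=0), 2.0, atol=1e-2)

    def test_batch_of_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            ef.batch_norm(np.ones((1, 4)), BatchNormState.create(4), training=True)

    def test_inference_uses_running_statistics(self):
        st = BatchNormState.create(2)
        st.running_mean[:] = 10.0
        st.running_var[:] = 4.0
        y = ef.batch_norm(np.array([[12.0, 12.0], [8.0, 8.0]]), st, training=False)
        assert np.allclose(y, [[1.0, 1.0], [-1.0, -1.0]], atol=1e-3)


class TestPooling:
    def test_max_pool_values(self):
        assert np.allclose(ef.max_pool(np.array([1.0, 3, 2, 5]), 2), [3, 5])

    def test_constant_input(self):
        assert np.allclose(ef.max_pool(np.ones(8), 2), np.ones(4))

    def test_length_halves(self):
        x = np.random.default_rng(4).normal(size=(3, 20, 2))
        assert ef.max_pool(x, 2).shape == (3, 10, 2)

    def test_floor_semantics_drops_tail(self):
        assert ef.max_pool(np.arange(7.0), 2).shape == (3,)

    def test_gap_all_ones(self):
        x = np.ones((2, 5, 128))
        assert np.allclose(ef.global_average_pool(x), np.ones((2, 128)))

    def test_gap_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(4, 9, 6))
        expected = np.stack([[x[n, :, c].sum() / 9 for c in range(6)] for n in range(4)])
        assert np.allclose(ef.global_average_pool(x), expected, atol=1e-12)


class TestArchitecture:
    def test_default_concat_width(self):
        spec = ef.default_architecture()
        assert [b.gap_width for b in spec.branches] == [128, 32, 64]
        assert spec.concat_width == 224

    def test_single_branch_concat_width(self):
        spec = ef.default_architecture()
        single = ArchitectureSpec([spec.branches[1]])
        assert single.concat_width == 32

    def test_build_is_deterministic(self):
        m1 = ef.build_midcnn(small_architecture(), seed=3)
        m2 = ef.build_midcnn(small_architecture(), seed=3)
        p1 = m1.parameters()
        p2 = m2.parameters()
        assert len(p1) == len(p2)
        for (a, _), (b, _) in zip(p1, p2):
            assert np.array_equal(a, b)
        assert m1.n_parameters() > 0

    def test_too_short_input_reports_minimum(self):
        spec = ef.default_architecture()
        bad = BranchConfig("ecg", 3, spec.branches[0].blocks)
        with pytest.raises(InvalidParameterError, match="minimum"):
            MIDCNN(ArchitectureSpec([bad]))

    def test_gap_width_equals_last_block_filters(self):
        for b in ef.default_architecture().branches:
            assert b.gap_width == b.blocks[-1].filters

    def test_block_parameter_validation(self):
        with pytest.raises(InvalidParameterError):
            ConvBlockSpec(0, 3)


class TestSingleInputVariants:
    def test_single_modality_accepts_one_channel(self):
        spec = small_architecture()
        m = ef.build_single_input_dcnn(spec, ("ecg",), seed=0)
        x = np.zeros((4, spec.branches[0].input_length, 1))
        assert m.forward([x]).shape == (4, 2)

    def test_stacked_accepts_three_channels(self):
        spec = small_architecture()
        m = ef.build_single_input_dcnn(spec, ("ecg", "eda", "rsp"), seed=0)
        x = np.zeros((4, spec.branches[0].input_length, 3))
        assert m.forward([x]).shape == (4, 2)

    def test_stacked_first_layer_kernels_span_all_channels(self):
        spec = small_architecture()
        stacked = ef.build_single_input_dcnn(spec, ("ecg", "eda", "rsp"), seed=0)
        multi = ef.build_midcnn(spec, seed=0)
        w_stacked = stacked.branches[0][0].w
        assert w_stacked.shape[1] == 3  # shared filters see all three channels
        for layers in multi.branches:
            assert layers[0].w.shape[1] == 1  # per-branch filters see one channel


class TestTraining:
    def _toy_problem(self, n=60, L=32, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        x = rng.normal(0, 0.3, (n, L, 1)) + y[:, None, None] * 1.5
        spec = ArchitectureSpec([BranchConfig("x", L, [
            ConvBlockSpec(4, 5, (1, 1)), ConvBlockSpec(4, 5, (1, 1)),
            ConvBlockSpec(4, 3, (1, 1))])], fc_hidden=8)
        return spec, [x], y

    def test_loss_decreases_on_separable_data(self):
        spec, X, y = self._toy_problem()
        model = MIDCNN(spec, seed=1)
        hist = ef.train(model, X, y, epochs=10, batch_size=16, seed=0)
        first, last = np.mean(hist["loss"][:3]), np.mean(hist["loss"][-3:])
        assert last < first

    def test_training_is_deterministic(self):
        spec, X, y = self._toy_problem()
        h1 = ef.train(MIDCNN(spec, seed=2), X, y, epochs=3, batch_size=16, seed=0)
        h2 = ef.train(MIDCNN(spec, seed=2), X, y, epochs=3, batch_size=16, seed=0)
        assert h1["loss"] == h2["loss"]

    def test_gradients_match_finite_differences(self):
        spec = ArchitectureSpec([
            BranchConfig("a", 16, [ConvBlockSpec(3, 4, (2, 1)),
                                   ConvBlockSpec(2, 3, (1, 1)),
                                   ConvBlockSpec(2, 3, (1, 1))]),
        ], fc_hidden=5)
        m = MIDCNN(spec, seed=0)
        for layers in m.branches:
            for lay in layers:
                if hasattr(lay, "state"):
                    lay.state.momentum = 1.0  # freeze running stats for the check
        rng = np.random.default_rng(1)
        X = [rng.normal(size=(6, 16, 1))]
        y = rng.integers(0, 2, 6)
        onehot = np.eye(2)[y]

        def loss():
            probs = _softmax(m.forward(X, training=True))
            return -np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1))

        probs = _softmax(m.forward(X, training=True))
        m.backward((probs - onehot) / len(y))
        params = m.parameters()
        for pi in (0, 3, len(params) - 1):
            arr, g = params[pi]
            flat = arr.ravel()
            k = arr.size // 2
            eps, old = 1e-6, flat[k]
            flat[k] = old + eps
            lp = loss()
            flat[k] = old - eps
            lm = loss()
            flat[k] = old
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(g.ravel()[k], rel=1e-4, abs=1e-8)

    def test_mismatched_input_count_rejected(self):
        spec, X, y = self._toy_problem()
        model = MIDCNN(spec, seed=1)
        with pytest.raises(ShapeError):
            model.forward(X + X)
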