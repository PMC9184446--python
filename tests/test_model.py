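"""Network architecture: convolution semantics, causality, SE gating,
residual blocks, and the assembled predictor."""

import numpy as np
import pytest

from emdtcn import autodiff as ad
from emdtcn.autodiff import Tensor
from emdtcn.errors import ConfigurationError, ContractError
from emdtcn.model import (
    ModelConfig,
    SEnetTCN,
    build_model,
    causal_conv,
    dilated_conv,
    receptive_field,
)


def brute_force_causal(x, taps, d):
    """Direct double-loop evaluation of the dilated causal sum."""
    K = len(taps)
    out = np.zeros(len(x))
    for t in range(len(x)):
        for k in range(1, K + 1):  # 1-based tap index
            src = t - (K - k) * d
            if src >= 0:
                out[t] += taps[k - 1] * x[src]
    return out


class TestCausalConv:
    def test_identity_kernel(self):
        x = np.array([3.0, -1.0, 2.0, 7.0])
        assert np.array_equal(causal_conv(x, [1.0]), x)

    def test_delta_kernels(self):
        x = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(causal_conv(x, [0.0, 1.0]), x)
        assert np.array_equal(causal_conv(x, [1.0, 0.0]), [0.0, 1.0, 2.0])

    @pytest.mark.parametrize("K,d", [(3, 1), (3, 4), (5, 2), (2, 8), (7, 1)])
    def test_matches_brute_force(self, K, d):
        rng = np.random.default_rng(K * 10 + d)
        x = rng.standard_normal(64)
        taps = rng.standard_normal(K)
        got = causal_conv(x, taps, dilation=d)
        want = brute_force_causal(x, taps, d)
        assert np.allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_dilation_one_equals_plain_causal(self):
        rng = np.random.default_rng(0)
        x, taps = rng.standard_normal(32), rng.standard_normal(4)
        assert np.array_equal(dilated_conv(x, taps, 1), causal_conv(x, taps))

    def test_causality_future_perturbation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        taps = rng.standard_normal(3)
        base = causal_conv(x, taps, dilation=2)
        x2 = x.copy()
        x2[25] += 100.0
        pert = causal_conv(x2, taps, dilation=2)
        assert np.array_equal(base[:25], pert[:25])

    def test_invalid_dilation(self):
        with pytest.raises(ConfigurationError):
            causal_conv([1.0, 2.0], [1.0], dilation=0)


class TestReceptiveField:
    @pytest.mark.parametrize("K,dil", [(3, [1, 2, 4]), (3, [1, 2, 4, 8]), (5, [1, 2])])
    def test_formula_matches_impulse_tracing(self, K, dil):
        """1 + 2(K-1) * sum(d) for two convs per residual block, verified by
        brute-force dependency tracing on an impulse."""
        T = receptive_field(K, dil) + 10
        taps = np.ones(K)

        def block_stack(x):
            h = x
            for d in dil:
                h = brute(h, taps, d)
                h = brute(h, taps, d)
            return h

        def brute(x, taps, d):
            out = np.zeros(len(x))
            for t in range(len(x)):
                for k in range(K):
                    src = t - (K - 1 - k) * d
                    if src >= 0:
                        out[t] += taps[k] * x[src]
            return out

        x = np.zeros(T)
        x[0] = 1.0
        reach = np.flatnonzero(block_stack(x))
        span = reach.max() - 0 + 1
        assert span == receptive_field(K, dil)


class TestSEBlock:
    def _block(self, seed=0):
        model = build_model(ModelConfig(), 100, 10, seed=seed)
        return model, model._front[0][1]

    def test_gates_in_unit_interval(self):
        model, weights = self._block()
        rng = np.random.default_rng(0)
        fmap = Tensor(rng.standard_normal((2, 16, 8, 4)))
        out = model._se_block(fmap, weights)
        gates = out.data / np.where(fmap.data == 0, 1, fmap.data)
        gates = gates[fmap.data != 0]
        assert np.all(gates > 0) and np.all(gates < 1)

    def test_unit_gates_recover_identity(self):
        model, weights = self._block()
        w1, b1, w2, b2 = weights
        b2.data = np.full_like(b2.data, 1e9)   # sigmoid -> 1
        w2.data = np.zeros_like(w2.data)
        fmap = Tensor(np.random.default_rng(1).standard_normal((3, 16, 4, 2)))
        out = model._se_block(fmap, weights)
        assert np.allclose(out.data, fmap.data, rtol=1e-6)

    def test_squeeze_statistic_monotone_under_channel_scaling(self):
        """Doubling one channel's (positive) activations does not decrease
        its pooled squeeze statistic."""
        rng = np.random.default_rng(2)
        fmap = np.abs(rng.standard_normal((1, 16, 6, 3))) + 0.1
        squeeze1 = fmap.mean(axis=(2, 3))
        fmap2 = fmap.copy()
        fmap2[:, 5] *= 2.0
        squeeze2 = fmap2.mean(axis=(2, 3))
        assert squeeze2[0, 5] >= squeeze1[0, 5]
        assert np.allclose(np.delete(squeeze2, 5, 1), np.delete(squeeze1, 5, 1))


class TestResidualBlock:
    def test_zero_branch_with_matching_channels_is_relu_skip(self):
        model = build_model(ModelConfig(), 100, 10, seed=0)
        blk = model._blocks[1]  # channels already reconciled to tcn_filters
        assert "skip" not in blk
        for li in range(2):
            v, gain, bias = blk[f"conv{li}"]
            gain.data = np.zeros_like(gain.data)
            bias.data = np.zeros_like(bias.data)
        x = Tensor(np.random.default_rng(3).standard_normal((2, 32, 50)))
        out = model._residual_block(x, blk)
        assert np.allclose(out.data, np.maximum(x.data, 0.0), rtol=1e-6)

    def test_inference_is_dropout_free_and_deterministic(self):
        model = build_model(ModelConfig(dropout=0.5), 100, 10, seed=0)
        x = np.random.default_rng(4).standard_normal((4, 100, 10))
        a = model.predict(x)
        b = model.predict(x)
        assert np.array_equal(a, b)


class TestTcnCausality:
    def _tcn_out(self, model, seq):
        h = Tensor(seq)
        for blk in model._blocks:
            h = model._residual_block(h, blk)
        return h.data

    def test_future_perturbation_never_changes_past(self):
        """Bit-level causality across the full TCN stack on random tensors."""
        model = build_model(ModelConfig(), 100, 10, seed=0)
        C = model.bridge_channels
        rng = np.random.default_rng(5)
        for trial in range(20):
            T = int(rng.integers(10, 60))
            t_cut = int(rng.integers(1, T))
            seq = rng.standard_normal((1, C, T)).astype(np.float32)
            base = self._tcn_out(model, seq)
            pert = seq.copy()
            pert[:, :, t_cut:] += rng.standard_normal(
                (1, C, T - t_cut)
            ).astype(np.float32)
            out2 = self._tcn_out(model, pert)
            assert np.array_equal(base[:, :, :t_cut], out2[:, :, :t_cut])

    @pytest.mark.parametrize("T", [8, 32, 100, 512])
    def test_equal_length_mapping(self, T):
        model = build_model(ModelConfig(), 100, 10, seed=0)
        seq = np.random.default_rng(6).standard_normal(
            (1, model.bridge_channels, T)
        )
        assert self._tcn_out(model, seq).shape == (1, model.cfg.tcn_filters, T)


class TestBuildModel:
    def test_forward_smoke_contract(self):
        model = build_model(ModelConfig(), 100, 10, seed=0)
        out = model.forward(np.random.default_rng(0).standard_normal((5, 100, 10)))
        assert out.shape == (5, 1)
        assert np.all(np.isfinite(out.data))

    def test_raw_signal_variant_builds_with_width_one(self):
        cfg = ModelConfig(use_emd_features=False)
        model = build_model(cfg, 100, 1, seed=0)
        out = model.forward(np.random.default_rng(1).standard_normal((3, 100, 1)))
        assert out.shape == (3, 1)

    def test_same_seed_same_init_and_output(self):
        x = np.random.default_rng(2).standard_normal((4, 100, 10))
        a = build_model(ModelConfig(), 100, 10, seed=11)
        b = build_model(ModelConfig(), 100, 10, seed=11)
        assert all(
            np.array_equal(p.data, q.data)
            for p, q in zip(a.parameters, b.parameters)
        )
        assert np.array_equal(a.forward(x).data, b.forward(x).data)

    def test_incompatible_shapes_fail_at_build_time(self):
        with pytest.raises(ConfigurationError):
            build_model(ModelConfig(), 10, 10, seed=0)  # too short for 7x5 + pool
        with pytest.raises(ConfigurationError):
            build_model(ModelConfig(tcn_dilations=[3]), 100, 10, seed=0)
        with pytest.raises(ConfigurationError):
            build_model(ModelConfig(scale_kernels=[]), 100, 10, seed=0)

    def test_call_time_shape_mismatch_is_contract_error(self):
        model = build_model(ModelConfig(), 100, 10, seed=0)
        with pytest.raises(ContractError):
            model.forward(np.zeros((2, 80, 10)))

    def test_parameter_count_is_config_deterministic(self):
        a = build_model(ModelConfig(), 100, 10, seed=0)
        b = build_model(ModelConfig(), 100, 10, seed=99)
        assert a.n_parameters() == b.n_parameters()
        summary = a.summary()
        assert summary["n_parameters"] == a.n_parameters()
        assert summary["input_len"] == 100

    def test_state_dict_round_trip(self):
        a = build_model(ModelConfig(), 100, 10, seed=0)
        b = build_model(ModelConfig(), 100, 10, seed=1)
        b.load_state_dict(a.state_dict())
        x = np.random.default_rng(3).standard_normal((2, 100, 10))
        assert np.array_equal(a.forward(x).data, b.forward(x).data)


class TestCapacity:
    def test_overfits_small_window_set(self):
        """Learnability: the default architecture drives training MAE on 32
        windows below 1% of the signal amplitude."""
        from emdtcn.traineval import TrainConfig, train
        from emdtcn.preprocess import WindowSpec, WindowedDataset

        rng = np.random.default_rng(7)
        amp = 10.0
        X = rng.standard_normal((32, 100, 10))
        y = amp * rng.uniform(-1, 1, size=32)
        spec = WindowSpec(input_len=100, lead=10)
        ds = WindowedDataset(
            features=X, targets=y, end_indices=np.arange(32), spec=spec
        )
        ds._last_observed = y.copy()
        model = build_model(ModelConfig(dropout=0.0), 100, 10, seed=0)
        train(
            model, ds, ds,
            TrainConfig(epochs=500, batch_size=32, seed=0, early_stop=None),
        )
        mae = np.mean(np.abs(model.predict(X) - y))
        assert mae < 0.01 * amp
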