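"""GRU cell/forward equation fidelity, loss formula, and training behaviour."""

import numpy as np
import pytest

from fedecg.gru import (
    FitResult,
    GRUClassifier,
    GRUConfig,
    GRUParams,
    TrainConfig,
    forward,
    gru_cell_step,
    load_params,
    save_params,
    smoothed_cross_entropy,
    train_centralized,
)
from tests.conftest import TEST_MODEL, TEST_TRAIN, make_normalized_split


def scalar_gru_oracle(xs, layer_params):
    """Per-equation, scalar-by-scalar recomputation of the GRU recurrence."""
    import math

    W_z, U_z, b_z = layer_params["W_z"], layer_params["U_z"], layer_params["b_z"]
    W_r, U_r, b_r = layer_params["W_r"], layer_params["U_r"], layer_params["b_r"]
    W_h, U_h, b_h = layer_params["W_h"], layer_params["U_h"], layer_params["b_h"]
    H = W_z.shape[0]
    h = [0.0] * H
    for x in xs:
        z = [0.0] * H
        r = [0.0] * H
        hc = [0.0] * H
        for i in range(H):
            az = b_z[i] + sum(W_z[i, j] * x[j] for j in range(len(x)))
            az += sum(U_z[i, j] * h[j] for j in range(H))
            z[i] = 1.0 / (1.0 + math.exp(-az))
            ar = b_r[i] + sum(W_r[i, j] * x[j] for j in range(len(x)))
            ar += sum(U_r[i, j] * h[j] for j in range(H))
            r[i] = 1.0 / (1.0 + math.exp(-ar))
        for i in range(H):
            ah = b_h[i] + sum(W_h[i, j] * x[j] for j in range(len(x)))
            ah += sum(U_h[i, j] * r[j] * h[j] for j in range(H))
            hc[i] = math.tanh(ah)
        h = [(1.0 - z[i]) * h[i] + z[i] * hc[i] for i in range(H)]
    return np.array(h)


def _random_layer(rng, h, d):
    return {
        "W_z": rng.normal(size=(h, d)), "U_z": rng.normal(size=(h, h)), "b_z": rng.normal(size=h),
        "W_r": rng.normal(size=(h, d)), "U_r": rng.normal(size=(h, h)), "b_r": rng.normal(size=h),
        "W_h": rng.normal(size=(h, d)), "U_h": rng.normal(size=(h, h)), "b_h": rng.normal(size=h),
    }


class TestCell:
    def test_zero_params_give_half_gates(self):
        lp = {k: np.zeros((2, 3)) if k.startswith("W") else np.zeros((2, 2)) if k.startswith("U")
              else np.zeros(2) for k in ("W_z", "U_z", "b_z", "W_r", "U_r", "b_r", "W_h", "U_h", "b_h")}
        st = gru_cell_step(np.array([1.0, -2.0, 0.5]), np.zeros(2), lp)
        assert np.allclose(st.z, 0.5) and np.allclose(st.r, 0.5)
        assert np.allclose(st.h_candidate, 0.0) and np.allclose(st.h, 0.0)

    def test_closed_update_gate_keeps_previous_state(self, rng):
        lp = _random_layer(rng, 3, 2)
        lp["b_z"] = np.full(3, -1e6)  # z ~ 0 -> h_t = h_prev
        h_prev = rng.normal(size=3)
        st = gru_cell_step(rng.normal(size=2), h_prev, lp)
        assert np.allclose(st.h, h_prev, atol=1e-6)

    def test_matches_scalar_oracle_over_steps(self, rng):
        lp = _random_layer(rng, 3, 2)
        xs = rng.normal(size=(5, 2))
        h = np.zeros(3)
        for x in xs:
            h = gru_cell_step(x, h, lp).h
        assert np.allclose(h, scalar_gru_oracle(xs, lp), atol=1e-6)

    def test_gate_ranges(self, rng):
        for _ in range(20):
            lp = _random_layer(rng, 4, 3)
            st = gru_cell_step(rng.normal(size=3), rng.normal(size=4), lp)
            assert np.all((st.z >= 0) & (st.z <= 1))
            assert np.all((st.r >= 0) & (st.r <= 1))
            assert np.all((st.h_candidate >= -1) & (st.h_candidate <= 1))

    def test_dimension_mismatch_raises(self, rng):
        lp = _random_layer(rng, 3, 2)
        with pytest.raises(ValueError, match="mismatch"):
            gru_cell_step(np.zeros(5), np.zeros(3), lp)


class TestForward:
    def test_probabilities_sum_to_one(self, rng):
        params = GRUParams.init(GRUConfig(hidden_size=4, num_layers=2), seed=0)
        p = forward(rng.normal(size=(12, 20)), None, params)
        assert np.all(p >= 0) and abs(p.sum() - 1.0) < 1e-9

    def test_fusion_isolation_with_zeroed_feature_weights(self, rng):
        cfg = GRUConfig(hidden_size=4, num_layers=1, fusion=True)
        params = GRUParams.init(cfg, seed=1)
        params.arrays["head.W"][:, cfg.hidden_size:] = 0.0
        sig = rng.normal(size=(12, 15))
        p1 = forward(sig, np.zeros(13), params)
        p2 = forward(sig, rng.normal(size=13), params)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_missing_features_with_fusion_raises(self, rng):
        params = GRUParams.init(GRUConfig(hidden_size=4, num_layers=1, fusion=True), seed=0)
        with pytest.raises(ValueError, match="fusion"):
            forward(rng.normal(size=(12, 8)), None, params)

    def test_wrong_channel_count_raises(self, rng):
        params = GRUParams.init(GRUConfig(hidden_size=4, num_layers=1), seed=0)
        with pytest.raises(ValueError):
            forward(rng.normal(size=(11, 8)), None, params)

    def test_matches_stacked_scalar_oracle(self, rng):
        """12x8 input through 2 stacked layers equals the per-equation oracle."""
        cfg = GRUConfig(input_size=12, hidden_size=3, num_layers=2)
        params = GRUParams.init(cfg, seed=3)
        for k in params.arrays:
            params.arrays[k] = rng.normal(scale=0.5, size=params.arrays[k].shape)
        sig = rng.normal(size=(12, 8))
        xs = sig.T
        h1_seq = []
        h = np.zeros(3)
        lp0 = params.layer(0)
        for t in range(8):
            h = gru_cell_step(xs[t], h, lp0).h
            h1_seq.append(h)
        h_final = scalar_gru_oracle(np.array(h1_seq), params.layer(1))
        logits = params.arrays["head.W"] @ h_final + params.arrays["head.b"]
        expect = np.exp(logits - logits.max())
        expect /= expect.sum()
        assert np.allclose(forward(sig, None, params), expect, atol=1e-6)

    def test_head_class_permutation_equivariance(self, rng):
        params = GRUParams.init(GRUConfig(hidden_size=4, num_layers=1), seed=5)
        sig = rng.normal(size=(12, 10))
        p = forward(sig, None, params)
        perm = np.array([2, 0, 3, 1])
        permuted = GRUParams(params.config, {k: v.copy() for k, v in params.arrays.items()})
        permuted.arrays["head.W"] = params.arrays["head.W"][perm]
        permuted.arrays["head.b"] = params.arrays["head.b"][perm]
        assert np.allclose(forward(sig, None, permuted), p[perm], atol=1e-12)


class TestLoss:
    def test_one_hot_truth_zero_loss(self):
        assert smoothed_cross_entropy(np.array([1.0, 0, 0, 0]), "SB", 0.0) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("s", [0.0, 0.1, 0.2, 0.5])
    def test_uniform_probs_give_ln4(self, s):
        p = np.full(4, 0.25)
        assert smoothed_cross_entropy(p, "GSVT", s) == pytest.approx(np.log(4), abs=1e-9)

    def test_formula_oracle(self):
        p = np.array([0.7, 0.1, 0.1, 0.1])
        expect = -(0.85 * np.log(0.7) + 3 * 0.05 * np.log(0.1))
        assert smoothed_cross_entropy(p, "SB", 0.2) == pytest.approx(expect, abs=1e-9)

    def test_zero_probability_clamped_finite(self):
        p = np.array([1.0, 0.0, 0.0, 0.0])
        assert np.isfinite(smoothed_cross_entropy(p, "SR", 0.2))

    def test_invalid_smoothing(self):
        with pytest.raises(ValueError):
            smoothed_cross_entropy(np.full(4, 0.25), "SB", 1.0)


class TestTraining:
    def test_zero_epochs_leaves_params_unchanged(self, split_cache):
        split = split_cache(60, 3)
        params = GRUParams.init(TEST_MODEL, seed=0)
        trained, history = train_centralized(split, params, TEST_TRAIN, epochs=0, seed=0)
        assert trained == params and history == []

    def test_determinism(self, split_cache):
        split = split_cache(60, 3)
        clf = GRUClassifier(TEST_MODEL, TEST_TRAIN)
        a = clf.fit(split, epochs=2, seed=4)
        b = clf.fit(split, epochs=2, seed=4)
        assert a.params == b.params
        assert a.history == b.history

    def test_learns_separable_rate_coded_classes(self, split_cache):
        """Small separable experiment: >= 95% test accuracy within 30 epochs."""
        split = split_cache(200, 11)
        clf = GRUClassifier(TEST_MODEL, TEST_TRAIN)
        fit = clf.fit(split, epochs=30, seed=11, stop_at_accuracy=0.98)
        assert fit.evaluate(split.test).accuracy >= 0.95

    def test_loss_trend_non_increasing_within_tolerance(self, split_cache):
        split = split_cache(200, 11)
        clf = GRUClassifier(TEST_MODEL, TEST_TRAIN)
        fit = clf.fit(split, epochs=15, seed=11)
        losses = [h["train_loss"] for h in fit.history]
        assert all(b <= a + 0.05 for a, b in zip(losses, losses[1:]))

    def test_checkpoint_round_trip(self, tmp_path):
        params = GRUParams.init(GRUConfig(hidden_size=4, num_layers=2, fusion=True), seed=2)
        save_params(params, tmp_path / "ckpt.npz")
        back = load_params(tmp_path / "ckpt.npz")
        assert back == params and back.config == params.config
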