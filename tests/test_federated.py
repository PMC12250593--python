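"""Aggregation exactness, centralized reduction, and federated behaviour."""

import numpy as np
import pytest

from fedecg.data import partition_clients
from fedecg.dp import DPConfig
from fedecg.federated import (
    ClientState,
    fedavg_aggregate,
    local_train,
    personalize,
    run_federated,
)
from fedecg.gru import GRUConfig, GRUParams, TrainConfig, train_centralized
from tests.conftest import TEST_MODEL, TEST_TRAIN


@pytest.fixture(scope="module")
def small_split(split_cache):
    return split_cache(80, 21)


def _rand_params(cfg, seed):
    p = GRUParams.init(cfg, seed)
    rng = np.random.default_rng(seed + 1000)
    for k in p.arrays:
        p.arrays[k] = rng.normal(size=p.arrays[k].shape)
    return p


class TestAggregate:
    CFG = GRUConfig(hidden_size=3, num_layers=1)

    def test_identical_clients_preserved_exactly(self):
        w = _rand_params(self.CFG, 0)
        agg = fedavg_aggregate([w.copy(), w.copy(), w.copy()], [3, 7, 11])
        for k in w.arrays:
            assert np.array_equal(agg.arrays[k], w.arrays[k])

    def test_two_client_scalar_example(self):
        a, b = _rand_params(self.CFG, 1), _rand_params(self.CFG, 1)
        a.arrays["head.b"] = np.array([0.0, 0, 0, 0])
        b.arrays["head.b"] = np.array([4.0, 0, 0, 0])
        agg = fedavg_aggregate([a, b], [1, 3])
        assert agg.arrays["head.b"][0] == pytest.approx(3.0, abs=1e-12)

    def test_matches_weighted_mean_oracle(self):
        clients = [_rand_params(self.CFG, s) for s in range(5)]
        sizes = [3, 9, 1, 7, 5]
        agg = fedavg_aggregate(clients, sizes)
        total = sum(sizes)
        for k in clients[0].arrays:
            oracle = sum(n / total * c.arrays[k] for c, n in zip(clients, sizes))
            assert np.allclose(agg.arrays[k], oracle, atol=1e-12)

    def test_schema_mismatch_rejected(self):
        a = _rand_params(self.CFG, 0)
        b = _rand_params(GRUConfig(hidden_size=4, num_layers=1), 0)
        with pytest.raises(ValueError, match="schema"):
            fedavg_aggregate([a, b], [1, 1])

    def test_zero_total_size_rejected(self):
        a = _rand_params(self.CFG, 0)
        with pytest.raises(ValueError):
            fedavg_aggregate([a], [0])


class TestLocalTrain:
    def test_zero_epochs_returns_global_weights(self, small_split):
        client = ClientState(0, small_split.train)
        g = GRUParams.init(TEST_MODEL, seed=0)
        w, n = local_train(client, g, 0, TEST_TRAIN)
        assert w == g and n == len(small_split.train)

    def test_dp_identity_equals_no_dp(self, small_split):
        """sigma=0 with infinite clip is bit-compatible with plain training."""
        client = ClientState(0, small_split.train)
        g = GRUParams.init(TEST_MODEL, seed=0)
        w_plain, _ = local_train(client, g, 1, TEST_TRAIN, dp=None, seed=5)
        dp_off = DPConfig(clip_norm=np.inf, noise_multiplier=0.0)
        w_dp, _ = local_train(client, g, 1, TEST_TRAIN, dp=dp_off, seed=5)
        for k in w_plain.arrays:
            assert np.allclose(w_plain.arrays[k], w_dp.arrays[k], atol=1e-9)

    def test_single_client_matches_centralized(self, small_split):
        client = ClientState(0, small_split.train)
        g = GRUParams.init(TEST_MODEL, seed=3)
        w, _ = local_train(client, g, 3, TEST_TRAIN, seed=3)
        central, _ = train_centralized(small_split, g, TEST_TRAIN, epochs=3, seed=3)
        for k in w.arrays:
            assert np.allclose(w.arrays[k], central.arrays[k], atol=1e-9)

    def test_returns_only_weights_and_size(self, small_split):
        """Privacy plumbing: no record objects cross the client boundary."""
        client = ClientState(0, small_split.train)
        g = GRUParams.init(TEST_MODEL, seed=0)
        out = local_train(client, g, 1, TEST_TRAIN)
        assert isinstance(out, tuple) and len(out) == 2
        assert isinstance(out[0], GRUParams) and isinstance(out[1], int)
        record_ids = {id(r) for r in small_split.train}
        assert not any(id(v) in record_ids for v in out[0].arrays.values())


class TestPersonalize:
    def test_zero_epochs_identity(self, small_split):
        client = ClientState(0, small_split.train)
        g = GRUParams.init(TEST_MODEL, seed=0)
        assert personalize(client, g, 0, TEST_TRAIN) == g

    def test_fine_tuning_does_not_increase_local_loss(self, small_split):
        from fedecg.gru import _mean_loss

        tcfg = TrainConfig(batch_size=16, learning_rate=1e-3)
        deltas = []
        for seed in (1, 2, 3):
            client = ClientState(0, small_split.train)
            g, _ = train_centralized(small_split, GRUParams.init(TEST_MODEL, seed),
                                     tcfg, epochs=2, seed=seed)
            before = _mean_loss(g, client.records, tcfg.label_smoothing)
            p = personalize(client, g, 2, tcfg, seed=seed)
            after = _mean_loss(p, client.records, tcfg.label_smoothing)
            deltas.append(after - before)
        assert np.mean(deltas) <= 0.0


class TestRunFederated:
    def test_single_client_single_round_equals_centralized(self, small_split):
        from fedecg.data import ClientPartition

        init = GRUParams.init(TEST_MODEL, seed=9)
        # one client holding the full train split, in the same record order
        part = ClientPartition(clients=[list(small_split.train)])
        state = run_federated(
            small_split, part, E_g=1, E_l=2, train_cfg=TEST_TRAIN, seed=9,
            init_params=init, personalization="none", local_test_frac=0.0,
        )
        central, _ = train_centralized(small_split, init, TEST_TRAIN, epochs=2, seed=9)
        for k in central.arrays:
            assert np.allclose(state.params.arrays[k], central.arrays[k], atol=1e-9)

    def test_replayable_per_seed(self, small_split):
        part = partition_clients(small_split.train, 2, "iid", seed=0)
        kw = dict(E_g=2, E_l=1, train_cfg=TEST_TRAIN, seed=13, personalization="none")
        a = run_federated(small_split, part, **kw)
        b = run_federated(small_split, part, **kw)
        assert a.params == b.params
        assert a.history == b.history

    def test_history_records_schedule_and_accuracy(self, small_split):
        part = partition_clients(small_split.train, 2, "iid", seed=0)
        dp = DPConfig(clip_norm=1.0, noise_multiplier=0.2, schedule="linear_decay")
        state = run_federated(small_split, part, E_g=3, E_l=1, train_cfg=TEST_TRAIN,
                              dp=dp, seed=0, model_cfg=TEST_MODEL,
                              personalization="none")
        frame = state.history_frame()
        assert list(frame["round"]) == [1, 2, 3]
        assert frame["sigma_t"].is_monotonic_decreasing
        assert "global_test_accuracy" in frame

    def test_personalization_history_populated(self, small_split):
        part = partition_clients(small_split.train, 2, "iid", seed=0)
        state = run_federated(small_split, part, E_g=1, E_l=1, train_cfg=TEST_TRAIN,
                              seed=0, model_cfg=TEST_MODEL,
                              personalization="final", personalize_epochs=1)
        assert len(state.personalized) == 2
        cf = state.client_frame()
        assert {"personalized_local_accuracy", "global_local_accuracy"} <= set(cf.columns)
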