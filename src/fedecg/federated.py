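"""Federated training: global rounds, DP local updates, FedAvg, personalization.

One global round t:

1. the DP schedule resolves (sigma_t, C_t);
2. every client loads the global weights and runs E_l local epochs of
   (optionally DP-) mini-batch training on its own records;
3. the server aggregates the returned weights by the size-weighted mean

       theta_new = sum_i (N_i / sum_j N_j) * W_i        (FedAvg)

4. the global model is evaluated on the shared test set;
5. each client fine-tunes the fresh global model on its local data (plain,
   non-DP training) to produce its personalized model, evaluated on the
   client's local held-out records.

Only weight arrays and dataset sizes ever cross the client boundary; raw
records never leave the local-training call.  A master seed derives
per-(round, client) generators, so runs replay bit-identically and a
single-client, no-DP run reduces exactly to centralized training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ClientPartition, DatasetSplit
from .dp import DPConfig, schedule_step
from .gru import (
    GRUConfig,
    GRUParams,
    TrainConfig,
    _accuracy,
    _mean_loss,
    derive_rng,
    sgd_epochs,
)

__all__ = [
    "ClientState",
    "GlobalState",
    "local_train",
    "fedavg_aggregate",
    "personalize",
    "run_federated",
    "FederatedRunner",
]

_PERSONALIZE_STREAM = 10_000  # client-index offset keeping rng streams disjoint


@dataclass
class ClientState:
    """One simulated client (hospital): its id and local records."""

    client_id: int
    records: list

    def __post_init__(self):
        if not self.records:
            raise ValueError(f"client {self.client_id} has no records")

    @property
    def n(self) -> int:
        return len(self.records)


def local_train(
    client: ClientState,
    global_params: GRUParams,
    E_l: int,
    train_cfg: TrainConfig,
    dp: DPConfig | None = None,
    seed: int = 0,
    round_idx: int = 1,
    total_rounds: int = 1,
    loss_log: list | None = None,
) -> tuple[GRUParams, int]:
    """E_l local epochs starting from the global weights.

    Returns only the trained weights and the client's dataset size; records
    never leave this call.  With ``dp`` set, every batch gradient is clipped
    and noised per the schedule point (round_idx, total_rounds).
    """
    params = global_params.copy()
    rng = derive_rng(seed, round_idx, client.client_id)
    sgd_epochs(
        params,
        client.records,
        train_cfg,
        E_l,
        rng,
        dp=dp,
        dp_round=(round_idx, total_rounds),
        loss_log=loss_log,
    )
    return params, client.n


def fedavg_aggregate(weights: list[GRUParams], sizes: list[int]) -> GRUParams:
    """Size-weighted mean of client parameters, array by array.

    Computed as W_0 + sum_i w_i (W_i - W_0), the exact weighted mean in a
    form that preserves any array on which all clients agree bit-exactly.
    """
    if not weights:
        raise ValueError("need at least one client")
    if len(weights) != len(sizes):
        raise ValueError("weights and sizes must align")
    total = float(sum(sizes))
    if total <= 0:
        raise ValueError("total client size must be positive")
    keys = weights[0].arrays.keys()
    for w in weights[1:]:
        if w.arrays.keys() != keys or any(
            w.arrays[k].shape != weights[0].arrays[k].shape for k in keys
        ):
            raise ValueError("client parameter schemas do not match")
    factors = [n / total for n in sizes]
    out = weights[0].copy()
    for k in keys:
        base = weights[0].arrays[k]
        acc = np.zeros_like(base)
        for w, f in zip(weights, factors):
            delta = w.arrays[k] - base
            if np.any(delta):
                acc = acc + f * delta
        out.arrays[k] = base + acc
    return out


def personalize(
    client: ClientState,
    global_params: GRUParams,
    fine_tune_epochs: int,
    train_cfg: TrainConfig,
    seed: int = 0,
    round_idx: int = 1,
) -> GRUParams:
    """Plain (non-DP) local fine-tuning of the global model on client data."""
    params = global_params.copy()
    rng = derive_rng(seed, round_idx, _PERSONALIZE_STREAM + client.client_id)
    sgd_epochs(params, client.records, train_cfg, fine_tune_epochs, rng)
    return params


@dataclass
class GlobalState:
    """Results object of a federated run: final models, history, diagnostics."""

    params: GRUParams  # final global model
    personalized: dict[int, GRUParams]  # client_id -> personalized model
    history: list[dict]  # per-round global metrics + DP schedule values
    client_history: list[dict]  # per-(round, client) metrics
    rounds_run: int
    train_cfg: TrainConfig
    dp: DPConfig | None = None

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    def client_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.client_history)

    def evaluate(self, records):
        from .gru import forward
        from .metrics import evaluate_model

        return evaluate_model(lambda r: forward(r.signal, r.features, self.params), records)

    def summary(self) -> str:
        lines = [
            "Federated GRU run",
            f"  rounds={self.rounds_run} clients={len(self.personalized) or 'n/a'} "
            f"dp={'on' if self.dp else 'off'}",
        ]
        if self.history:
            last = self.history[-1]
            lines.append(
                "  final round: "
                + " ".join(
                    f"{k}={v:.4f}" if isinstance(v, float) else f"{k}={v}"
                    for k, v in last.items()
                )
            )
        return "\n".join(lines)


def _split_local(records, frac: float, rng) -> tuple[list, list]:
    """Per-client holdout used to score personalization; deterministic."""
    n = len(records)
    if n < 5 or frac <= 0:
        return list(records), []
    order = rng.permutation(n)
    n_test = max(1, int(round(frac * n)))
    test_idx = set(order[:n_test].tolist())
    train = [records[i] for i in range(n) if i not in test_idx]
    test = [records[i] for i in range(n) if i in test_idx]
    return train, test


def run_federated(
    split: DatasetSplit,
    partition: ClientPartition,
    E_g: int,
    E_l: int,
    train_cfg: TrainConfig,
    dp: DPConfig | None = None,
    seed: int = 0,
    model_cfg: GRUConfig | None = None,
    init_params: GRUParams | None = None,
    personalize_epochs: int = 1,
    personalization: str = "per_round",
    local_test_frac: float = 0.2,
    stop_at_accuracy: float | None = None,
) -> GlobalState:
    """Run the full federated algorithm and return its results object.

    ``personalization`` is "per_round" (fine-tune and score every round, as
    the round loop prescribes), "final" (only after the last round) or
    "none".  ``stop_at_accuracy`` stops the round loop early once the global
    test accuracy reaches that level.
    """
    if personalization not in ("per_round", "final", "none"):
        raise ValueError(f"unknown personalization mode {personalization!r}")
    model_cfg = model_cfg or (init_params.config if init_params is not None else GRUConfig())
    global_params = (
        init_params.copy() if init_params is not None else GRUParams.init(model_cfg, seed)
    )

    clients = []
    local_tests: dict[int, list] = {}
    for i, recs in enumerate(partition.clients):
        rng = derive_rng(seed, 0, i)
        train_recs, test_recs = _split_local(recs, local_test_frac, rng)
        clients.append(ClientState(client_id=i, records=train_recs))
        local_tests[i] = test_recs

    history: list[dict] = []
    client_history: list[dict] = []
    personalized: dict[int, GRUParams] = {}
    rounds_run = 0

    for t in range(1, int(E_g) + 1):
        rounds_run = t
        if dp is not None:
            sigma_t, clip_t = schedule_step(t, E_g, dp)
        else:
            sigma_t, clip_t = None, None

        results = []
        for client in clients:
            losses: list = []
            w_i, n_i = local_train(
                client,
                global_params,
                E_l,
                train_cfg,
                dp=dp,
                seed=seed,
                round_idx=t,
                total_rounds=E_g,
                loss_log=losses,
            )
            results.append((client.client_id, w_i, n_i, losses))

        sizes = [n for _, _, n, _ in results]
        factors = np.array(sizes, dtype=float) / sum(sizes)
        assert abs(factors.sum() - 1.0) <= 1e-12
        global_params = fedavg_aggregate([w for _, w, _, _ in results], sizes)

        row = {"round": t, "sigma_t": sigma_t, "clip_t": clip_t}
        if split.test:
            row["global_test_accuracy"] = _accuracy(global_params, split.test)
            row["global_test_loss"] = _mean_loss(
                global_params, split.test, train_cfg.label_smoothing
            )

        do_personalize = personalization == "per_round" or (
            personalization == "final" and t == E_g
        )
        if do_personalize:
            local_accs, global_accs = [], []
            for client in clients:
                p_i = personalize(
                    client, global_params, personalize_epochs, train_cfg, seed, round_idx=t
                )
                personalized[client.client_id] = p_i
                entry = {"round": t, "client": client.client_id, "n": client.n}
                if local_tests[client.client_id]:
                    lt = local_tests[client.client_id]
                    entry["personalized_local_accuracy"] = _accuracy(p_i, lt)
                    entry["global_local_accuracy"] = _accuracy(global_params, lt)
                    local_accs.append(entry["personalized_local_accuracy"])
                    global_accs.append(entry["global_local_accuracy"])
                if split.test:
                    entry["personalized_test_accuracy"] = _accuracy(p_i, split.test)
                client_history.append(entry)
            if local_accs:
                row["mean_personalized_local_accuracy"] = float(np.mean(local_accs))
                row["mean_global_local_accuracy"] = float(np.mean(global_accs))
        history.append(row)

        if (
            stop_at_accuracy is not None
            and row.get("global_test_accuracy", 0.0) >= stop_at_accuracy
        ):
            break

    return GlobalState(
        params=global_params,
        personalized=personalized,
        history=history,
        client_history=client_history,
        rounds_run=rounds_run,
        train_cfg=train_cfg,
        dp=dp,
    )


class FederatedRunner:
    """Model-style wrapper: configure once, ``fit`` a split + partition."""

    def __init__(
        self,
        model_cfg: GRUConfig | None = None,
        train_cfg: TrainConfig | None = None,
        dp: DPConfig | None = None,
        E_g: int = 10,
        E_l: int = 1,
        personalize_epochs: int = 1,
        personalization: str = "per_round",
    ):
        self.model_cfg = model_cfg or GRUConfig()
        self.train_cfg = train_cfg or TrainConfig()
        self.dp = dp
        self.E_g = E_g
        self.E_l = E_l
        self.personalize_epochs = personalize_epochs
        self.personalization = personalization

    def fit(self, split: DatasetSplit, partition: ClientPartition, seed: int = 0, **kw) -> GlobalState:
        return run_federated(
            split,
            partition,
            self.E_g,
            self.E_l,
            self.train_cfg,
            dp=self.dp,
            seed=seed,
            model_cfg=self.model_cfg,
            personalize_epochs=self.personalize_epochs,
            personalization=self.personalization,
            **kw,
        )
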