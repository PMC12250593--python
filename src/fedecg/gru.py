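"""From-scratch stacked GRU sequence classifier with clinical-feature fusion.

One GRU cell step, for input x_t and previous hidden state h_{t-1}:

    z_t = sigmoid(W_z x_t + U_z h_{t-1} + b_z)          (update gate)
    r_t = sigmoid(W_r x_t + U_r h_{t-1} + b_r)          (reset gate)
    hc_t = tanh(W_h x_t + U_h (r_t * h_{t-1}) + b_h)    (candidate state)
    h_t = (1 - z_t) * h_{t-1} + z_t * hc_t

The classifier stacks L such layers over the 12-lead sample sequence (each
time step's input is the 12 per-lead sample values), takes the last layer's
final hidden state, optionally concatenates the 13 normalized clinical
features (parallel feature fusion), and applies a linear head with softmax
over the 4 rhythm classes.  Training minimizes label-smoothed cross-entropy
with Adam or SGD; gradients come from full backpropagation through time.

Everything is plain numpy: parameters live in a name->array dict so that
federated aggregation and differential-privacy clipping can operate on flat
vectors with no framework involved.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .labels import CLASSES, N_CLASSES, label_index

__all__ = [
    "GRUConfig",
    "TrainConfig",
    "GRUParams",
    "GRUState",
    "gru_cell_step",
    "forward",
    "smoothed_cross_entropy",
    "train_centralized",
    "GRUClassifier",
    "FitResult",
    "flatten_grads",
    "unflatten_grads",
]

_PROB_FLOOR = 1e-12  # documented floor for log-probabilities in the loss


@dataclass(frozen=True)
class GRUConfig:
    """Architecture of the classifier.

    ``pool`` mean-pools the input sequence over non-overlapping windows of
    that many samples before the recurrence (1 = feed raw samples, the
    full-resolution configuration); it trades temporal resolution for speed.
    """

    input_size: int = 12
    hidden_size: int = 64
    num_layers: int = 5
    n_classes: int = N_CLASSES
    fusion: bool = False
    n_features: int = 13
    pool: int = 1

    @property
    def head_in(self) -> int:
        return self.hidden_size + (self.n_features if self.fusion else 0)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    weight_decay: float = 1e-5
    label_smoothing: float = 0.2
    batch_size: int = 64
    optimizer: str = "adam"  # "adam" or "sgd"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.label_smoothing < 1:
            raise ValueError("label_smoothing must be in [0, 1)")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


_GATE_NAMES = ("W_z", "U_z", "b_z", "W_r", "U_r", "b_r", "W_h", "U_h", "b_h")


class GRUParams:
    """Named parameter arrays: per-layer gate weights plus the fusion head.

    Array names are ``l{i}.{W_z,U_z,b_z,W_r,U_r,b_r,W_h,U_h,b_h}`` for layer
    i in [0, L) and ``head.W``, ``head.b``; this naming is the checkpoint
    contract used by federated aggregation.
    """

    def __init__(self, config: GRUConfig, arrays: dict[str, np.ndarray]):
        self.config = config
        self.arrays = arrays

    @classmethod
    def init(cls, config: GRUConfig, seed: int = 0) -> "GRUParams":
        """Uniform(+-1/sqrt(hidden)) initialization, deterministic per seed."""
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x1417]))
        bound = 1.0 / np.sqrt(config.hidden_size)
        arrays: dict[str, np.ndarray] = {}
        for layer in range(config.num_layers):
            in_dim = config.input_size if layer == 0 else config.hidden_size
            h = config.hidden_size
            for gate in ("z", "r", "h"):
                arrays[f"l{layer}.W_{gate}"] = rng.uniform(-bound, bound, (h, in_dim))
                arrays[f"l{layer}.U_{gate}"] = rng.uniform(-bound, bound, (h, h))
                arrays[f"l{layer}.b_{gate}"] = np.zeros(h)
        arrays["head.W"] = rng.uniform(-bound, bound, (config.n_classes, config.head_in))
        arrays["head.b"] = np.zeros(config.n_classes)
        return cls(config, arrays)

    def copy(self) -> "GRUParams":
        return GRUParams(self.config, {k: v.copy() for k, v in self.arrays.items()})

    def layer(self, i: int) -> dict[str, np.ndarray]:
        return {g: self.arrays[f"l{i}.{g}"] for g in _GATE_NAMES}

    def __eq__(self, other):
        return (
            isinstance(other, GRUParams)
            and self.arrays.keys() == other.arrays.keys()
            and all(np.array_equal(self.arrays[k], other.arrays[k]) for k in self.arrays)
        )


@dataclass
class GRUState:
    """Result of one cell step; gate vectors lie in their activation images."""

    h: np.ndarray
    z: np.ndarray
    r: np.ndarray
    h_candidate: np.ndarray


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def gru_cell_step(x_t: np.ndarray, h_prev: np.ndarray, layer_params: dict) -> GRUState:
    """One GRU step; works on single vectors or batches (leading axis)."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    W_z, U_z, b_z = layer_params["W_z"], layer_params["U_z"], layer_params["b_z"]
    if x_t.shape[-1] != W_z.shape[1] or h_prev.shape[-1] != U_z.shape[1]:
        raise ValueError(
            f"dimension mismatch: x_t {x_t.shape}, h_prev {h_prev.shape}, "
            f"W_z {W_z.shape}, U_z {U_z.shape}"
        )
    z = _sigmoid(x_t @ W_z.T + h_prev @ U_z.T + b_z)
    r = _sigmoid(x_t @ layer_params["W_r"].T + h_prev @ layer_params["U_r"].T + layer_params["b_r"])
    hc = np.tanh(
        x_t @ layer_params["W_h"].T + (r * h_prev) @ layer_params["U_h"].T + layer_params["b_h"]
    )
    h = (1.0 - z) * h_prev + z * hc
    return GRUState(h=h, z=z, r=r, h_candidate=hc)


def _pool_sequence(X: np.ndarray, pool: int) -> np.ndarray:
    """Mean-pool (B, T, C) over non-overlapping windows of ``pool`` steps."""
    if pool <= 1:
        return X
    B, T, C = X.shape
    T2 = T // pool
    return X[:, : T2 * pool].reshape(B, T2, pool, C).mean(axis=2)


def _forward_batch(params: GRUParams, X: np.ndarray, F: np.ndarray | None, with_cache: bool):
    """Stacked-GRU forward over a batch.

    X : (B, T, 12) raw sequences, F : (B, 13) normalized features or None.
    Returns (probs, logits, cache).
    """
    cfg = params.config
    if X.shape[2] != cfg.input_size:
        raise ValueError(f"expected {cfg.input_size} input channels, got {X.shape[2]}")
    if cfg.fusion and F is None:
        raise ValueError("fusion is enabled but no feature vectors were given")
    X = _pool_sequence(X, cfg.pool)
    B, T, _ = X.shape
    H = cfg.hidden_size

    layer_in = X
    cache_layers = []
    for layer in range(cfg.num_layers):
        lp = params.layer(layer)
        h = np.zeros((B, H))
        hs = np.empty((B, T, H))
        steps = [] if with_cache else None
        for t in range(T):
            st = gru_cell_step(layer_in[:, t], h, lp)
            h = st.h
            hs[:, t] = h
            if with_cache:
                steps.append(st)
        if with_cache:
            cache_layers.append({"input": layer_in, "steps": steps, "hs": hs})
        layer_in = hs

    h_last = layer_in[:, -1]
    head_in = np.concatenate([h_last, F], axis=1) if cfg.fusion else h_last
    logits = head_in @ params.arrays["head.W"].T + params.arrays["head.b"]
    probs = _softmax(logits)
    cache = {"layers": cache_layers, "head_in": head_in, "probs": probs, "T": T, "B": B}
    return probs, logits, (cache if with_cache else None)


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def forward(signal: np.ndarray, features, params: GRUParams) -> np.ndarray:
    """Class probability vector (length 4) for one 12 x d record signal."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2 or signal.shape[0] != params.config.input_size:
        raise ValueError(f"expected a {params.config.input_size} x d signal, got {signal.shape}")
    X = signal.T[None, :, :]
    F = None
    if params.config.fusion:
        if features is None:
            raise ValueError("fusion is enabled but no feature vector was given")
        F = np.asarray(
            features.to_array() if hasattr(features, "to_array") else features, dtype=float
        )[None, :]
    probs, _, _ = _forward_batch(params, X, F, with_cache=False)
    return probs[0]


def smoothed_cross_entropy(probs: np.ndarray, label, smoothing: float = 0.2) -> float:
    """Label-smoothed cross-entropy of a probability vector against a label.

    Target distribution q_k = (1 - s) [k == y] + s / K; probabilities are
    floored at 1e-12 inside the log so degenerate inputs stay finite.
    """
    if not 0 <= smoothing < 1:
        raise ValueError("smoothing must be in [0, 1)")
    probs = np.asarray(probs, dtype=float)
    y = label_index(label) if isinstance(label, str) else int(label)
    K = probs.shape[-1]
    q = np.full(K, smoothing / K)
    q[y] += 1.0 - smoothing
    return float(-(q * np.log(np.maximum(probs, _PROB_FLOOR))).sum())


def _loss_and_dlogits(probs: np.ndarray, y_idx: np.ndarray, smoothing: float):
    """Mean smoothed CE over the batch and its gradient w.r.t. the logits."""
    B, K = probs.shape
    q = np.full((B, K), smoothing / K)
    q[np.arange(B), y_idx] += 1.0 - smoothing
    loss = float(-(q * np.log(np.maximum(probs, _PROB_FLOOR))).sum() / B)
    dlogits = (probs - q) / B
    return loss, dlogits


def _backward_batch(params: GRUParams, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
    """Full BPTT through the head and every stacked layer."""
    cfg = params.config
    grads = {k: np.zeros_like(v) for k, v in params.arrays.items()}
    head_in = cache["head_in"]
    grads["head.W"] = dlogits.T @ head_in
    grads["head.b"] = dlogits.sum(axis=0)
    dhead_in = dlogits @ params.arrays["head.W"]
    H = cfg.hidden_size
    T = cache["T"]
    B = cache["B"]

    # Gradient arriving at the top layer's hidden sequence: only the final step.
    d_hs_top = np.zeros((B, T, H))
    d_hs_top[:, -1] = dhead_in[:, :H]

    d_hs = d_hs_top
    for layer in reversed(range(cfg.num_layers)):
        lp = params.layer(layer)
        lc = cache["layers"][layer]
        layer_in, steps, hs = lc["input"], lc["steps"], lc["hs"]
        d_input = np.zeros_like(layer_in)
        dh = np.zeros((B, H))
        for t in reversed(range(T)):
            dh = dh + d_hs[:, t]
            st = steps[t]
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H))
            x_t = layer_in[:, t]
            z, r, hc = st.z, st.r, st.h_candidate

            dhc = dh * z
            dz = dh * (hc - h_prev)
            dh_prev = dh * (1.0 - z)

            da_c = dhc * (1.0 - hc**2)
            grads[f"l{layer}.W_h"] += da_c.T @ x_t
            grads[f"l{layer}.U_h"] += da_c.T @ (r * h_prev)
            grads[f"l{layer}.b_h"] += da_c.sum(axis=0)
            d_rh = da_c @ lp["U_h"]
            dr = d_rh * h_prev
            dh_prev += d_rh * r

            da_z = dz * z * (1.0 - z)
            grads[f"l{layer}.W_z"] += da_z.T @ x_t
            grads[f"l{layer}.U_z"] += da_z.T @ h_prev
            grads[f"l{layer}.b_z"] += da_z.sum(axis=0)
            dh_prev += da_z @ lp["U_z"]

            da_r = dr * r * (1.0 - r)
            grads[f"l{layer}.W_r"] += da_r.T @ x_t
            grads[f"l{layer}.U_r"] += da_r.T @ h_prev
            grads[f"l{layer}.b_r"] += da_r.sum(axis=0)
            dh_prev += da_r @ lp["U_r"]

            d_input[:, t] = da_z @ lp["W_z"] + da_r @ lp["W_r"] + da_c @ lp["W_h"]
            dh = dh_prev
        d_hs = d_input  # becomes the hidden-sequence gradient of the layer below

    return grads


def flatten_grads(grads: dict[str, np.ndarray]) -> tuple[np.ndarray, list]:
    """Concatenate named arrays (sorted by name) into one flat vector."""
    names = sorted(grads)
    flat = np.concatenate([grads[n].ravel() for n in names])
    layout = [(n, grads[n].shape) for n in names]
    return flat, layout


def unflatten_grads(flat: np.ndarray, layout: list) -> dict[str, np.ndarray]:
    out = {}
    pos = 0
    for name, shape in layout:
        size = int(np.prod(shape))
        out[name] = flat[pos : pos + size].reshape(shape)
        pos += size
    return out


class _Optimizer:
    """Adam (torch-style L2 weight decay folded into the gradient) or SGD."""

    def __init__(self, params: GRUParams, cfg: TrainConfig):
        self.cfg = cfg
        self.t = 0
        if cfg.optimizer == "adam":
            self.m = {k: np.zeros_like(v) for k, v in params.arrays.items()}
            self.v = {k: np.zeros_like(v) for k, v in params.arrays.items()}

    def step(self, params: GRUParams, grads: dict[str, np.ndarray]):
        lr, wd = self.cfg.learning_rate, self.cfg.weight_decay
        if self.cfg.optimizer == "sgd":
            for k, p in params.arrays.items():
                p -= lr * (grads[k] + wd * p)
            return
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, p in params.arrays.items():
            g = grads[k] + wd * p
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


def stack_records(records, fusion: bool):
    """Records -> (X (B,T,12), F (B,13) or None, y (B,) class indices)."""
    X = np.stack([r.signal.T for r in records])
    F = np.stack([r.features.to_array() for r in records]) if fusion else None
    y = np.array([label_index(r.label) for r in records])
    return X, F, y


def derive_rng(seed: int, round_idx: int, client_idx: int) -> np.random.Generator:
    """Per-(round, client) generator; round 1 / client 0 is the centralized stream."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, int(round_idx), int(client_idx)])
    )


def sgd_epochs(
    params: GRUParams,
    records,
    train_cfg: TrainConfig,
    epochs: int,
    rng: np.random.Generator,
    dp=None,
    dp_round: tuple[int, int] | None = None,
    loss_log: list | None = None,
    optimizer: "_Optimizer | None" = None,
):
    """Run ``epochs`` of mini-batch training in place on ``params``.

    ``dp`` is an optional DPConfig: per batch the flattened loss gradient is
    L2-clipped and Gaussian noise is added before the optimizer update
    (weight decay, being data-independent, is applied after the mechanism).
    ``dp_round`` = (round_index, total_rounds) selects the DP schedule point.
    """
    from . import dp as dp_mod  # local import to avoid a cycle

    cfg = params.config
    X, F, y = stack_records(records, cfg.fusion)
    n = len(records)
    opt = optimizer if optimizer is not None else _Optimizer(params, train_cfg)
    if dp is not None:
        sigma_t, clip_t = dp_mod.schedule_step(*(dp_round or (1, 1)), dp)
        noise_std = dp_mod.noise_std(dp, sigma_t, clip_t)

    for _ in range(int(epochs)):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            probs, _, cache = _forward_batch(
                params, X[idx], None if F is None else F[idx], with_cache=True
            )
            loss, dlogits = _loss_and_dlogits(probs, y[idx], train_cfg.label_smoothing)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss {loss} on a batch of {len(idx)}"
                )
            grads = _backward_batch(params, cache, dlogits)
            if dp is not None:
                flat, layout = flatten_grads(grads)
                flat = dp_mod.clip_gradient(flat, clip_t)
                flat = dp_mod.add_gaussian_noise(flat, noise_std, rng)
                grads = unflatten_grads(flat, layout)
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
        if loss_log is not None:
            loss_log.append(epoch_loss / n)
    return params


def _accuracy(params: GRUParams, records) -> float:
    X, F, y = stack_records(records, params.config.fusion)
    probs, _, _ = _forward_batch(params, X, F, with_cache=False)
    return float((probs.argmax(axis=1) == y).mean())


def _mean_loss(params: GRUParams, records, smoothing: float) -> float:
    X, F, y = stack_records(records, params.config.fusion)
    probs, _, _ = _forward_batch(params, X, F, with_cache=False)
    loss, _ = _loss_and_dlogits(probs, y, smoothing)
    return loss


def train_centralized(
    split,
    params: GRUParams,
    cfg: TrainConfig,
    epochs: int,
    seed: int = 0,
    stop_at_accuracy: float | None = None,
):
    """Centralized training on split.train with per-epoch validation logging.

    Returns (trained params, history) where history is a list of per-epoch
    dicts.  ``stop_at_accuracy`` optionally stops early once the validation
    (or train, if no validation records) accuracy reaches that level.
    """
    if not split.train:
        raise ValueError("train split is empty")
    params = params.copy()
    rng = derive_rng(seed, 1, 0)
    opt = _Optimizer(params, cfg)  # optimizer state persists across epochs
    history = []
    for epoch in range(int(epochs)):
        losses: list = []
        sgd_epochs(params, split.train, cfg, 1, rng, loss_log=losses, optimizer=opt)
        entry = {
            "epoch": epoch + 1,
            "train_loss": losses[0],
            "train_accuracy": _accuracy(params, split.train),
        }
        if split.validation:
            entry["val_loss"] = _mean_loss(params, split.validation, cfg.label_smoothing)
            entry["val_accuracy"] = _accuracy(params, split.validation)
        history.append(entry)
        if stop_at_accuracy is not None:
            monitor = entry.get("val_accuracy", entry["train_accuracy"])
            if monitor >= stop_at_accuracy:
                break
    return params, history


@dataclass
class FitResult:
    """Trained parameters plus the training history and diagnostics."""

    params: GRUParams
    history: list[dict]
    train_cfg: TrainConfig

    def predict_proba(self, records) -> np.ndarray:
        X, F, _ = stack_records(records, self.params.config.fusion)
        probs, _, _ = _forward_batch(self.params, X, F, with_cache=False)
        return probs

    def predict(self, records) -> list[str]:
        return [CLASSES[i] for i in self.predict_proba(records).argmax(axis=1)]

    def evaluate(self, records):
        from .metrics import evaluate_model

        return evaluate_model(lambda r: forward(r.signal, r.features, self.params), records)

    def summary(self) -> str:
        cfg = self.params.config
        lines = [
            "GRU sequence classifier fit",
            f"  hidden={cfg.hidden_size} layers={cfg.num_layers} "
            f"fusion={cfg.fusion} pool={cfg.pool}",
            f"  optimizer={self.train_cfg.optimizer} lr={self.train_cfg.learning_rate} "
            f"weight_decay={self.train_cfg.weight_decay} "
            f"label_smoothing={self.train_cfg.label_smoothing}",
            f"  epochs run: {len(self.history)}",
        ]
        if self.history:
            last = self.history[-1]
            lines.append(
                "  final: "
                + " ".join(f"{k}={v:.4f}" for k, v in last.items() if k != "epoch")
            )
        return "\n".join(lines)


CHECKPOINT_VERSION = 1


def save_params(params: GRUParams, path) -> None:
    """Single-archive checkpoint: named arrays + architecture + version tag."""
    import json

    meta = {
        "version": CHECKPOINT_VERSION,
        "config": {
            "input_size": params.config.input_size,
            "hidden_size": params.config.hidden_size,
            "num_layers": params.config.num_layers,
            "n_classes": params.config.n_classes,
            "fusion": params.config.fusion,
            "n_features": params.config.n_features,
            "pool": params.config.pool,
        },
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **params.arrays)


def load_params(path) -> GRUParams:
    import json

    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
    return GRUParams(GRUConfig(**meta["config"]), arrays)


class GRUClassifier:
    """Model object built from an architecture + training configuration.

    ``fit(split, epochs, seed)`` trains centralized and returns a
    :class:`FitResult`; federated training lives in :mod:`fedecg.federated`.
    """

    def __init__(self, config: GRUConfig | None = None, train_cfg: TrainConfig | None = None):
        self.config = config or GRUConfig()
        self.train_cfg = train_cfg or TrainConfig()

    def init_params(self, seed: int = 0) -> GRUParams:
        return GRUParams.init(self.config, seed)

    def fit(
        self,
        split,
        epochs: int = 30,
        seed: int = 0,
        params: GRUParams | None = None,
        stop_at_accuracy: float | None = None,
    ) -> FitResult:
        params = params if params is not None else self.init_params(seed)
        trained, history = train_centralized(
            split, params, self.train_cfg, epochs, seed, stop_at_accuracy
        )
        return FitResult(params=trained, history=history, train_cfg=self.train_cfg)
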