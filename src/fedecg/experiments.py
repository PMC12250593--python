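"""The four-scenario experiment harness.

Scenario 1: centralized GRU on raw 12-lead sequences, no feature fusion
            (preset: hidden 64, 5 layers, lr 0.001).
Scenario 2: centralized GRU with parallel fusion of the 13 clinical features
            (preset: hidden 48, 5 layers).
Scenario 3: scenario-2 model trained federatedly with size-weighted FedAvg.
Scenario 4: scenario 3 plus the differential-privacy gradient mechanism and
            per-client personalization.

Every run writes its resolved configuration, per-epoch/per-round history and
final metrics report to its output directory, so a run folder replays
bit-identically from config + seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import normalize_features, partition_clients, read_records, split_dataset
from .dp import DPConfig
from .federated import run_federated
from .gru import GRUClassifier, GRUConfig, TrainConfig, save_params
from .metrics import MetricsReport
from .preprocess import FilterConfig, preprocess_record
from .synthetic import NoiseSpec, generate_dataset

__all__ = [
    "DataBlock",
    "FederatedBlock",
    "DPBlock",
    "ScenarioConfig",
    "scenario_preset",
    "run_scenario",
    "compare_scenarios",
    "ScenarioResult",
]

logger = logging.getLogger(__name__)

#: hidden size, GRU layers, fusion per scenario
_PRESETS = {
    1: {"hidden_size": 64, "num_layers": 5, "fusion": False},
    2: {"hidden_size": 48, "num_layers": 5, "fusion": True},
    3: {"hidden_size": 48, "num_layers": 5, "fusion": True},
    4: {"hidden_size": 48, "num_layers": 5, "fusion": True},
}


@dataclass
class DataBlock:
    """Synthetic generation settings, or a path to a stored dataset directory."""

    path: str | None = None
    n_records: int = 400
    proportions: tuple = (0.25, 0.25, 0.25, 0.25)
    fs: float = 500.0
    duration: float = 10.0
    powerline_amp: float = 0.0
    baseline_amp: float = 0.0
    white_sigma: float = 0.0
    preprocess: bool = False
    cutoff_hz: float = 50.0


@dataclass
class FederatedBlock:
    n_clients: int = 4
    E_g: int = 10
    E_l: int = 1
    strategy: str = "iid"
    alpha: float = 0.5
    personalize_epochs: int = 1
    personalization: str = "per_round"


@dataclass
class DPBlock:
    epsilon: float = 1.0
    clip_norm: float = 1.0
    noise_multiplier: float = 0.5
    schedule: str = "constant"
    noise_convention: str = "multiplier"


@dataclass
class ScenarioConfig:
    scenario: int = 1
    hidden_size: int | None = None  # None -> scenario preset
    num_layers: int | None = None
    fusion: bool | None = None
    pool: int = 1
    learning_rate: float = 0.001
    weight_decay: float = 1e-5
    label_smoothing: float = 0.2
    batch_size: int = 64
    optimizer: str = "adam"
    epochs: int = 30  # centralized scenarios
    data: DataBlock = field(default_factory=DataBlock)
    federated: FederatedBlock | None = None
    dp: DPBlock | None = None
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if self.scenario not in (1, 2, 3, 4):
            raise ValueError(f"scenario must be 1-4, got {self.scenario}")
        if self.scenario in (1, 2):
            if self.federated is not None:
                raise ValueError(f"scenario {self.scenario} must not have a federated block")
            if self.dp is not None:
                raise ValueError(f"scenario {self.scenario} must not have a dp block")
        if self.scenario == 3:
            if self.dp is not None:
                raise ValueError("scenario 3 must not have a dp block")
            if self.federated is None:
                self.federated = FederatedBlock()
        if self.scenario == 4:
            if self.federated is None:
                self.federated = FederatedBlock()
            if self.dp is None:
                self.dp = DPBlock()
        preset = _PRESETS[self.scenario]
        if self.hidden_size is None:
            self.hidden_size = preset["hidden_size"]
        if self.num_layers is None:
            self.num_layers = preset["num_layers"]
        if self.fusion is None:
            self.fusion = preset["fusion"]

    def model_config(self) -> GRUConfig:
        return GRUConfig(
            hidden_size=self.hidden_size,
            num_layers=self.num_layers,
            fusion=self.fusion,
            pool=self.pool,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            label_smoothing=self.label_smoothing,
            batch_size=self.batch_size,
            optimizer=self.optimizer,
        )

    def dp_config(self) -> DPConfig | None:
        if self.dp is None:
            return None
        return DPConfig(
            epsilon=self.dp.epsilon,
            clip_norm=self.dp.clip_norm,
            noise_multiplier=self.dp.noise_multiplier,
            schedule=self.dp.schedule,
            noise_convention=self.dp.noise_convention,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if d.get("data") is not None and isinstance(d["data"], dict):
            d["data"] = DataBlock(**d["data"])
        if d.get("federated") is not None and isinstance(d["federated"], dict):
            d["federated"] = FederatedBlock(**d["federated"])
        if d.get("dp") is not None and isinstance(d["dp"], dict):
            d["dp"] = DPBlock(**d["dp"])
        return cls(**d)


def scenario_preset(scenario: int, **overrides) -> ScenarioConfig:
    """The named preset for a scenario, with keyword overrides."""
    return ScenarioConfig(scenario=scenario, **overrides)


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    report: MetricsReport
    history: pd.DataFrame
    outdir: Path | None


def _load_data(cfg: ScenarioConfig):
    d = cfg.data
    if d.path:
        records = read_records(d.path)
    else:
        noise = NoiseSpec(d.powerline_amp, d.baseline_amp, d.white_sigma)
        records = generate_dataset(
            d.n_records, tuple(d.proportions), seed=cfg.seed, fs=d.fs,
            duration=d.duration, noise=noise,
        )
    if d.preprocess:
        fcfg = FilterConfig(cutoff_hz=d.cutoff_hz)
        records = [preprocess_record(r, fcfg) for r in records]
    return records


def run_scenario(cfg: ScenarioConfig) -> ScenarioResult:
    """Dispatch to centralized (1-2), FedAvg (3) or DP-federated (4) training."""
    records = _load_data(cfg)
    split = split_dataset(records, seed=cfg.seed)
    split, _stats = normalize_features(split)
    model_cfg = cfg.model_config()
    train_cfg = cfg.train_config()

    if cfg.scenario in (1, 2):
        clf = GRUClassifier(model_cfg, train_cfg)
        fit = clf.fit(split, epochs=cfg.epochs, seed=cfg.seed)
        report = fit.evaluate(split.test)
        history = pd.DataFrame(fit.history)
        final_params = fit.params
    else:
        fed = cfg.federated
        partition = partition_clients(
            split.train, fed.n_clients, strategy=fed.strategy, alpha=fed.alpha, seed=cfg.seed
        )
        state = run_federated(
            split,
            partition,
            fed.E_g,
            fed.E_l,
            train_cfg,
            dp=cfg.dp_config(),
            seed=cfg.seed,
            model_cfg=model_cfg,
            personalize_epochs=fed.personalize_epochs,
            personalization=fed.personalization,
        )
        report = state.evaluate(split.test)
        history = state.history_frame()
        final_params = state.params

    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(_yaml_safe(cfg.to_dict()), fh, sort_keys=False)
        history.to_csv(outdir / "history.csv", index=False)
        frame = report.to_frame()
        frame.to_csv(outdir / "report.csv")
        with open(outdir / "report.txt", "w") as fh:
            fh.write(report.summary() + "\n")
        save_params(final_params, outdir / "checkpoint.npz")
        logger.info("scenario %d artifacts written to %s", cfg.scenario, outdir)
    return ScenarioResult(config=cfg, report=report, history=history, outdir=outdir)


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def compare_scenarios(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Tabulate per-class sensitivity and aggregate metrics across scenarios.

    Rows: the 4 classes (per-class accuracy, i.e. sensitivity) followed by
    overall accuracy, kappa and MCC.  With >= 2 reports a ``diff`` column
    gives the max-minus-min spread per row.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    class_sets = [tuple(r.per_class.keys()) for r in reports.values()]
    if len(set(class_sets)) != 1:
        raise ValueError("reports have mismatched class sets")
    classes = class_sets[0]
    table = {}
    for name, rep in reports.items():
        col = {cls: rep.per_class[cls]["sensitivity"] for cls in classes}
        col["accuracy"] = rep.accuracy
        col["kappa"] = rep.kappa
        col["mcc"] = rep.mcc
        table[name] = col
    df = pd.DataFrame(table)
    df["diff"] = df.max(axis=1) - df.min(axis=1)
    return df
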