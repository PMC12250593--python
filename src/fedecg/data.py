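"""Record I/O, splitting, feature normalization and federated client partitioning.

Storage dialect: a dataset directory holds ``manifest.csv`` (one row per
record: id, label, fs, demographic columns and the 13 clinical features, plus
the relative path of the record's signal file) and a ``signals/`` folder with
one CSV per record, 12 columns (one per lead) and one row per sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .labels import CLASSES
from .synthetic import FEATURE_NAMES, ECGRecord, FeatureVector

__all__ = [
    "DatasetSplit",
    "ClientPartition",
    "FeatureStats",
    "split_dataset",
    "partition_clients",
    "normalize_features",
    "write_records",
    "read_records",
]

MANIFEST_COLUMNS = (
    ["record_id", "label", "fs", "duration", "sex"]
    + list(FEATURE_NAMES)
    + ["signal_path"]
)


@dataclass
class DatasetSplit:
    """Disjoint train / validation / test record lists."""

    train: list[ECGRecord]
    validation: list[ECGRecord]
    test: list[ECGRecord]
    fractions: tuple[float, float, float] = (0.75, 0.10, 0.15)

    def __iter__(self):
        yield from (self.train, self.validation, self.test)

    @property
    def n(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


@dataclass
class ClientPartition:
    """A disjoint cover of the training records across simulated clients."""

    clients: list[list[ECGRecord]]
    strategy: str = "iid"
    alpha: float | None = None

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clients]


@dataclass
class FeatureStats:
    """Train-split mean/std of the 13 features, reusable at inference."""

    mean: np.ndarray
    std: np.ndarray

    def transform(self, features: FeatureVector) -> FeatureVector:
        x = features.to_array()
        z = np.where(self.std > 0, (x - self.mean) / np.where(self.std > 0, self.std, 1.0), 0.0)
        return FeatureVector.from_array(z)

    def inverse(self, features: FeatureVector) -> FeatureVector:
        z = features.to_array()
        return FeatureVector.from_array(z * self.std + self.mean)


def split_dataset(
    records: list[ECGRecord],
    fractions: tuple[float, float, float] = (0.75, 0.10, 0.15),
    seed: int = 0,
) -> DatasetSplit:
    """Stratified train/validation/test split with the given fractions."""
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {sum(fractions)}")
    n = len(records)
    if n < 4:
        raise ValueError("need at least 4 records to split")
    labels = [r.label for r in records]
    counts = pd.Series(labels).value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"classes with fewer records than split bins: {small}")

    sizes = _largest_remainder(n, np.asarray(fractions))  # train/val/test counts
    rest, test = train_test_split(
        records, test_size=int(sizes[2]), stratify=labels,
        random_state=int(seed) & 0x7FFFFFFF,
    )
    rest_labels = [r.label for r in rest]
    train, val = train_test_split(
        rest, test_size=int(sizes[1]), stratify=rest_labels,
        random_state=(int(seed) + 1) & 0x7FFFFFFF,
    )
    return DatasetSplit(train=train, validation=val, test=test, fractions=fractions)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    raw = total * weights / weights.sum()
    out = np.floor(raw).astype(int)
    for k in np.argsort(-(raw - out))[: total - out.sum()]:
        out[k] += 1
    return out


def partition_clients(
    train_records: list[ECGRecord],
    n_clients: int,
    strategy: str = "iid",
    alpha: float = 0.5,
    seed: int = 0,
) -> ClientPartition:
    """Partition records across clients.

    ``iid`` deals shuffled records round-robin (sizes differ by at most one);
    ``dirichlet`` draws, for every class, the proportion of that class's
    records going to each client from a symmetric Dirichlet(alpha), producing
    label-skewed (non-IID) clients for small alpha.
    """
    n = len(train_records)
    if n_clients < 1:
        raise ValueError("n_clients must be >= 1")
    if n_clients > n:
        raise ValueError(f"cannot partition {n} records across {n_clients} clients")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC11E]))

    clients: list[list[ECGRecord]] = [[] for _ in range(n_clients)]
    if strategy == "iid":
        order = rng.permutation(n)
        for pos, idx in enumerate(order):
            clients[pos % n_clients].append(train_records[idx])
    elif strategy == "dirichlet":
        by_class: dict[str, list[ECGRecord]] = {c: [] for c in CLASSES}
        for r in train_records:
            by_class[r.label].append(r)
        for c in CLASSES:
            recs = by_class[c]
            if not recs:
                continue
            order = rng.permutation(len(recs))
            w = rng.dirichlet(np.full(n_clients, alpha))
            counts = _largest_remainder(len(recs), np.maximum(w, 1e-12))
            start = 0
            for i, m in enumerate(counts):
                clients[i].extend(recs[j] for j in order[start : start + m])
                start += m
        # Guarantee nonempty clients (possible under extreme skew).
        for i, c in enumerate(clients):
            if not c:
                donor = max(range(n_clients), key=lambda j: len(clients[j]))
                clients[i].append(clients[donor].pop())
    else:
        raise ValueError(f"unknown partition strategy {strategy!r}")

    return ClientPartition(
        clients=clients, strategy=strategy, alpha=alpha if strategy == "dirichlet" else None
    )


def normalize_features(split: DatasetSplit) -> tuple[DatasetSplit, FeatureStats]:
    """Z-score all 13 features using train-split statistics only.

    Constant features (zero std) map to 0.  Validation and test records are
    transformed with the train statistics, never their own.
    """
    if not split.train:
        raise ValueError("train split is empty")
    train_x = np.stack([r.features.to_array() for r in split.train])
    stats = FeatureStats(mean=train_x.mean(axis=0), std=train_x.std(axis=0))

    def _apply(records):
        return [
            dataclasses.replace(r, features=stats.transform(r.features)) for r in records
        ]

    out = DatasetSplit(
        train=_apply(split.train),
        validation=_apply(split.validation),
        test=_apply(split.test),
        fractions=split.fractions,
    )
    return out, stats


def write_records(records: list[ECGRecord], path: str | Path) -> None:
    """Write a dataset directory: manifest.csv + one signal CSV per record."""
    path = Path(path)
    (path / "signals").mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        sig_rel = f"signals/{r.record_id}.csv"
        sig = pd.DataFrame(r.signal.T, columns=[f"lead_{i + 1}" for i in range(12)])
        sig.to_csv(path / sig_rel, index=False)
        row = {
            "record_id": r.record_id,
            "label": r.label,
            "fs": r.fs,
            "duration": r.duration,
            "sex": r.sex,
            **dict(zip(FEATURE_NAMES, r.features.to_array())),
            "signal_path": sig_rel,
        }
        rows.append(row)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path / "manifest.csv", index=False)


def read_records(path: str | Path) -> list[ECGRecord]:
    """Read a dataset directory written by :func:`write_records`."""
    path = Path(path)
    manifest = pd.read_csv(path / "manifest.csv")
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    records = []
    for row in manifest.itertuples(index=False):
        if row.label not in CLASSES:
            raise ValueError(
                f"record {row.record_id}: unknown label {row.label!r}; valid labels are {CLASSES}"
            )
        sig = pd.read_csv(path / row.signal_path)
        if sig.shape[1] != 12:
            raise ValueError(
                f"record {row.record_id}: expected 12 signal columns, got {sig.shape[1]}"
            )
        features = FeatureVector.from_array([getattr(row, n) for n in FEATURE_NAMES])
        records.append(
            ECGRecord(
                record_id=row.record_id,
                signal=sig.to_numpy().T,
                fs=float(row.fs),
                duration=float(row.duration),
                label=row.label,
                features=features,
                sex=row.sex,
                age=float(row.age),
            )
        )
    return records
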