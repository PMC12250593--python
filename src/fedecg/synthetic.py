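"""Synthetic 12-lead ECG generator with class-dependent rhythm structure.

Records are built from a phenomenological beat model: each heartbeat is a sum
of Gaussian bumps for the P wave, the QRS complex (Q, R, S deflections) and the
T wave, projected onto 12 leads through a fixed amplitude vector.  The rhythm
class controls the ventricular rate range and the beat-to-beat (RR) interval
variability:

=====  ==================  =========  ===========
class  ventricular rate    RR CV      P wave
=====  ==================  =========  ===========
SB     [40, 60) bpm        <= 0.05    present
SR     [60, 100) bpm       <= 0.05    present
AFIB   [60, 160) bpm       >= 0.15    absent
GSVT   [100, 200) bpm      <= 0.05    present
=====  ==================  =========  ===========

The 13 clinical features are computed consistently from the generated beat
train (e.g. ventricular_rate = 60 / mean RR, qrs_count = number of beats), so
a rate-threshold rule separates SB/SR/GSVT perfectly on clean data and the
irregular, P-less AFIB signature is available to a sequence model.

Contamination (50 Hz power-line interference, sub-0.5 Hz baseline wander,
white noise) is additive and controlled by :class:`NoiseSpec`; the clean
signal is retained on the record so denoising can be scored against truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .labels import CLASSES

__all__ = [
    "FeatureVector",
    "NoiseSpec",
    "ECGRecord",
    "generate_record",
    "generate_dataset",
    "FEATURE_NAMES",
    "RATE_RANGES",
]

FEATURE_NAMES = (
    "age",
    "gender",
    "ventricular_rate",
    "atrial_rate",
    "qrs_duration",
    "qt_interval",
    "qt_corrected",
    "r_axis",
    "t_axis",
    "qrs_count",
    "q_onset",
    "q_offset",
    "t_offset",
)

#: Ventricular rate (bpm) sampling range per rhythm class.
RATE_RANGES = {
    "SB": (40.0, 60.0),
    "SR": (60.0, 100.0),
    "AFIB": (60.0, 160.0),
    "GSVT": (100.0, 200.0),
}

#: RR-interval coefficient of variation per class.  AFIB is irregular.
RR_CV = {"SB": 0.03, "SR": 0.03, "AFIB": 0.20, "GSVT": 0.03}

# Fixed per-lead projection of the single-channel beat waveform onto the 12
# leads (I, II, III, aVR, aVL, aVF, V1..V6).  aVR is inverted, as on a real
# frontal-plane montage; precordial leads grow towards V5.
LEAD_SCALE = np.array(
    [0.6, 1.0, 0.4, -0.5, 0.3, 0.7, 0.35, 0.5, 0.75, 0.9, 1.1, 0.95]
)


@dataclass(frozen=True)
class FeatureVector:
    """The 13 clinical ECG measurements attached to every record."""

    age: float
    gender: float  # encoded 0 = F, 1 = M
    ventricular_rate: float  # bpm
    atrial_rate: float  # bpm
    qrs_duration: float  # ms
    qt_interval: float  # ms
    qt_corrected: float  # ms
    r_axis: float  # degrees
    t_axis: float  # degrees
    qrs_count: float  # beats in the record (nonnegative integer value)
    q_onset: float  # samples
    q_offset: float  # samples
    t_offset: float  # samples

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "FeatureVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (13,):
            raise ValueError(f"expected 13 features, got shape {values.shape}")
        return cls(**dict(zip(FEATURE_NAMES, values)))


@dataclass(frozen=True)
class NoiseSpec:
    """Additive contamination amplitudes, all in millivolts.

    ``powerline_amp`` scales a 50 Hz sinusoid, ``baseline_amp`` a slow
    (< 0.5 Hz) drift, ``white_sigma`` the per-sample Gaussian noise std.
    """

    powerline_amp: float = 0.0
    baseline_amp: float = 0.0
    white_sigma: float = 0.0

    def __post_init__(self):
        if min(self.powerline_amp, self.baseline_amp, self.white_sigma) < 0:
            raise ValueError("noise amplitudes must be nonnegative")

    @classmethod
    def typical(cls) -> "NoiseSpec":
        """A realistic mild-contamination preset."""
        return cls(powerline_amp=0.2, baseline_amp=0.5, white_sigma=0.05)


@dataclass
class ECGRecord:
    """One subject's recording: 12 x d signal matrix plus clinical features.

    ``clean_signal`` is the pre-contamination waveform when the record was
    synthesized (None for records read from disk).
    """

    record_id: str
    signal: np.ndarray  # (12, d) millivolts
    fs: float  # Hz
    duration: float  # seconds
    label: str
    features: FeatureVector
    sex: str  # "M" or "F"
    age: float
    clean_signal: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != 12:
            raise ValueError(
                f"signal must have 12 channel rows, got shape {self.signal.shape}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.label not in CLASSES:
            raise ValueError(
                f"unknown rhythm label {self.label!r}; valid labels are {CLASSES}"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def _beat_times(rng, mean_rr: float, cv: float, duration: float) -> np.ndarray:
    """R-peak times covering [0, duration), irregular when cv is large.

    RR multipliers are normalized to sample mean 1, so the generated interval
    sequence has mean exactly ``mean_rr`` and the record's rate feature equals
    the drawn target rate.
    """
    n_max = int(np.ceil(duration / mean_rr)) + 3
    mult = np.maximum(1.0 + cv * rng.standard_normal(n_max), 0.3)
    mult /= mult.mean()
    rr = mean_rr * mult
    t0 = rng.uniform(0.1, 0.1 + rr[0])
    times = t0 + np.concatenate([[0.0], np.cumsum(rr[1:])])
    return times[times < duration]


def _gauss(t, center, width, amp):
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def _beat_waveform(t, r_times, qt: float, with_p: bool, qrs_width_s: float):
    """Single-channel beat train: Gaussian P, Q, R, S and T bumps per beat."""
    x = np.zeros_like(t)
    w_qrs = qrs_width_s / 4.0  # Gaussian sigma; bump support ~ 4 sigma
    for tb in r_times:
        if with_p:
            x += _gauss(t, tb - 0.16, 0.025, 0.15)
        x += _gauss(t, tb - 0.022, w_qrs * 0.8, -0.15)  # Q
        x += _gauss(t, tb, w_qrs, 1.0)  # R
        x += _gauss(t, tb + 0.022, w_qrs * 0.8, -0.20)  # S
        x += _gauss(t, tb + 0.75 * qt, 0.05, 0.30)  # T
    return x


def _contamination(rng, t, n_leads: int, fs: float, noise: NoiseSpec):
    """Additive noise matrix (n_leads, len(t)) per the NoiseSpec."""
    out = np.zeros((n_leads, t.size))
    if noise.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += noise.powerline_amp * np.sin(2 * np.pi * 50.0 * t + phase)
    if noise.baseline_amp > 0:
        f_drift = rng.uniform(0.05, 0.4)  # below 0.5 Hz
        phase = rng.uniform(0, 2 * np.pi)
        out += noise.baseline_amp * np.sin(2 * np.pi * f_drift * t + phase)
    if noise.white_sigma > 0:
        out += noise.white_sigma * rng.standard_normal((n_leads, t.size))
    return out


def generate_record(
    label: str,
    seed: int,
    fs: float = 500.0,
    duration: float = 10.0,
    noise: NoiseSpec | None = None,
    record_id: str | None = None,
) -> ECGRecord:
    """Generate one labeled 12-lead record; a pure function of its arguments.

    Parameters
    ----------
    label : one of SB, AFIB, GSVT, SR.
    seed : integer controlling every random draw.
    fs : sampling rate, Hz (>= 100).
    duration : record length in seconds.
    noise : contamination amplitudes; None means a clean record.
    """
    if label not in CLASSES:
        raise ValueError(f"unknown rhythm label {label!r}; valid labels are {CLASSES}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    noise = noise or NoiseSpec()

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5EC5]))
    lo, hi = RATE_RANGES[label]
    rate = rng.uniform(lo, hi)
    mean_rr = 60.0 / rate
    r_times = _beat_times(rng, mean_rr, RR_CV[label], duration)

    n = int(round(fs * duration))
    t = np.arange(n) / fs
    # Bazett scaling with subject-level QTc variability
    qtc = rng.normal(0.38, 0.015)
    qt = qtc * np.sqrt(mean_rr)
    qrs_width_s = rng.uniform(0.080, 0.100)
    base = _beat_waveform(t, r_times, qt, with_p=label != "AFIB", qrs_width_s=qrs_width_s)
    base -= base.mean()  # AC-coupled leads: isoelectric baseline at zero
    clean = LEAD_SCALE[:, None] * base[None, :]
    signal = clean + _contamination(rng, t, 12, fs, noise)

    # Clinical features derived from the same beat train; the mean of the
    # generated RR sequence is exactly 60/rate by construction.
    v_rate = rate
    if label == "AFIB":
        a_rate = rng.uniform(300.0, 450.0)  # fibrillatory atrial activity
    else:
        a_rate = v_rate
    age = float(rng.integers(20, 90))
    sex = "M" if rng.random() < 0.5 else "F"
    first_r = r_times[0] if r_times.size else 0.3
    features = FeatureVector(
        age=age,
        gender=1.0 if sex == "M" else 0.0,
        ventricular_rate=v_rate,
        atrial_rate=a_rate,
        qrs_duration=qrs_width_s * 1000.0,
        qt_interval=qt * 1000.0,
        qt_corrected=qtc * 1000.0,
        r_axis=float(rng.normal(45.0, 20.0)),
        t_axis=float(rng.normal(40.0, 20.0)),
        qrs_count=float(r_times.size),
        q_onset=float(np.floor((first_r - qrs_width_s / 2) * fs)),
        q_offset=float(np.ceil((first_r + qrs_width_s / 2) * fs)),
        t_offset=float(np.ceil((first_r + 0.75 * qt + 0.1) * fs)),
    )
    return ECGRecord(
        record_id=record_id or f"rec-{label}-{seed}",
        signal=signal,
        fs=fs,
        duration=duration,
        label=label,
        features=features,
        sex=sex,
        age=age,
        clean_signal=clean,
    )


def generate_dataset(
    n: int,
    proportions=(0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    fs: float = 500.0,
    duration: float = 10.0,
    noise: NoiseSpec | None = None,
) -> list[ECGRecord]:
    """Generate ``n`` records with class counts = rounded n x proportions.

    Counts use largest-remainder rounding so they always sum to ``n``.  Every
    record's seed derives deterministically from the master ``seed``.
    """
    proportions = np.asarray(proportions, dtype=float)
    if proportions.shape != (len(CLASSES),):
        raise ValueError(f"need {len(CLASSES)} class proportions")
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {proportions.sum()}")

    raw = n * proportions
    counts = np.floor(raw).astype(int)
    for k in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[k] += 1

    labels = [c for c, m in zip(CLASSES, counts) for _ in range(m)]
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xDA7A])
    # Shuffle the label order and derive one child seed per record.
    order = np.random.default_rng(ss.spawn(1)[0]).permutation(n)
    child_seeds = ss.generate_state(n) & 0x7FFFFFFF
    return [
        generate_record(
            labels[j],
            seed=int(child_seeds[i]),
            fs=fs,
            duration=duration,
            noise=noise,
            record_id=f"rec{i:05d}",
        )
        for i, j in enumerate(order)
    ]


def replace_features(record: ECGRecord, features: FeatureVector) -> ECGRecord:
    """Copy of ``record`` with a new feature vector (signals shared)."""
    return dataclasses.replace(record, features=features)
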