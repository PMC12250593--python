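"""Differential-privacy gradient machinery: clipping, Gaussian noise, calibration.

Per batch, the flattened loss gradient g is L2-clipped,

    g_clip = g * min(1, C / ||g||_2),

then perturbed with independent per-coordinate Gaussian noise.  Under the
default ``multiplier`` convention the noise std is sigma * C (sigma is a
noise *multiplier* relative to the clipping norm, as in DP-SGD); the
``literal`` convention uses std = sigma directly.  The multiplier can be
calibrated from a privacy budget as sigma = constant * sensitivity / epsilon.

No formal (epsilon, delta) accountant is provided: epsilon enters only
through that calibration, which is a documented limitation of the mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DPConfig",
    "clip_gradient",
    "add_gaussian_noise",
    "calibrate_sigma",
    "noise_std",
    "schedule_step",
    "dp_batch_gradient",
]


@dataclass(frozen=True)
class DPConfig:
    """Differential-privacy settings for local training.

    epsilon : privacy budget (> 0), used only by sigma calibration.
    clip_norm : L2 bound C applied to each batch gradient.
    noise_multiplier : sigma; interpreted per ``noise_convention``.
    mechanism_constant : the calibration constant (defaults to clip_norm).
    sensitivity : max gradient change from one record (defaults to clip_norm,
        the L2 sensitivity of a clipped contribution).
    schedule : "constant" or "linear_decay" (sigma decays to
        floor_fraction * sigma over the rounds; clip_norm held fixed).
    noise_convention : "multiplier" (std = sigma * C) or "literal" (std = sigma).
    """

    epsilon: float = 1.0
    clip_norm: float = 1.0
    noise_multiplier: float = 1.0
    mechanism_constant: float | None = None
    sensitivity: float | None = None
    schedule: str = "constant"
    noise_convention: str = "multiplier"
    floor_fraction: float = 0.5

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")
        if self.noise_multiplier < 0:
            raise ValueError("noise_multiplier must be nonnegative")
        if self.schedule not in ("constant", "linear_decay"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.noise_convention not in ("multiplier", "literal"):
            raise ValueError(f"unknown noise convention {self.noise_convention!r}")


def clip_gradient(g: np.ndarray, clip_norm: float) -> np.ndarray:
    """L2 clip: g * min(1, C / ||g||); direction preserved, norm <= C."""
    g = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("gradient contains non-finite values")
    norm = float(np.linalg.norm(g))
    if norm == 0.0 or not np.isfinite(clip_norm):
        return g.copy()
    return g * min(1.0, clip_norm / norm)


def add_gaussian_noise(g: np.ndarray, noise_std: float, rng: np.random.Generator) -> np.ndarray:
    """Add independent N(0, noise_std^2) noise to every coordinate."""
    if noise_std < 0:
        raise ValueError("noise_std must be nonnegative")
    g = np.asarray(g, dtype=float)
    if noise_std == 0.0:
        return g.copy()
    return g + noise_std * rng.standard_normal(g.shape)


def calibrate_sigma(mechanism_constant: float, sensitivity: float, epsilon: float) -> float:
    """sigma = constant * sensitivity / epsilon."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return mechanism_constant * sensitivity / epsilon


def noise_std(dp: DPConfig, sigma: float | None = None, clip: float | None = None) -> float:
    """Resolve the Gaussian std from the configured convention."""
    sigma = dp.noise_multiplier if sigma is None else sigma
    clip = dp.clip_norm if clip is None else clip
    if dp.noise_convention == "multiplier":
        return sigma * (clip if np.isfinite(clip) else 1.0)
    return sigma


def schedule_step(round_index: int, total_rounds: int, dp: DPConfig) -> tuple[float, float]:
    """Per-round (sigma_t, clip_norm_t); sigma_t is non-increasing in t."""
    if not 1 <= round_index <= total_rounds:
        raise ValueError(f"round_index {round_index} outside [1, {total_rounds}]")
    if dp.schedule == "constant":
        return dp.noise_multiplier, dp.clip_norm
    # linear_decay: sigma interpolates from sigma0 down to floor * sigma0.
    if total_rounds == 1:
        frac = 1.0
    else:
        frac = (round_index - 1) / (total_rounds - 1)
    sigma_t = dp.noise_multiplier * (1.0 - (1.0 - dp.floor_fraction) * frac)
    return sigma_t, dp.clip_norm


def dp_batch_gradient(
    batch,
    params,
    train_cfg,
    dp: DPConfig,
    rng: np.random.Generator,
    dp_round: tuple[int, int] = (1, 1),
) -> dict[str, np.ndarray]:
    """Noisy clipped gradient of the mean smoothed cross-entropy on a batch.

    Computes the batch loss gradient through the GRU, flattens it, clips to
    the scheduled clip norm, adds Gaussian noise per the convention, and
    returns the named-array gradient ready for an optimizer update.
    """
    from .gru import (
        _backward_batch,
        _forward_batch,
        _loss_and_dlogits,
        flatten_grads,
        stack_records,
        unflatten_grads,
    )

    if not batch:
        raise ValueError("batch is empty")
    X, F, y = stack_records(batch, params.config.fusion)
    probs, _, cache = _forward_batch(params, X, F, with_cache=True)
    loss, dlogits = _loss_and_dlogits(probs, y, train_cfg.label_smoothing)
    if not np.isfinite(loss):
        raise RuntimeError(f"non-finite loss {loss} in dp_batch_gradient")
    grads = _backward_batch(params, cache, dlogits)
    sigma_t, clip_t = schedule_step(*dp_round, dp)
    flat, layout = flatten_grads(grads)
    flat = clip_gradient(flat, clip_t)
    flat = add_gaussian_noise(flat, noise_std(dp, sigma_t, clip_t), rng)
    return unflatten_grads(flat, layout)
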