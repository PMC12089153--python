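"""Stochastic augmentation operators for training segments.

Five operators, each shape-preserving on ``[19 x 2000]`` arrays: random-channel
re-referencing, Gaussian noise (SD drawn in units of the per-channel signal
SD), single-channel amplitude amplification, time reversal, and horizontal
compression with zero padding.  Operators are pure functions of (segment,
rng, config); a seeded stream is bit-reproducible.  They are applied to
training segments only — the train module enforces that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "AugmentConfig", "random_rereference", "add_gaussian_noise", "amplify_channel",
    "horizontal_flip", "horizontal_scale", "augment_segment", "augment_batch",
]


@dataclass
class AugmentConfig:
    """Augmentation parameters.

    ``noise_sd_max`` is unitless (fraction of per-channel SD), ``amp_max`` a
    multiplicative factor, ``scale_min`` the lower bound of the horizontal
    compression factor.  ``probs`` gives the independent per-operator
    application probability.
    """

    noise_sd_max: float = 0.2
    amp_max: float = 1.2
    scale_min: float = 0.5
    probs: dict = field(default_factory=lambda: {
        "rereference": 0.5, "noise": 0.5, "amplify": 0.5, "flip": 0.5, "scale": 0.5,
    })

    def validate(self) -> None:
        if self.noise_sd_max < 0:
            raise ValueError("noise_sd_max must be >= 0")
        if self.amp_max < 1:
            raise ValueError("amp_max must be >= 1")
        if not 0 < self.scale_min <= 1:
            raise ValueError("scale_min must lie in (0, 1]")
        for k, p in self.probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probs[{k!r}] must lie in [0, 1]")


def random_rereference(seg: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Subtract a randomly drawn channel from every channel.

    Returns the re-referenced segment and the chosen channel index (whose
    output row is identically zero).  Channel-pair differences are untouched.
    """
    c = int(rng.integers(seg.shape[0]))
    return seg - seg[c : c + 1, :], c


def add_gaussian_noise(
    seg: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig | None = None,
    sd: float | None = None,
) -> np.ndarray:
    """Add zero-mean Gaussian noise with SD drawn uniform [0, noise_sd_max],
    expressed as a fraction of each channel's own SD (scale-free)."""
    cfg = cfg or AugmentConfig()
    if sd is None:
        sd = float(rng.uniform(0.0, cfg.noise_sd_max))
    if sd == 0.0:
        return seg.copy()
    chan_sd = seg.std(axis=1, keepdims=True)
    noise = rng.standard_normal(seg.shape, dtype=np.float32 if seg.dtype == np.float32 else np.float64)
    return seg + sd * chan_sd * noise


def amplify_channel(
    seg: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig | None = None,
    factor: float | None = None, channel: int | None = None,
) -> np.ndarray:
    """Scale one random channel by a factor drawn uniform [1, amp_max]."""
    cfg = cfg or AugmentConfig()
    if channel is None:
        channel = int(rng.integers(seg.shape[0]))
    if factor is None:
        factor = float(rng.uniform(1.0, cfg.amp_max))
    out = seg.copy()
    out[channel] *= factor
    return out


def horizontal_flip(seg: np.ndarray) -> np.ndarray:
    """Reverse the time axis on all channels (an involution)."""
    return seg[:, ::-1].copy()


def horizontal_scale(
    seg: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig | None = None,
    factor: float | None = None,
) -> np.ndarray:
    """Compress along time to round(n*f) samples, f ~ uniform [scale_min, 1],
    then zero-pad at the end back to the original length."""
    cfg = cfg or AugmentConfig()
    if factor is None:
        factor = float(rng.uniform(cfg.scale_min, 1.0))
    n = seg.shape[1]
    m = int(round(n * factor))
    if m == n:
        return seg.copy()
    out = np.zeros_like(seg)
    out[:, :m] = sps.resample(seg, m, axis=1)
    return out


def augment_segment(
    seg: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig | None = None
) -> np.ndarray:
    """Apply each operator independently with its configured probability."""
    cfg = cfg or AugmentConfig()
    out = seg
    if rng.random() < cfg.probs.get("rereference", 0.0):
        out, _ = random_rereference(out, rng)
    if rng.random() < cfg.probs.get("noise", 0.0):
        out = add_gaussian_noise(out, rng, cfg)
    if rng.random() < cfg.probs.get("amplify", 0.0):
        out = amplify_channel(out, rng, cfg)
    if rng.random() < cfg.probs.get("flip", 0.0):
        out = horizontal_flip(out)
    if rng.random() < cfg.probs.get("scale", 0.0):
        out = horizontal_scale(out, rng, cfg)
    return out if out is not seg else seg.copy()


def augment_batch(
    batch: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig | None = None
) -> np.ndarray:
    """Augment each segment of a ``[B x 19 x 2000]`` batch independently."""
    return np.stack([augment_segment(s, rng, cfg) for s in batch])
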