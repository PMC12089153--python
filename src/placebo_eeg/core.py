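"""Core containers shared across the pipeline.

A :class:`Recording` is one resting-state session of one subject: a
``[n_channels x n_samples]`` matrix in microvolts with its montage and an
eyes-open / eyes-closed tag.  Preprocessing turns recordings into a
:class:`SegmentSet`, the fixed-shape tensor the classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Canonical 19-channel International 10-20 montage, in pipeline order.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F8", "F3", "F4", "Fz",
    "T7", "T8", "C3", "C4", "Cz",
    "P7", "P8", "P3", "P4", "Pz", "O1", "O2",
)

N_CHANNELS = len(CANONICAL_CHANNELS)

#: Samples per segment fed to the model (16 s at 125 Hz).
SEGMENT_SAMPLES = 2000
SEGMENT_SECONDS = 16.0
SEGMENT_RATE_HZ = 125.0
#: Hop between consecutive segment starts (16-s windows, 15-s overlap).
SEGMENT_STRIDE_S = 1.0


@dataclass
class Recording:
    """One multichannel EEG session in microvolts."""

    subject_id: str
    session_id: str
    eye_state: str  # "EO" or "EC"
    rate_hz: float
    channels: tuple[str, ...]
    data: np.ndarray  # [n_channels, n_samples], float, µV

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.eye_state not in ("EO", "EC"):
            raise ValueError(f"eye_state must be 'EO' or 'EC', got {self.eye_state!r}")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data must be [n_channels x n_samples]; got shape {self.data.shape} "
                f"for {len(self.channels)} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy())

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None


#: Valid artifact-rule identifiers, in the order they are evaluated.
ARTIFACT_RULES: tuple[str, ...] = (
    "muscle", "extreme_voltage", "abrupt_transition", "kurtosis", "blink", "bridging",
)


@dataclass(frozen=True)
class ArtifactWindow:
    """One flagged stretch of a recording, in seconds from recording start."""

    start_s: float
    end_s: float
    rule_id: str
    channel: Optional[str] = None
    score: float = float("nan")


@dataclass
class ArtifactReport:
    """All artifact windows detected in one recording."""

    windows: list[ArtifactWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        for w in self.windows:
            if w.rule_id not in ARTIFACT_RULES:
                raise ValueError(f"unknown rule_id {w.rule_id!r}; valid: {ARTIFACT_RULES}")
            if w.end_s <= w.start_s:
                raise ValueError(f"empty artifact window {w}")

    def by_rule(self, rule_id: str) -> list[ArtifactWindow]:
        return [w for w in self.windows if w.rule_id == rule_id]

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class SegmentSet:
    """Fixed-shape segments of one or more recordings.

    ``data`` holds every candidate window, kept or not, so rejection is an
    annotation (``kept_mask`` / ``reject_reason``) rather than a destructive
    filter; downstream consumers select ``data[kept_mask]``.
    """

    data: np.ndarray  # [n_segments, 19, 2000] µV
    index: list[dict]  # per segment: subject_id, session_id, eye_state, start_s
    kept_mask: np.ndarray  # bool per segment
    reject_reason: list[tuple[str, ...]]  # rule ids, empty tuple when kept

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        n = self.data.shape[0]
        if self.data.ndim != 3 or (n and self.data.shape[1:] != (N_CHANNELS, SEGMENT_SAMPLES)):
            raise ValueError(
                f"segment tensor must be [n x {N_CHANNELS} x {SEGMENT_SAMPLES}], got {self.data.shape}"
            )
        if not (len(self.index) == n == len(self.kept_mask) == len(self.reject_reason)):
            raise ValueError("index, kept_mask and reject_reason must align with data")
        for kept, reasons in zip(self.kept_mask, self.reject_reason):
            if kept and reasons:
                raise ValueError("a kept segment cannot carry reject reasons")
            if not kept and not reasons:
                raise ValueError("a rejected segment must carry at least one rule id")

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    def kept_data(self) -> np.ndarray:
        return self.data[self.kept_mask]

    def kept_index(self) -> list[dict]:
        return [ix for ix, k in zip(self.index, self.kept_mask) if k]

    @staticmethod
    def empty() -> "SegmentSet":
        return SegmentSet(
            data=np.zeros((0, N_CHANNELS, SEGMENT_SAMPLES)),
            index=[], kept_mask=np.zeros(0, dtype=bool), reject_reason=[],
        )

    @staticmethod
    def concatenate(parts: list["SegmentSet"]) -> "SegmentSet":
        parts = [p for p in parts if p.n_segments] or [SegmentSet.empty()]
        return SegmentSet(
            data=np.concatenate([p.data for p in parts], axis=0),
            index=[ix for p in parts for ix in p.index],
            kept_mask=np.concatenate([p.kept_mask for p in parts]),
            reject_reason=[r for p in parts for r in p.reject_reason],
        )
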