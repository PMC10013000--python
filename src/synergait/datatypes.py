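"""Domain containers shared across the pipeline.

All containers are plain dataclasses holding numpy arrays; the pipeline
stages pass them around explicitly rather than mutating shared state.
Amplitudes are in arbitrary (amplifier) units until the low-support
scaling step, after which envelopes are unitless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Canonical bilateral muscle set (12 muscles per side), right side first.
MUSCLES_PER_SIDE = (
    "TA", "GM", "GL", "SOL", "RF", "VM", "VL", "BF", "SEM", "TFL", "GLM", "ES",
)

#: The four body-weight-support levels, in fixed reporting order.
LEVELS = ("no", "low", "medium", "high")


def default_channel_labels(n_muscles: int = 24) -> list[str]:
    """Bilateral channel labels ``rTA .. rES, lTA .. lES``.

    ``n_muscles`` must be even; the first half is the right side.
    """
    if n_muscles % 2:
        raise ValueError("n_muscles must be even (bilateral pairs)")
    per_side = n_muscles // 2
    if per_side > len(MUSCLES_PER_SIDE):
        names = [f"M{i + 1}" for i in range(per_side)]
    else:
        names = list(MUSCLES_PER_SIDE[:per_side])
    return [f"r{m}" for m in names] + [f"l{m}" for m in names]


@dataclass
class EmgRecording:
    """Multi-channel surface EMG, uniformly sampled.

    Attributes
    ----------
    channels : list of str
        Unique muscle labels, one per data column.
    rate : float
        Sampling rate in Hz (the study recorded at 2 kHz).
    data : ndarray, shape (n_samples, n_channels)
    t0 : float
        Time of the first sample, seconds.
    """

    channels: list[str]
    rate: float
    data: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x channel)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel count does not match data columns")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def copy_with(self, **kwargs) -> "EmgRecording":
        return replace(self, **kwargs)


@dataclass
class ForceTrace:
    """Vertical ground-reaction force, uniformly sampled (1 kHz in the study)."""

    rate: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return self.values.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate


@dataclass
class Stride:
    """One gait cycle: right foot strike to the consecutive right foot strike."""

    start: float
    end: float
    stride_id: int = 0
    sequence: int = 0
    valid: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class GaitTimeline:
    """Foot-strike / foot-off events and the strides derived from them.

    ``events`` rows are ``(time_s, side, type)`` with side in {left, right}
    and type in {strike, off}. Strides are built from consecutive right
    strikes; validity is assigned by :func:`synergait.gait.select_valid_strides`.
    """

    events: list[tuple[float, str, str]]
    strides: list[Stride] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t, side, typ in self.events:
            if side not in ("left", "right") or typ not in ("strike", "off"):
                raise ValueError(f"malformed event ({t}, {side}, {typ})")
        # events strictly increasing per (side, type)
        streams: dict[tuple[str, str], float] = {}
        for t, side, typ in sorted(self.events):
            key = (side, typ)
            if key in streams and t <= streams[key]:
                raise ValueError(f"events not strictly increasing for {key}")
            streams[key] = t

    def right_strikes(self) -> np.ndarray:
        return np.array(sorted(t for t, s, y in self.events
                               if s == "right" and y == "strike"))

    def valid_strides(self) -> list[Stride]:
        return [s for s in self.strides if s.valid]


@dataclass
class Cycle:
    """One time-normalized gait cycle (200 samples x muscles)."""

    stride_id: int
    data: np.ndarray
    level: Optional[str] = None
    subject: str = "s1"


@dataclass
class NormalizedCycleSet:
    """Per-stride 200-sample envelope matrices with support-level labels.

    ``scale_reference`` holds the per-muscle divisor applied by the
    low-support amplitude scaling (None before scaling).
    """

    channels: list[str]
    cycles: list[Cycle]
    n_points: int = 200
    scale_reference: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for c in self.cycles:
            c.data = np.asarray(c.data, dtype=float)
            if c.data.shape != (self.n_points, len(self.channels)):
                raise ValueError(
                    f"cycle {c.stride_id}: expected shape "
                    f"({self.n_points}, {len(self.channels)}), got {c.data.shape}"
                )

    def by_level(self, level: str) -> list[Cycle]:
        return [c for c in self.cycles if c.level == level]

    def levels_present(self) -> list[str]:
        return [lv for lv in LEVELS if any(c.level == lv for c in self.cycles)]


@dataclass
class SupportAssignment:
    """Per-stride body-weight-support percentage and level label."""

    body_weight: float
    bws_percent: dict[int, float]
    level: dict[int, str]


@dataclass
class GrandAverage:
    """Sample-wise mean envelope for one support level, with its SEM."""

    mean: np.ndarray
    sem: np.ndarray
    n: int
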