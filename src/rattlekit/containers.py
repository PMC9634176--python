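"""In-memory containers shared by every pipeline stage.

The pipeline is unit-agnostic in acceleration (all detection thresholds are
relative: mean + 1 SD within a window), so axis values may be in g or m/s²
as long as they are consistent within a session.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Tier",
    "Condition",
    "Interval",
    "AccelTimeSeries",
    "MagnitudeSeries",
    "AnnotationTrack",
    "EventSeries",
    "Provenance",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a container or file violates a structural invariant."""


class Tier(enum.Enum):
    """Annotation tiers exported by the video coder."""

    CLAP = "CLAP"
    RATTLING = "RATTLING"


class Condition(enum.Enum):
    """Social context of a rattling episode.

    MOTHER_NOT_PROVIDING: the infant rattles alone, no external rhythm.
    MOTHER_PROVIDING: the mother rattles/sings alongside (or just before).
    """

    MOTHER_NOT_PROVIDING = "Mother Not Providing Rhythm"
    MOTHER_PROVIDING = "Mother Providing Rhythm"


class Provenance(enum.Enum):
    RAW_NORM = "RAW_NORM"
    SMOOTHED = "SMOOTHED"


@dataclass(frozen=True)
class Interval:
    """One labeled annotation interval; times are half-open [onset, offset)."""

    tier: Tier
    onset_s: float
    offset_s: float
    label: Optional[Condition] = None

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValidationError(
                f"interval offset ({self.offset_s}) must exceed onset ({self.onset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def shifted(self, delta_s: float) -> "Interval":
        return Interval(self.tier, self.onset_s + delta_s, self.offset_s + delta_s, self.label)


@dataclass
class AccelTimeSeries:
    """Uniformly sampled tri-axial acceleration for a single wrist sensor.

    ``missing_mask[i]`` marks grid slots with no recorded sample; axis values
    there are undefined until interpolation.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.t.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n = len(self.t)
        for name in ("ax", "ay", "az", "missing_mask"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"axis array {name!r} length != time length {n}")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1.0 / self.fs) > 1e-9):
                raise ValidationError("time grid is not uniform at 1/fs within 1e-9")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def copy(self) -> "AccelTimeSeries":
        return AccelTimeSeries(
            self.t.copy(), self.ax.copy(), self.ay.copy(), self.az.copy(),
            self.fs, self.missing_mask.copy(),
        )


@dataclass
class MagnitudeSeries:
    """One-dimensional normalized acceleration Acc = sqrt(ax² + ay² + az²)."""

    t: np.ndarray
    acc: np.ndarray
    fs: float
    provenance: Provenance = Provenance.RAW_NORM

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if len(self.t) != len(self.acc):
            raise ValidationError("t and acc must have equal length")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")

    def __len__(self) -> int:
        return len(self.acc)

    def with_acc(self, acc: np.ndarray, provenance: Provenance) -> "MagnitudeSeries":
        return MagnitudeSeries(self.t, np.asarray(acc, dtype=float), self.fs, provenance)


@dataclass
class AnnotationTrack:
    """Ordered, per-tier non-overlapping labeled intervals from the video coder."""

    intervals: list[Interval]

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.onset_s, iv.offset_s))
        for tier in Tier:
            tier_ivs = [iv for iv in self.intervals if iv.tier is tier]
            for a, b in zip(tier_ivs, tier_ivs[1:]):
                if b.onset_s < a.offset_s - 1e-12:
                    raise ValidationError(
                        f"overlapping {tier.value} intervals: "
                        f"[{a.onset_s}, {a.offset_s}) and [{b.onset_s}, {b.offset_s})"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def tier_intervals(self, tier: Tier) -> list[Interval]:
        return [iv for iv in self.intervals if iv.tier is tier]

    def filtered(
        self, tier: Optional[Tier] = None, condition: Optional[Condition] = None
    ) -> "AnnotationTrack":
        ivs = self.intervals
        if tier is not None:
            ivs = [iv for iv in ivs if iv.tier is tier]
        if condition is not None:
            ivs = [iv for iv in ivs if iv.label is condition]
        return AnnotationTrack(list(ivs))

    def shifted(self, delta_s: float) -> "AnnotationTrack":
        return AnnotationTrack([iv.shifted(delta_s) for iv in self.intervals])


@dataclass
class EventSeries:
    """Binarized supra-threshold activity and the discrete events derived from it.

    ``b`` is a full-length 0/1 array (0 outside ``window``); ``events`` are the
    maximal supra-threshold runs after the merge rule, as half-open time
    intervals on the sensor clock.
    """

    b: np.ndarray
    events: list[tuple[float, float]]
    window: tuple[float, float]
    threshold: float
    fs: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=np.int8)

    @property
    def n_events(self) -> int:
        return len(self.events)
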