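"""Movement-event detection within aligned rattling episodes.

Per visit: join the magnitude samples of the annotated rattling episodes,
detect supra-threshold movement events per episode (threshold mean + 1 SD of
that episode's samples, 50 ms merge rule applied within episodes only),
combine the two arms by union on the time axis, and derive the per-visit
metrics: episode count, mean episode duration, movement count, and rattling
frequency (movements / total annotated rattling time). Visits whose rattling
frequency exceeds 2.5 Hz are flagged as outliers (excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .containers import (
    AnnotationTrack,
    Condition,
    Interval,
    MagnitudeSeries,
    Provenance,
    Tier,
    ValidationError,
)
from .sync import DEFAULT_MERGE_GAP_S, _runs, merge_runs

__all__ = [
    "EpisodeSegment",
    "VisitMetrics",
    "segment_episodes",
    "count_movements",
    "visit_metrics",
    "EXCLUSION_FREQ_HZ",
]

logger = logging.getLogger(__name__)

#: Rattling-frequency outlier threshold in Hz.
EXCLUSION_FREQ_HZ = 2.5


@dataclass
class EpisodeSegment:
    """Position of one source episode inside the joined series."""

    interval: Interval
    start: int  # joined-series index, half-open
    stop: int


@dataclass
class VisitMetrics:
    visit_id: str
    condition: str  # "ALL" or a Condition name
    n_episodes: int
    mean_episode_dur_s: float
    n_movements: int
    rattling_freq_hz: float
    excluded: bool

    def as_row(self) -> dict:
        return {
            "visit_id": self.visit_id,
            "condition": self.condition,
            "n_rattling_episodes": self.n_episodes,
            "mean_episode_duration_s": self.mean_episode_dur_s,
            "n_rattling_movements": self.n_movements,
            "rattling_frequency_hz": self.rattling_freq_hz,
            "excluded": self.excluded,
        }


def segment_episodes(
    m: MagnitudeSeries,
    track: AnnotationTrack,
    condition_filter: Optional[Condition] = None,
    min_duration_s: float = 0.0,
) -> Optional[tuple[MagnitudeSeries, list[EpisodeSegment]]]:
    """Join the magnitude samples of the (aligned) rattling episodes.

    Episodes are sliced half-open [onset, offset) from the sensor grid and
    concatenated in temporal order; the joined series carries a fresh
    0-based time axis (positions, not original times — the boundaries list
    retains each segment's source interval). Returns ``None`` when no
    episode survives the filter (the caller skips the visit).
    """
    intervals = track.filtered(Tier.RATTLING, condition_filter).intervals
    intervals = [iv for iv in intervals if iv.duration_s >= min_duration_s]
    if not intervals:
        return None
    t0 = m.t[0]
    pieces: list[np.ndarray] = []
    boundaries: list[EpisodeSegment] = []
    pos = 0
    for iv in intervals:
        i0 = int(np.ceil((iv.onset_s - t0) * m.fs - 1e-9))
        i1 = int(np.ceil((iv.offset_s - t0) * m.fs - 1e-9))
        i0, i1 = max(i0, 0), min(i1, len(m))
        if i1 <= i0:
            continue
        pieces.append(m.acc[i0:i1])
        boundaries.append(EpisodeSegment(iv, pos, pos + (i1 - i0)))
        pos += i1 - i0
    if not pieces:
        return None
    acc = np.concatenate(pieces)
    joined = MagnitudeSeries(np.arange(len(acc)) / m.fs, acc, m.fs, m.provenance)
    return joined, boundaries


def _episode_event_runs(
    seg: np.ndarray, fs: float, merge_gap_s: float
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Supra-threshold runs within one episode segment (local indices)."""
    sd = float(np.std(seg))
    if sd == 0.0:
        return [], np.zeros(len(seg), dtype=np.int8)
    threshold = float(np.mean(seg)) + sd
    b = (seg > threshold).astype(np.int8)
    return merge_runs(_runs(b), fs, merge_gap_s), b


def count_movements(
    joined_arms: list[tuple[MagnitudeSeries, list[EpisodeSegment]]],
    merge_gap_s: float = DEFAULT_MERGE_GAP_S,
    combine: Literal["union", "per-arm"] = "union",
    threshold_scope: Literal["episode", "joined"] = "episode",
) -> tuple[int, list[int]]:
    """Count rattling movements over one or two arms' joined series.

    Detection runs per episode segment: threshold = mean + 1 SD of that
    episode's samples (``threshold_scope="joined"`` switches to whole-series
    statistics), binarize, merge runs separated by ≤ 50 ms — never across
    episode joins. With two arms and ``combine="union"`` the supra-threshold
    binaries are OR-ed on the time axis before run extraction, so a bimanual
    shake counts once; ``combine="per-arm"`` sums the two arms' counts.

    Zero-variance episodes contribute 0 events (logged).
    """
    if not joined_arms:
        raise ValidationError("count_movements needs at least one joined series")
    boundaries = joined_arms[0][1]
    for _, b in joined_arms[1:]:
        if [(s.start, s.stop) for s in b] != [(s.start, s.stop) for s in boundaries]:
            raise ValidationError("arms must share identical episode boundaries")

    per_episode: list[int] = []
    fs = joined_arms[0][0].fs
    for k, seg_info in enumerate(boundaries):
        sl = slice(seg_info.start, seg_info.stop)
        binaries = []
        for m, _ in joined_arms:
            seg = m.acc[sl]
            if threshold_scope == "joined":
                sd = float(np.std(m.acc))
                if sd == 0.0:
                    binaries.append(np.zeros(len(seg), dtype=np.int8))
                    continue
                thr = float(np.mean(m.acc)) + sd
                binaries.append((seg > thr).astype(np.int8))
            else:
                runs, b = _episode_event_runs(seg, fs, merge_gap_s)
                if not runs and b.sum() == 0 and float(np.std(seg)) == 0.0:
                    logger.warning("zero-variance episode %d contributes 0 events", k)
                binaries.append(b)
        if combine == "union" or len(binaries) == 1:
            union = np.bitwise_or.reduce(binaries)
            n_ev = len(merge_runs(_runs(union), fs, merge_gap_s))
        else:
            n_ev = sum(len(merge_runs(_runs(b), fs, merge_gap_s)) for b in binaries)
        per_episode.append(n_ev)
    return int(sum(per_episode)), per_episode


def visit_metrics(
    visit_id: str,
    boundaries: list[EpisodeSegment],
    n_movements: int,
    condition: Optional[Condition] = None,
) -> VisitMetrics:
    """Per-visit summary; rattling frequency uses annotated episode durations."""
    if not boundaries:
        raise ValidationError("no episodes: metrics undefined")
    durations = [seg.interval.duration_s for seg in boundaries]
    total = float(sum(durations))
    if total <= 0:
        raise ValidationError("total rattling duration is zero")
    freq = n_movements / total
    return VisitMetrics(
        visit_id=visit_id,
        condition=condition.name if condition is not None else "ALL",
        n_episodes=len(boundaries),
        mean_episode_dur_s=float(np.mean(durations)),
        n_movements=int(n_movements),
        rattling_freq_hz=freq,
        excluded=freq > EXCLUSION_FREQ_HZ,
    )
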