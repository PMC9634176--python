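"""End-to-end session analysis: raw arms + video track → visit results."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .containers import AnnotationTrack, Condition, MagnitudeSeries
from .coherence import CoherenceResult, SurrogateNull, surrogate_null, wavelet_coherence
from .events import VisitMetrics, count_movements, segment_episodes, visit_metrics
from .preprocess import preprocess_sensor
from .sync import LagEstimate, synchronize

__all__ = ["SessionResult", "analyze_session"]


@dataclass
class SessionResult:
    lag: LagEstimate
    aligned_track: AnnotationTrack
    metrics: list[VisitMetrics]  # ALL plus one per observed condition
    coherence: Optional[CoherenceResult]  # between-arms WC on joined episodes
    null: Optional[SurrogateNull]


def analyze_session(
    left_raw,
    right_raw,
    video_track: AnnotationTrack,
    clap_window: tuple[float, float],
    visit_id: str = "visit",
    n_surrogates: int = 0,
    surrogate_seed: int = 0,
    min_episodes_per_visit: int = 0,
) -> Optional[SessionResult]:
    """Run the full pipeline on one session.

    Stages: preprocess both arms (interpolate → magnitude → median smooth),
    synchronize the video annotations onto the sensor clock via the claps,
    join the rattling episodes, count movement events (union across arms),
    compute per-condition visit metrics, and — on the joined series —
    between-arms wavelet coherence with an optional shuffled-surrogate null.

    Returns ``None`` when no rattling episode survives (the visit is
    skipped) or fewer than ``min_episodes_per_visit`` episodes remain.
    """
    mag_l = preprocess_sensor(left_raw)
    mag_r = preprocess_sensor(right_raw)
    aligned, lag = synchronize(mag_l, video_track, clap_window)

    seg_l = segment_episodes(mag_l, aligned)
    seg_r = segment_episodes(mag_r, aligned)
    if seg_l is None or seg_r is None:
        return None
    joined_l, boundaries = seg_l
    joined_r, _ = seg_r
    if len(boundaries) < min_episodes_per_visit:
        return None

    metrics: list[VisitMetrics] = []
    n_all, _per = count_movements([seg_l, seg_r])
    metrics.append(visit_metrics(visit_id, boundaries, n_all, None))
    for cond in Condition:
        seg_lc = segment_episodes(mag_l, aligned, cond)
        seg_rc = segment_episodes(mag_r, aligned, cond)
        if seg_lc is None or seg_rc is None:
            continue
        n_c, _ = count_movements([seg_lc, seg_rc])
        metrics.append(visit_metrics(visit_id, seg_lc[1], n_c, cond))

    coh = wavelet_coherence(joined_l, joined_r)
    null = None
    if n_surrogates > 0:
        null = surrogate_null(joined_l, joined_r, n_surrogates, surrogate_seed)
    return SessionResult(lag, aligned, metrics, coh, null)
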