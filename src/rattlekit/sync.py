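"""Sensor↔video synchronization via mother-clap events.

The session start contains a few sharp claps recorded both by the wrist
sensors and by the video coder. Both representations are binarized (sensor:
magnitude > mean + 1 SD within the clap window; video: rasterized clap
intervals) and the lag between the clocks is estimated from the diagonal
cross-recurrence profile — the matched-clap rate as a function of relative
shift. A short (6 s) window is tried first; if the peak is weak the search
automatically widens to 15 s.

Lag convention: ``lag_s`` is the video clock minus the sensor clock (the same
convention as ``SessionConfig.true_lag_s``), i.e. an event at sensor time
``t`` appears in the video annotations at ``t + lag_s``. ``align`` therefore
subtracts ``lag_s`` from annotation times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import (
    AnnotationTrack,
    EventSeries,
    Interval,
    MagnitudeSeries,
    Tier,
    ValidationError,
)

__all__ = [
    "detect_events",
    "binarize_annotations",
    "estimate_lag",
    "align",
    "synchronize",
    "LagEstimate",
    "DEFAULT_MERGE_GAP_S",
]

logger = logging.getLogger(__name__)

DEFAULT_MERGE_GAP_S = 0.050
#: Minimum matched-clap fraction considered a confident DCRP peak. A true
#: alignment matches most binarized clap samples (rate near 1), while a false
#: peak from one clap landing on a *different* clap matches at most ~1/n_claps
#: of them, so "majority matched" separates the two regimes.
PEAK_RATE_FLOOR = 0.5


@dataclass
class LagEstimate:
    """DCRP lag-search result.

    ``lag_s``: video minus sensor time. ``profile`` holds the recurrence rate
    per candidate lag (``lags_s`` gives the axis); ``peak_rate`` is its
    maximum — the fraction of binarized clap samples matched at the best
    shift. ``low_confidence`` marks peaks below the confidence floor even
    after widening.
    """

    lag_s: float
    window_s: float
    lags_s: np.ndarray
    profile: np.ndarray
    peak_rate: float
    low_confidence: bool = False


def _runs(binary: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of ones as half-open index pairs."""
    b = np.asarray(binary).astype(np.int8)
    if b.size == 0:
        return []
    edges = np.diff(np.concatenate(([0], b, [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def merge_runs(
    runs: list[tuple[int, int]], fs: float, merge_gap_s: float = DEFAULT_MERGE_GAP_S
) -> list[tuple[int, int]]:
    """Merge runs whose separating gap is ``merge_gap_s`` or less."""
    if not runs:
        return []
    merged = [runs[0]]
    for start, stop in runs[1:]:
        gap_s = (start - merged[-1][1]) / fs
        if gap_s <= merge_gap_s + 1e-12:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return merged


def detect_events(
    m: MagnitudeSeries,
    window: tuple[float, float],
    merge_gap_s: float = DEFAULT_MERGE_GAP_S,
) -> EventSeries:
    """Binarize supra-threshold movement inside ``window`` and extract events.

    The threshold is mean + 1 population SD of the magnitude within the
    window; samples strictly above it are 1, everything outside the window is
    0. Maximal 1-runs separated by ``merge_gap_s`` (default 50 ms) or less
    are merged into single events.
    """
    start_s, end_s = window
    t0 = m.t[0]
    i0 = int(np.ceil((start_s - t0) * m.fs - 1e-9))
    i1 = int(np.floor((end_s - t0) * m.fs + 1e-9)) + 1
    i0 = max(i0, 0)
    i1 = min(i1, len(m))
    if i1 - i0 < 2:
        raise ValidationError("analysis window contains fewer than 2 samples")
    seg = m.acc[i0:i1]
    sd = float(np.std(seg))  # population SD
    if sd == 0.0:
        raise ValidationError("zero-variance window: threshold undefined")
    threshold = float(np.mean(seg)) + sd
    b = np.zeros(len(m), dtype=np.int8)
    b[i0:i1] = (seg > threshold).astype(np.int8)
    runs = merge_runs(_runs(b), m.fs, merge_gap_s)
    events = [(t0 + s / m.fs, t0 + e / m.fs) for s, e in runs]
    return EventSeries(b, events, (start_s, end_s), threshold, m.fs)


def binarize_annotations(
    track: AnnotationTrack, tier: Tier, fs: float, extent_s: float
) -> np.ndarray:
    """Rasterize the tier's intervals: sample i is 1 iff i/fs ∈ [onset, offset)."""
    n = int(round(extent_s * fs))
    b = np.zeros(n, dtype=np.int8)
    for iv in track.tier_intervals(tier):
        i0 = int(np.ceil(iv.onset_s * fs - 1e-9))
        i1 = int(np.ceil(iv.offset_s * fs - 1e-9))
        b[max(i0, 0): min(i1, n)] = 1
    return b


def _dcrp(x: np.ndarray, y: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Match-count profile between binary x (sensor) and y (video).

    profile[k] for lag ℓ = lags[k] is the number of indices with
    x[i] = y[i + ℓ] = 1, normalized by the smaller count of ones each series
    contributes to the overlap, so a perfect alignment scores 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lags = np.arange(-max_lag, max_lag + 1)
    # cross-correlation: c[ℓ] = Σ_i x[i] · y[i + ℓ]
    full = np.correlate(y, x, mode="full")  # index ℓ + (len(x) - 1)
    center = len(x) - 1
    matches = full[center + lags[0]: center + lags[-1] + 1]
    cx = np.concatenate(([0.0], np.cumsum(x)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    nx, ny = len(x), len(y)
    profile = np.zeros(len(lags))
    for k, lag in enumerate(lags):
        # overlap of i in [max(0, -lag), min(nx, ny - lag))
        i0 = max(0, -lag)
        i1 = min(nx, ny - lag)
        if i1 <= i0:
            continue
        ones_x = cx[i1] - cx[i0]
        ones_y = cy[i1 + lag] - cy[i0 + lag]
        denom = min(ones_x, ones_y)
        if denom > 0:
            profile[k] = matches[k] / denom
    return lags, profile


def estimate_lag(
    sensor_claps: np.ndarray,
    video_claps: np.ndarray,
    fs: float,
    window_s: float = 6.0,
    widen_to_s: float = 15.0,
    peak_rate_floor: float = PEAK_RATE_FLOOR,
) -> LagEstimate:
    """Estimate the video-minus-sensor lag from two binary clap series.

    Searches integer-sample lags in ±``window_s``; if the best matched-clap
    rate is below ``peak_rate_floor`` the search is repeated at
    ``widen_to_s`` (the two-stage 6 s / 15 s procedure). Ties break toward
    the smallest |lag|, then negative before positive.
    """
    sensor_claps = np.asarray(sensor_claps)
    video_claps = np.asarray(video_claps)
    if sensor_claps.sum() == 0 or video_claps.sum() == 0:
        raise ValidationError("clap series must each contain at least one 1")

    def _search(win: float) -> LagEstimate:
        max_lag = int(round(win * fs))
        lags, profile = _dcrp(sensor_claps, video_claps, max_lag)
        peak = float(profile.max())
        best = np.flatnonzero(profile >= peak - 1e-12)
        # ties: smallest |lag|, then negative first
        order = sorted(best, key=lambda k: (abs(int(lags[k])), lags[k]))
        k0 = order[0]
        # the true lag is generally a non-integer number of samples, so the
        # match profile peaks as a short tent with a near-tied plateau whose
        # ends depend on rasterization phase; localize the peak as the
        # match-weighted centroid of the contiguous half-maximum region
        # around the argmax, rounded back to an integer sample
        half = peak / 2.0
        lo = k0
        while lo > 0 and profile[lo - 1] >= half:
            lo -= 1
        hi = k0
        while hi < len(lags) - 1 and profile[hi + 1] >= half:
            hi += 1
        w = profile[lo: hi + 1]
        centroid = float(np.dot(lags[lo: hi + 1], w) / w.sum())
        lag_samples = int(np.floor(centroid + 0.5))
        return LagEstimate(lag_samples / fs, win, lags / fs, profile, peak)

    est = _search(window_s)
    if est.peak_rate < peak_rate_floor and widen_to_s > window_s:
        logger.info(
            "DCRP peak rate %.3f below floor %.2f at window %.0f s; widening to %.0f s",
            est.peak_rate, peak_rate_floor, window_s, widen_to_s,
        )
        est = _search(widen_to_s)
    if est.peak_rate < peak_rate_floor:
        est.low_confidence = True
    return est


def align(
    track: AnnotationTrack, lag: LagEstimate, sensor_extent_s: float | None = None
) -> AnnotationTrack:
    """Map annotation times from the video clock onto the sensor clock.

    Shifts every interval by −lag_s; if ``sensor_extent_s`` is given,
    intervals are clipped to [0, extent] and fully-outside intervals dropped
    (with a logged count).
    """
    shifted = track.shifted(-lag.lag_s)
    if sensor_extent_s is None:
        return shifted
    kept: list[Interval] = []
    dropped = 0
    for iv in shifted.intervals:
        on = max(iv.onset_s, 0.0)
        off = min(iv.offset_s, sensor_extent_s)
        if off <= on:
            dropped += 1
            continue
        kept.append(Interval(iv.tier, on, off, iv.label))
    if dropped:
        logger.warning("align: dropped %d interval(s) outside the sensor extent", dropped)
    return AnnotationTrack(kept)


def synchronize(
    m: MagnitudeSeries,
    track: AnnotationTrack,
    clap_window: tuple[float, float],
    window_s: float = 6.0,
) -> tuple[AnnotationTrack, LagEstimate]:
    """Full stage: detect sensor claps, estimate the lag, align the track.

    ``clap_window`` is the user-supplied sensor-time period containing the
    claps (replacing the interactive selection step with an explicit value).
    """
    ev = detect_events(m, clap_window)
    extent_s = len(m) / m.fs
    video_extent = max(
        extent_s, max((iv.offset_s for iv in track.intervals), default=0.0)
    ) + 16.0
    video_b = binarize_annotations(track, Tier.CLAP, m.fs, video_extent)
    n = max(len(ev.b), len(video_b))
    sensor_b = np.zeros(n, dtype=np.int8)
    sensor_b[: len(ev.b)] = ev.b
    video_full = np.zeros(n, dtype=np.int8)
    video_full[: len(video_b)] = video_b
    est = estimate_lag(sensor_b, video_full, m.fs, window_s=window_s)
    return align(track, est, sensor_extent_s=extent_s), est
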