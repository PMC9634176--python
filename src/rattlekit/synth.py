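"""Synthetic dyad-session generator with known ground truth.

Emulates a ~5 min rattle-shaking recording: two wrist sensors at 60 Hz with
white per-axis noise and a constant gravity offset, mother-clap transients at
the session start (the synchronization anchor), and annotated rattling
episodes containing a known number of oscillatory movement packets at a known
burst frequency with controllable left–right coupling. The video annotation
track is the true event timing shifted by a known sensor↔video lag.

Signal model
------------
Each rattling movement is one period-scale packet: a Hann-windowed cosine,
window length 1.25 carrier periods with the carrier peak at the window
center, added to the gravity axis. Riding on the gravity offset, each packet
produces exactly one supra-threshold run in the magnitude series, so
ground-truth movement counts are well defined. Coupling c ∈ [0, 1] controls
the right arm: each right-arm packet is the left-arm packet shifted in time
by (1 − c)·U(−L/2, L/2) (L = episode length, wrapped into the episode) plus
a sub-period circular jitter of SD π(1 − c) on the carrier clock. c = 1
yields phase-locked identical arm signals (up to sensor noise); c = 0 yields
independently placed, independently phased packets.

Only magnitude-level realism is attempted: no joint models, orientations, or
quaternions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import (
    AccelTimeSeries,
    AnnotationTrack,
    Condition,
    Interval,
    Tier,
    ValidationError,
)

__all__ = [
    "EpisodeSpec",
    "SessionConfig",
    "EpisodeTruth",
    "GroundTruth",
    "generate_session",
    "default_session_config",
]

#: Packet window length in carrier periods (period-scale burst).
PACKET_PERIODS = 1.25
#: Clap transient width in seconds (half-sine).
CLAP_WIDTH_S = 0.10


@dataclass(frozen=True)
class EpisodeSpec:
    """One annotated rattling episode with its latent movement content."""

    onset_s: float
    offset_s: float
    burst_freq_hz: float = 1.2
    n_movements: int = 3
    coupling: float = 1.0
    amplitude: float = 5.0
    condition: Condition = Condition.MOTHER_NOT_PROVIDING

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValidationError("episode offset must exceed onset")
        if not (0.5 <= self.burst_freq_hz <= 2.5):
            raise ValidationError("burst_freq_hz must lie in [0.5, 2.5]")
        if self.n_movements < 1:
            raise ValidationError("n_movements must be ≥ 1")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValidationError("coupling must lie in [0, 1]")
        if self.amplitude <= 0:
            raise ValidationError("amplitude must be positive")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class SessionConfig:
    """Full latent description of one synthetic dyad session.

    Defaults correspond to the recording setup emulated throughout: ~5 min
    sessions sampled at 60 Hz, a handful of claps near the start, gravity on
    one axis, and order-of-magnitude sensor noise (units are arbitrary but
    consistent; all downstream thresholds are relative).
    """

    duration_s: float = 300.0
    fs: float = 60.0
    n_claps: int = 4
    clap_window: tuple[float, float] = (1.0, 15.0)
    true_lag_s: float = 0.0
    episodes: list[EpisodeSpec] = field(default_factory=list)
    noise_sd: float = 0.5
    gravity_offset: float = 9.81
    clap_amplitude: float = 30.0
    dropout_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValidationError("duration_s and fs must be positive")
        lo, hi = self.clap_window
        if not (0.0 <= lo < hi <= self.duration_s):
            raise ValidationError("clap_window must lie within [0, duration_s]")
        if abs(self.true_lag_s) > 15.0:
            raise ValidationError("true_lag_s must lie in [-15, 15] s")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.noise_sd > 0 and self.clap_amplitude < 5.0 * self.noise_sd:
            raise ValidationError("clap_amplitude must be ≥ 5× noise_sd")
        eps = sorted(self.episodes, key=lambda e: e.onset_s)
        for a, b in zip(eps, eps[1:]):
            if b.onset_s < a.offset_s:
                raise ValidationError(
                    f"overlapping episodes: [{a.onset_s}, {a.offset_s}) "
                    f"and [{b.onset_s}, {b.offset_s})"
                )
        for e in eps:
            if e.offset_s > self.duration_s:
                raise ValidationError("episode extends beyond session duration")
        self.episodes = eps


@dataclass
class EpisodeTruth:
    """Realized latent content of one episode (sensor clock)."""

    spec: EpisodeSpec
    left_centers_s: np.ndarray
    right_centers_s: np.ndarray


@dataclass
class GroundTruth:
    """Everything the generator knows and downstream stages must recover."""

    true_lag_s: float
    clap_times_s: np.ndarray
    clap_intervals: list[tuple[float, float]]
    episodes: list[EpisodeTruth]

    @property
    def n_movements_total(self) -> int:
        return sum(e.spec.n_movements for e in self.episodes)

    @property
    def episode_intervals(self) -> list[tuple[float, float]]:
        return [(e.spec.onset_s, e.spec.offset_s) for e in self.episodes]


def _hann_packet(t: np.ndarray, center: float, freq: float, amplitude: float) -> np.ndarray:
    """Hann-windowed cosine, window 1.25 periods, carrier peak at center."""
    half = 0.5 * PACKET_PERIODS / freq
    u = t - center
    inside = np.abs(u) < half
    out = np.zeros_like(t)
    w = 0.5 * (1.0 + np.cos(np.pi * u[inside] / half))
    out[inside] = amplitude * w * np.cos(2.0 * np.pi * freq * u[inside])
    return out


def _half_sine(t: np.ndarray, center: float, width: float, amplitude: float) -> np.ndarray:
    u = t - center
    inside = np.abs(u) < width / 2.0
    out = np.zeros_like(t)
    out[inside] = amplitude * np.cos(np.pi * u[inside] / width)
    return out


def _jittered_grid(rng: np.random.Generator, lo: float, hi: float, n: int,
                   jitter_frac: float = 0.2) -> np.ndarray:
    """n points evenly spread over [lo, hi] with small uniform jitter."""
    span = hi - lo
    step = span / n
    base = lo + (np.arange(n) + 0.5) * step
    return base + rng.uniform(-jitter_frac, jitter_frac, size=n) * step


def _wrap_into(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    if span <= 0:
        return np.full_like(x, 0.5 * (lo + hi))
    return lo + np.mod(x - lo, span)


def generate_session(
    config: SessionConfig,
) -> tuple[AccelTimeSeries, AccelTimeSeries, AnnotationTrack, GroundTruth]:
    """Generate one session: left/right sensor streams, video track, truth.

    All randomness derives from ``config.rng_seed`` through deterministic
    per-component substreams (noise per arm, claps, one per episode), so
    identical configs give bit-identical output.
    """
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    ss = np.random.SeedSequence(config.rng_seed)
    keys = ss.spawn(3 + len(config.episodes))
    rng_noise_l = np.random.default_rng(keys[0])
    rng_noise_r = np.random.default_rng(keys[1])
    rng_claps = np.random.default_rng(keys[2])

    sig_l = np.zeros(n)
    sig_r = np.zeros(n)

    # claps: shared transients on both arms inside the clap window
    lo, hi = config.clap_window
    margin = CLAP_WIDTH_S
    clap_times = _jittered_grid(rng_claps, lo + margin, hi - margin, config.n_claps)
    for c in clap_times:
        spike = _half_sine(t, c, CLAP_WIDTH_S, config.clap_amplitude)
        sig_l += spike
        sig_r += spike
    clap_intervals = [(c - CLAP_WIDTH_S / 2.0, c + CLAP_WIDTH_S / 2.0) for c in clap_times]

    episodes_truth: list[EpisodeTruth] = []
    for spec, key in zip(config.episodes, keys[3:]):
        rng = np.random.default_rng(key)
        f = spec.burst_freq_hz
        half_w = 0.5 * PACKET_PERIODS / f
        c_lo = spec.onset_s + half_w
        c_hi = spec.offset_s - half_w
        if c_hi <= c_lo:  # episode shorter than one packet: center it
            left_centers = np.full(spec.n_movements, 0.5 * (spec.onset_s + spec.offset_s))
        else:
            left_centers = _jittered_grid(rng, c_lo, c_hi, spec.n_movements)
        decouple = 1.0 - spec.coupling
        # coupling=1: right packets coincide with left packets (phase-locked);
        # coupling=0: right packets placed uniformly at random in the episode
        # with uniform carrier phase. The per-packet jitter is a time shift of
        # the whole packet: a placement component (1−c)·U(−L/2, L/2) wrapped
        # into the episode plus a sub-period component with circular SD
        # π·(1−c) on the carrier clock.
        placement = decouple * rng.uniform(
            -spec.duration_s / 2.0, spec.duration_s / 2.0, size=spec.n_movements
        )
        theta = rng.normal(0.0, math.pi * decouple, size=spec.n_movements)
        theta = np.mod(theta + math.pi, 2.0 * math.pi) - math.pi
        right_centers = _wrap_into(
            left_centers + placement + theta / (2.0 * math.pi * f), c_lo, max(c_hi, c_lo)
        )
        for c in left_centers:
            sig_l += _hann_packet(t, c, f, spec.amplitude)
        for c in right_centers:
            sig_r += _hann_packet(t, c, f, spec.amplitude)
        episodes_truth.append(EpisodeTruth(spec, left_centers, right_centers))

    def _assemble(sig: np.ndarray, rng: np.random.Generator) -> AccelTimeSeries:
        ax = config.gravity_offset + sig + rng.normal(0.0, config.noise_sd, n)
        ay = rng.normal(0.0, config.noise_sd, n)
        az = rng.normal(0.0, config.noise_sd, n)
        missing = np.zeros(n, dtype=bool)
        if config.dropout_rate > 0:
            missing = rng.uniform(size=n) < config.dropout_rate
            missing[[0, -1]] = False  # keep the grid extent well defined
            for arr in (ax, ay, az):
                arr[missing] = np.nan
        return AccelTimeSeries(t.copy(), ax, ay, az, config.fs, missing)

    left = _assemble(sig_l, rng_noise_l)
    right = _assemble(sig_r, rng_noise_r)

    lag = config.true_lag_s
    video_intervals = [
        Interval(Tier.CLAP, on + lag, off + lag) for on, off in clap_intervals
    ] + [
        Interval(Tier.RATTLING, e.spec.onset_s + lag, e.spec.offset_s + lag, e.spec.condition)
        for e in episodes_truth
    ]
    video_track = AnnotationTrack(video_intervals)
    truth = GroundTruth(lag, clap_times, clap_intervals, episodes_truth)
    return left, right, video_track, truth


def default_session_config(
    rng_seed: int,
    coupling: float = 0.9,
    n_episodes: int = 12,
    burst_freq_hz: float = 1.2,
    movements_per_period: float = 0.8,
    true_lag_s: float = 0.0,
    noise_sd: float = 0.5,
    condition_split: float = 0.7,
    **overrides,
) -> SessionConfig:
    """Study-condition session layout derived deterministically from a seed.

    Episodes of 1.5–4.5 s are spread after the clap window with 8–20 s gaps;
    each carries ``round(movements_per_period · f · duration)`` movements so
    the rattling frequency is ≈ 1 Hz. ``condition_split`` is the probability
    an episode is labeled "mother not providing rhythm" (the study observed
    roughly a 70/30 split).
    """
    layout_rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 0xE715)))
    duration_s = overrides.pop("duration_s", 300.0)
    episodes: list[EpisodeSpec] = []
    t_cur = 25.0
    for _ in range(n_episodes):
        dur = layout_rng.uniform(1.5, 4.5)
        if t_cur + dur > duration_s - 5.0:
            break
        n_mov = max(1, int(round(movements_per_period * burst_freq_hz * dur)))
        # cap by the center span so packets stay temporally distinct (one
        # supra-threshold run per movement): spacing ≥ 0.7 carrier periods
        span = dur - PACKET_PERIODS / burst_freq_hz
        n_mov = max(1, min(n_mov, int(span * burst_freq_hz / 0.7)))
        cond = (
            Condition.MOTHER_NOT_PROVIDING
            if layout_rng.uniform() < condition_split
            else Condition.MOTHER_PROVIDING
        )
        episodes.append(
            EpisodeSpec(t_cur, t_cur + dur, burst_freq_hz, n_mov, coupling, 5.0, cond)
        )
        t_cur += dur + layout_rng.uniform(8.0, 20.0)
    return SessionConfig(
        duration_s=duration_s,
        episodes=episodes,
        true_lag_s=true_lag_s,
        noise_sd=noise_sd,
        rng_seed=rng_seed,
        **overrides,
    )
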