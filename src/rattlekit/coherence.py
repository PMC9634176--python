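"""Morlet continuous wavelet transform and smoothed wavelet coherence.

Wavelet coherence between the two arms' magnitude series is

    WC = |S(Cx*·Cy)|² / ( S(|Cx|²) · S(|Cy|²) )

where Cx, Cy are continuous wavelet transforms at scale a and time b and S
is a smoothing operator in time and scale. Without smoothing the ratio is
identically 1 (the known degeneracy), so S is what makes WC informative.

Conventions (configurable):

* mother wavelet — analytic Morlet, ω₀ = 6, 12 voices per octave on a
  dyadic scale grid spanning 0.25–5 Hz by default (the 0.5–2.5 Hz analysis
  band with margin);
* smoothing — Gaussian in time with SD equal to the scale, boxcar of 0.6
  octave across scales (rounded to an odd number of rows), each field
  scale-normalized (divided by the scale) before smoothing;
* cone of influence — √2·scale e-folding convention, stored as the lowest
  edge-reliable frequency per time point.

Because the smoothing weights are non-negative and identical across the
numerator and denominator fields, the Cauchy–Schwarz inequality bounds WC in
[0, 1] up to floating-point error; overshoot beyond 1e-6 raises, signalling
a smoothing bug.

The heavy path (1000-iteration surrogate nulls) is fully vectorized: per
input length the FFT kernels for the wavelet and the per-scale Gaussian
smoothers are computed once and cached.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import fft as sfft

from .containers import MagnitudeSeries, ValidationError

__all__ = [
    "CWTResult",
    "CoherenceResult",
    "SurrogateNull",
    "cwt",
    "wavelet_coherence",
    "band_average",
    "surrogate_null",
    "group_null_test",
    "single_hand_spectrum",
    "morlet_fourier_factor",
]

DEFAULT_OMEGA0 = 6.0
DEFAULT_VOICES = 12
DEFAULT_F_MIN = 0.25
DEFAULT_F_MAX = 5.0
BAND_LO_HZ = 0.5
BAND_HI_HZ = 2.5
#: Scale-smoothing boxcar width in octaves.
SCALE_SMOOTH_OCTAVES = 0.6
#: Allowed numerical overshoot of WC beyond [0, 1].
CLIP_TOL = 1e-6


def morlet_fourier_factor(omega0: float = DEFAULT_OMEGA0) -> float:
    """Period/scale ratio of the Morlet wavelet: λ = 4π / (ω₀ + √(2 + ω₀²))."""
    return 4.0 * math.pi / (omega0 + math.sqrt(2.0 + omega0**2))


@dataclass
class CWTResult:
    coeffs: np.ndarray  # complex, (n_scales, n_times)
    freqs: np.ndarray  # Hz per scale row, strictly decreasing
    scales: np.ndarray  # seconds
    coi: np.ndarray  # per-time lowest edge-reliable frequency (Hz)
    fs: float
    short_input: bool = False  # set when input < 2 periods of the lowest freq


@dataclass
class CoherenceResult:
    wc: np.ndarray  # real, clipped to [0, 1]
    freqs: np.ndarray
    scales: np.ndarray
    coi: np.ndarray
    band_mean: float
    raw_min: float  # elementwise extremes before clipping
    raw_max: float
    smoothing_params: dict = field(default_factory=dict)


@dataclass
class SurrogateNull:
    observed: float
    null_values: np.ndarray
    n_iter: int
    seed: int

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.null_values, q))

    @property
    def exceedance_p(self) -> float:
        """Fraction of null draws ≥ observed (one-sided)."""
        return float(np.mean(self.null_values >= self.observed))


# ---------------------------------------------------------------------------
# plan cache


class _Plan:
    """Precomputed FFT kernels for one (length, grid, smoothing) setting."""

    def __init__(self, n: int, fs: float, f_min: float, f_max: float,
                 voices: int, omega0: float):
        self.n, self.fs = n, fs
        self.omega0 = omega0
        ff = morlet_fourier_factor(omega0)
        n_scales = int(math.ceil(voices * math.log2(f_max / f_min))) + 1
        self.freqs = f_max * 2.0 ** (-np.arange(n_scales) / voices)
        self.scales = 1.0 / (ff * self.freqs)
        self.voices = voices
        dt = 1.0 / fs
        pad = int(math.ceil(8.0 * self.scales.max() * fs))
        self.m = sfft.next_fast_len(n + pad)
        # Morlet in frequency: ψ̂(sω) = π^(-1/4) √(2πs/dt) e^(−(sω−ω₀)²/2), ω>0
        omega = 2.0 * math.pi * np.fft.fftfreq(self.m, d=dt)
        arg = self.scales[:, None] * omega[None, :] - omega0
        self.kernels = (
            math.pi ** -0.25
            * np.sqrt(2.0 * math.pi * self.scales[:, None] / dt)
            * np.exp(-0.5 * arg**2)
            * (omega[None, :] > 0)
        )
        # per-scale Gaussian time smoother (SD = scale), as FFT multipliers
        self.m2 = sfft.next_fast_len(n + pad)
        half = np.arange(self.m2 // 2 + 1) * dt
        gauss_f = []
        for s in self.scales:
            k = np.zeros(self.m2)
            sup = min(int(math.ceil(4.0 * s * fs)), self.m2 // 2 - 1)
            tt = np.arange(sup + 1) * dt
            g = np.exp(-0.5 * (tt / s) ** 2)
            k[: sup + 1] = g
            k[self.m2 - sup:] = g[1:][::-1]
            k /= k.sum()
            gauss_f.append(sfft.rfft(k))
        self.gauss_f = np.array(gauss_f)
        # scale boxcar half-width in rows (0.6 octave, odd total)
        width = max(1, int(round(SCALE_SMOOTH_OCTAVES * voices)))
        if width % 2 == 0:
            width += 1
        self.box_half = width // 2
        # cone of influence (lowest reliable frequency per time)
        d = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
        d = np.maximum(d, dt)
        self.coi = 1.0 / (ff * math.sqrt(2.0) * d)


_PLANS: dict[tuple, _Plan] = {}


def _get_plan(n: int, fs: float, f_min: float, f_max: float,
              voices: int, omega0: float) -> _Plan:
    key = (n, fs, f_min, f_max, voices, omega0)
    if key not in _PLANS:
        if len(_PLANS) > 32:
            _PLANS.clear()
        _PLANS[key] = _Plan(*key)
    return _PLANS[key]


# ---------------------------------------------------------------------------
# transforms


def _cwt_array(x: np.ndarray, plan: _Plan) -> np.ndarray:
    xf = sfft.fft(x - x.mean(), plan.m)
    return sfft.ifft(xf[None, :] * plan.kernels, axis=1)[:, : plan.n]


def _smooth(field_arr: np.ndarray, plan: _Plan) -> np.ndarray:
    """Grinsted-style smoothing: Gaussian (SD = scale) in time, boxcar in scale."""
    n = plan.n
    if np.iscomplexobj(field_arr):
        re = sfft.irfft(sfft.rfft(field_arr.real, plan.m2) * plan.gauss_f, plan.m2)
        im = sfft.irfft(sfft.rfft(field_arr.imag, plan.m2) * plan.gauss_f, plan.m2)
        out = re[:, :n] + 1j * im[:, :n]
    else:
        out = sfft.irfft(sfft.rfft(field_arr, plan.m2) * plan.gauss_f, plan.m2)[:, :n]
    # boxcar across scale rows, truncated and renormalized at the grid edges
    h = plan.box_half
    if h == 0:
        return out
    c = np.cumsum(out, axis=0)
    z = np.zeros((1,) + out.shape[1:], dtype=out.dtype)
    c = np.concatenate([z, c], axis=0)
    k = out.shape[0]
    idx = np.arange(k)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, k)
    return (c[hi] - c[lo]) / (hi - lo)[:, None]


def _check_series(m: MagnitudeSeries) -> np.ndarray:
    x = np.asarray(m.acc, dtype=float)
    if x.size == 0:
        raise ValidationError("empty input")
    if not np.all(np.isfinite(x)):
        raise ValidationError("input contains non-finite values")
    return x


def cwt(
    m: MagnitudeSeries,
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    voices: int = DEFAULT_VOICES,
    omega0: float = DEFAULT_OMEGA0,
) -> CWTResult:
    """Analytic Morlet CWT on a dyadic scale grid (``voices`` per octave).

    Inputs shorter than two periods of the lowest analyzed frequency are
    transformed anyway but flagged ``short_input`` (edge effects dominate).
    """
    x = _check_series(m)
    plan = _get_plan(len(x), m.fs, f_min, f_max, voices, omega0)
    short = len(x) < 2.0 * m.fs / f_min
    if short:
        warnings.warn(
            "input shorter than two periods of the lowest analyzed frequency",
            stacklevel=2,
        )
    coeffs = _cwt_array(x, plan)
    return CWTResult(coeffs, plan.freqs.copy(), plan.scales.copy(),
                     plan.coi.copy(), m.fs, short)


def _coherence_fields(
    x: np.ndarray, y: np.ndarray, plan: _Plan, smoothing: bool
) -> np.ndarray:
    wx = _cwt_array(x, plan)
    wy = _cwt_array(y, plan)
    inv_s = 1.0 / plan.scales[:, None]
    if smoothing:
        sxx = _smooth((wx.real**2 + wx.imag**2) * inv_s, plan)
        syy = _smooth((wy.real**2 + wy.imag**2) * inv_s, plan)
        sxy = _smooth(np.conj(wx) * wy * inv_s, plan)
    else:
        sxx = (wx.real**2 + wx.imag**2) * inv_s
        syy = (wy.real**2 + wy.imag**2) * inv_s
        sxy = np.conj(wx) * wy * inv_s
    if smoothing:
        # floor the auto-spectra at -70 dB of their maximum: FFT-based
        # smoothing carries absolute rounding error ~1e-14·max(field), which
        # would dominate the ratio at cells whose true power is vanishingly
        # small (e.g. far off a pure tone's frequency). Above the floor that
        # error is < 1e-6 relative, keeping WC within its [0, 1] tolerance;
        # floored (powerless) cells report coherence ~0. Without smoothing
        # the ratio is algebraically exact, so no floor is needed.
        sxx = np.maximum(sxx, 1e-7 * sxx.max())
        syy = np.maximum(syy, 1e-7 * syy.max())
    denom = sxx * syy
    with np.errstate(divide="ignore", invalid="ignore"):
        wc = (sxy.real**2 + sxy.imag**2) / denom
    wc[denom <= 0] = 0.0
    return wc


def wavelet_coherence(
    x: MagnitudeSeries,
    y: MagnitudeSeries,
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    voices: int = DEFAULT_VOICES,
    omega0: float = DEFAULT_OMEGA0,
    band: tuple[float, float] = (BAND_LO_HZ, BAND_HI_HZ),
    smoothing: bool = True,
) -> CoherenceResult:
    """Smoothed wavelet coherence between two equal-length magnitude series.

    ``smoothing=False`` disables S (returning the degenerate WC ≡ 1); it
    exists as a negative control, not an analysis option.
    """
    xa, ya = _check_series(x), _check_series(y)
    if len(xa) != len(ya):
        raise ValidationError("length mismatch between the two series")
    if x.fs != y.fs:
        raise ValidationError("sampling-rate mismatch between the two series")
    if np.std(xa) == 0.0 or np.std(ya) == 0.0:
        raise ValidationError("constant input: coherence denominator is zero")
    plan = _get_plan(len(xa), x.fs, f_min, f_max, voices, omega0)
    wc = _coherence_fields(xa, ya, plan, smoothing)
    raw_min, raw_max = float(wc.min()), float(wc.max())
    if raw_max > 1.0 + CLIP_TOL or raw_min < -CLIP_TOL:
        raise ValidationError(
            f"coherence outside [0,1] beyond tolerance: [{raw_min}, {raw_max}]"
        )
    wc = np.clip(wc, 0.0, 1.0)
    in_band = (plan.freqs >= band[0]) & (plan.freqs <= band[1])
    band_mean = float(wc[in_band].mean()) if in_band.any() else float("nan")
    return CoherenceResult(
        wc, plan.freqs.copy(), plan.scales.copy(), plan.coi.copy(),
        band_mean, raw_min, raw_max,
        {
            "time": "gaussian sd=scale",
            "scale": f"boxcar {2 * plan.box_half + 1} rows (~{SCALE_SMOOTH_OCTAVES} octave)",
            "enabled": smoothing,
            "omega0": omega0,
            "voices": voices,
        },
    )


def band_average(
    c: CoherenceResult, f_lo: float = BAND_LO_HZ, f_hi: float = BAND_HI_HZ,
    coi_exclude: bool = False,
) -> float:
    """Unweighted mean of WC over rows with f_lo ≤ freq ≤ f_hi, all times.

    ``coi_exclude=True`` drops time–frequency cells below the cone of
    influence (the conservative variant); the default includes all columns.
    """
    in_band = (c.freqs >= f_lo) & (c.freqs <= f_hi)
    if not in_band.any():
        raise ValidationError(f"no scale rows inside [{f_lo}, {f_hi}] Hz")
    sub = c.wc[in_band]
    if not coi_exclude:
        return float(sub.mean())
    valid = c.freqs[in_band][:, None] >= c.coi[None, :]
    if not valid.any():
        raise ValidationError("cone of influence excludes the whole band")
    return float(sub[valid].mean())


def _band_rows_grid(band: tuple[float, float], voices: int,
                    f_max: float) -> tuple[float, float]:
    """Reduced scale grid covering the band plus the scale-smoothing margin.

    Rows are drawn from the same dyadic family as the full grid (anchored at
    ``f_max``), extended ~4 voices beyond each band edge so the boxcar
    windows of the in-band rows are complete; the in-band WC values are then
    identical to the full-grid computation.
    """
    margin = 4.0 / voices
    lo = band[0] * 2.0 ** (-margin)
    hi = band[1] * 2.0 ** margin
    # anchor the top row on the full grid's dyadic family
    k = math.floor(voices * math.log2(f_max / hi))
    hi_anchor = f_max * 2.0 ** (-k / voices)
    return lo, min(hi_anchor, f_max)


def _band_mean_fast(
    xa: np.ndarray, ya: np.ndarray, plan: _Plan, band: tuple[float, float]
) -> float:
    wc = _coherence_fields(xa, ya, plan, smoothing=True)
    in_band = (plan.freqs >= band[0]) & (plan.freqs <= band[1])
    return float(np.clip(wc[in_band], 0.0, 1.0).mean())


def surrogate_null(
    x: MagnitudeSeries,
    y: MagnitudeSeries,
    n_iter: int = 1000,
    seed: int = 0,
    band: tuple[float, float] = (BAND_LO_HZ, BAND_HI_HZ),
    voices: int = DEFAULT_VOICES,
    omega0: float = DEFAULT_OMEGA0,
    method: str = "permutation",
) -> SurrogateNull:
    """Shuffled-surrogate null for the band-averaged coherence.

    Each iteration independently scrambles both series and records the band
    mean; the observed value comes from the unscrambled inputs. The default
    ``method="permutation"`` fully permutes the samples (destroying all
    temporal structure, hence whitening the surrogates);
    ``method="phase"`` randomizes Fourier phases instead, preserving each
    series' amplitude spectrum — the appropriate null when the question is
    cross-series phase coupling rather than any temporal structure at all.
    The scale grid is restricted to the band plus smoothing margin, which
    leaves the in-band values identical to the full-grid computation.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be ≥ 1")
    if method not in ("permutation", "phase"):
        raise ValidationError(f"unknown surrogate method {method!r}")
    xa, ya = _check_series(x), _check_series(y)
    if len(xa) != len(ya) or x.fs != y.fs:
        raise ValidationError("inputs must share length and sampling rate")
    if np.std(xa) == 0.0 or np.std(ya) == 0.0:
        raise ValidationError("constant input: coherence undefined")
    f_lo, f_hi = _band_rows_grid(band, voices, DEFAULT_F_MAX)
    plan = _get_plan(len(xa), x.fs, f_lo, f_hi, voices, omega0)
    observed = _band_mean_fast(xa, ya, plan, band)
    rng = np.random.default_rng(seed)
    if method == "permutation":
        def _scramble(v: np.ndarray) -> np.ndarray:
            return rng.permutation(v)
    else:
        def _scramble(v: np.ndarray) -> np.ndarray:
            vf = np.fft.rfft(v)
            phases = np.exp(2j * np.pi * rng.uniform(size=len(vf)))
            phases[0] = 1.0  # keep the mean
            if len(v) % 2 == 0:
                phases[-1] = 1.0  # Nyquist bin must stay real
            return np.fft.irfft(vf * phases, len(v))

    nulls = np.empty(n_iter)
    for i in range(n_iter):
        nulls[i] = _band_mean_fast(_scramble(xa), _scramble(ya), plan, band)
    return SurrogateNull(observed, nulls, n_iter, seed)


def group_null_test(
    observed: np.ndarray, null_means: np.ndarray
) -> tuple[float, float]:
    """Paired two-sided t-test of per-visit observed vs mean-null coherence."""
    observed = np.asarray(observed, dtype=float)
    null_means = np.asarray(null_means, dtype=float)
    if observed.shape != null_means.shape or observed.ndim != 1:
        raise ValidationError("observed and null_means must be equal-length vectors")
    n = len(observed)
    if n < 2:
        raise ValidationError("need at least 2 paired visits")
    d = observed - null_means
    sd = d.std(ddof=1)
    if sd <= 1e-12 * max(float(np.abs(d).max()), 1e-300):
        if d.mean() == 0.0:
            return 0.0, 1.0
        warnings.warn("zero-variance nonzero differences: degenerate paired test")
        return math.copysign(math.inf, d.mean()), 0.0
    from scipy.stats import ttest_rel

    t, p = ttest_rel(observed, null_means)
    return float(t), float(p)


def single_hand_spectrum(
    m: MagnitudeSeries, **cwt_kwargs
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged wavelet power per frequency for one arm: (freqs, power)."""
    res = cwt(m, **cwt_kwargs)
    power = (res.coeffs.real**2 + res.coeffs.imag**2).mean(axis=1)
    return res.freqs, power
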