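"""Raw tri-axial streams → smoothed one-dimensional magnitude.

Fixed stage order: cubic-spline interpolation of missing samples (per axis),
then the Euclidean norm Acc(t) = sqrt(ax² + ay² + az²), then a third-order
median filter that replaces each value with the median of its three-sample
neighborhood (zero-padded at the edges, matching MATLAB's ``medfilt1``).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import medfilt

from .containers import (
    AccelTimeSeries,
    MagnitudeSeries,
    Provenance,
    ValidationError,
)

__all__ = ["interpolate_missing", "magnitude", "median_smooth", "preprocess_sensor"]


def interpolate_missing(s: AccelTimeSeries) -> AccelTimeSeries:
    """Fill missing grid slots by per-axis cubic-spline interpolation.

    Known samples pass through bit-for-bit. Leading/trailing missing runs are
    filled by nearest-known-value extension rather than spline extrapolation
    (cubic extrapolation diverges; session endpoints are never analyzed).

    Raises
    ------
    ValidationError
        If fewer than 4 known samples are available on an axis.
    """
    if not s.has_missing:
        return s.copy()
    known = ~s.missing_mask
    if int(known.sum()) < 4:
        raise ValidationError("cubic interpolation needs at least 4 known samples")
    out = s.copy()
    t_known = s.t[known]
    first, last = t_known[0], t_known[-1]
    interior_missing = s.missing_mask & (s.t >= first) & (s.t <= last)
    for name in ("ax", "ay", "az"):
        vals = getattr(s, name)
        spline = CubicSpline(t_known, vals[known])
        filled = vals.copy()
        filled[interior_missing] = spline(s.t[interior_missing])
        # nearest-value extension for runs outside the known span
        lead = s.missing_mask & (s.t < first)
        trail = s.missing_mask & (s.t > last)
        filled[lead] = vals[known][0]
        filled[trail] = vals[known][-1]
        setattr(out, name, filled)
    out.missing_mask = np.zeros(len(s), dtype=bool)
    return out


def magnitude(s: AccelTimeSeries) -> MagnitudeSeries:
    """Pointwise Euclidean norm of the three axes (normalized acceleration)."""
    if s.has_missing:
        raise ValidationError("series has missing samples; run interpolate_missing first")
    acc = np.sqrt(s.ax**2 + s.ay**2 + s.az**2)
    return MagnitudeSeries(s.t, acc, s.fs, Provenance.RAW_NORM)


def median_smooth(m: MagnitudeSeries) -> MagnitudeSeries:
    """Third-order median filter; edges treated as zero-padded."""
    if len(m) < 3:
        raise ValidationError("median_smooth needs at least 3 samples")
    return m.with_acc(medfilt(m.acc, kernel_size=3), Provenance.SMOOTHED)


def preprocess_sensor(s: AccelTimeSeries) -> MagnitudeSeries:
    """Full stage: interpolate → magnitude → median smooth."""
    return median_smooth(magnitude(interpolate_missing(s)))
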