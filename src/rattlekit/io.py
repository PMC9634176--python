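"""Text-format readers and writers.

Supported formats (all plain text):

* sensor streams — CSV with columns ``time_s,ax,ay,az``, one file per arm;
* annotation tracks — the tab-delimited dialect that ELAN exports
  (``tier<TAB>onset_s<TAB>offset_s<TAB>label``); native .eaf XML is out of
  scope;
* visit summaries — CSV with one row per visit × condition.

Annotation times are on the *video* clock; conversion to the sensor clock
happens exclusively in :mod:`rattlekit.sync`.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .containers import (
    AccelTimeSeries,
    AnnotationTrack,
    Condition,
    Interval,
    Tier,
    ValidationError,
)

__all__ = [
    "read_sensor",
    "write_sensor",
    "read_annotations",
    "write_annotations",
    "read_visit_summary",
    "write_visit_summary",
    "SUMMARY_COLUMNS",
]

_SENSOR_COLUMNS = ["time_s", "ax", "ay", "az"]

#: Visit-summary columns; metric names mirror the descriptive table of the study
#: (episode counts, mean episode duration, movement counts, rattling frequency,
#: band-averaged wavelet coherence).
SUMMARY_COLUMNS = [
    "visit_id",
    "condition",
    "n_rattling_episodes",
    "mean_episode_duration_s",
    "n_rattling_movements",
    "rattling_frequency_hz",
    "wavelet_coherence",
    "excluded",
]


def read_sensor(path: str | os.PathLike, fs_expected: float) -> AccelTimeSeries:
    """Read one arm's tri-axial stream onto a uniform 1/fs grid.

    Gaps in the time column become ``missing_mask=True`` slots; sample values
    there are NaN until :func:`rattlekit.preprocess.interpolate_missing`.

    Raises
    ------
    ValidationError
        If the time column is non-monotone, the header is wrong, or the
        file's sampling rate differs from ``fs_expected`` by more than 1%.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in _SENSOR_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"sensor file {path} lacks columns {missing_cols}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValidationError(f"sensor file {path} has fewer than 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise ValidationError(
            f"non-monotone time column at row {i + 1}: {t[i]} -> {t[i + 1]}"
        )
    # Infer the file's rate from the smallest step (gaps are larger multiples).
    fs_file = 1.0 / float(np.min(dt))
    if abs(fs_file - fs_expected) > 0.01 * fs_expected:
        raise ValidationError(
            f"sampling-rate mismatch: file ≈ {fs_file:.3f} Hz, expected {fs_expected} Hz"
        )
    step = 1.0 / fs_expected
    n = int(round((t[-1] - t[0]) / step)) + 1
    grid = t[0] + np.arange(n) * step
    idx = np.round((t - t[0]) / step).astype(int)
    if np.any(np.diff(idx) <= 0):
        raise ValidationError("two samples map to the same grid slot")
    missing = np.ones(n, dtype=bool)
    missing[idx] = False
    axes = {}
    for name in ("ax", "ay", "az"):
        col = np.full(n, np.nan)
        col[idx] = df[name].to_numpy(dtype=float)
        axes[name] = col
    return AccelTimeSeries(grid, axes["ax"], axes["ay"], axes["az"], fs_expected, missing)


def write_sensor(series: AccelTimeSeries, path: str | os.PathLike) -> None:
    """Write a sensor stream as CSV, omitting missing grid slots."""
    keep = ~series.missing_mask
    pd.DataFrame(
        {
            "time_s": series.t[keep],
            "ax": series.ax[keep],
            "ay": series.ay[keep],
            "az": series.az[keep],
        }
    ).to_csv(path, index=False)


_TIER_NAMES = {t.value: t for t in Tier}
_CONDITION_NAMES = {c.value: c for c in Condition}


def read_annotations(path: str | os.PathLike) -> AnnotationTrack:
    """Read a tab-delimited annotation export (tier, onset_s, offset_s, label).

    Labels on the RATTLING tier must be one of the two condition strings
    ("Mother Not Providing Rhythm" / "Mother Providing Rhythm"); CLAP rows
    leave the label empty. Rows may appear in any order; the returned track
    is sorted by onset, and same-tier overlap is rejected.
    """
    intervals: list[Interval] = []
    with open(path, "r", encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if ln == 1 and parts[0].strip().lower() == "tier":
                continue  # optional header
            if len(parts) < 3:
                raise ValidationError(f"{path}:{ln}: expected ≥3 tab-separated fields")
            tier_name = parts[0].strip()
            if tier_name not in _TIER_NAMES:
                raise ValidationError(f"{path}:{ln}: unknown tier {tier_name!r}")
            onset, offset = float(parts[1]), float(parts[2])
            label_str = parts[3].strip() if len(parts) > 3 else ""
            label: Optional[Condition] = None
            if label_str:
                if label_str not in _CONDITION_NAMES:
                    raise ValidationError(f"{path}:{ln}: unknown label {label_str!r}")
                label = _CONDITION_NAMES[label_str]
            intervals.append(Interval(_TIER_NAMES[tier_name], onset, offset, label))
    return AnnotationTrack(intervals)


def write_annotations(track: AnnotationTrack, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tier\tonset_s\toffset_s\tlabel\n")
        for iv in track.intervals:
            label = iv.label.value if iv.label is not None else ""
            fh.write(
                f"{iv.tier.value}\t{float(iv.onset_s)!r}\t{float(iv.offset_s)!r}\t{label}\n"
            )


def write_visit_summary(rows: Iterable[dict], path: str | os.PathLike) -> None:
    """Write per-visit × condition metrics as CSV (header-only if empty)."""
    df = pd.DataFrame(list(rows), columns=SUMMARY_COLUMNS)
    df.to_csv(path, index=False)


def read_visit_summary(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"summary file {path} lacks columns {missing}")
    return df
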