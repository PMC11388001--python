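"""Heatwave detection from station daily-maximum temperature series.

The detection cascade mirrors a station-climatology approach: a threshold is
set as the summer (JJA) mean of the across-station-averaged daily maximum
temperature; days strictly above it are hot days; maximal runs of consecutive
hot days extending beyond five days are heatwave cases; the severe subset for
simulation keeps cases whose peak exceeds 35.1 degC and whose duration
extends beyond 14 days.  Each selected event gets a 96-hour simulation window
centred on its peak day at a fixed peak hour (21 UTC, i.e. mid-afternoon in
Houston).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HeatwaveEvent",
    "climatological_threshold",
    "detect_events",
    "select_severe",
    "wmo_check",
    "simulation_window",
    "events_to_jsonl",
    "events_table",
]

JJA = (6, 7, 8)


@dataclass
class HeatwaveEvent:
    """A detected heat episode and (optionally) its simulation window."""

    start_date: pd.Timestamp
    end_date: pd.Timestamp
    duration: int
    peak_tmax: float
    peak_date: pd.Timestamp
    window_start: Optional[pd.Timestamp] = field(default=None)
    window_end: Optional[pd.Timestamp] = field(default=None)

    def __post_init__(self) -> None:
        if self.duration != (self.end_date - self.start_date).days + 1:
            raise ValueError("duration inconsistent with start/end dates")
        if not (self.start_date <= self.peak_date <= self.end_date):
            raise ValueError("peak_date must lie within [start_date, end_date]")


def climatological_threshold(series: Sequence[pd.Series] | pd.Series,
                             years: Optional[tuple[int, int]] = None,
                             season: Iterable[int] = JJA,
                             max_missing_frac: float = 0.0) -> float:
    """Seasonal-mean of the station-averaged daily maximum temperature.

    Parameters
    ----------
    series
        One or more daily-maximum series indexed by date (one per station).
        ``urbanheat.synth.StationSeries`` objects are accepted.
    years
        Inclusive (first, last) calendar-year range; default: all years.
    season
        Months defining the season, default June-July-August.
    max_missing_frac
        Tolerated fraction of missing station-days within the selection;
        exceeding it raises ``ValueError`` (default: fail on any gap).
    """
    if isinstance(series, pd.Series):
        series = [series]
    cols = [getattr(s, "data", s) for s in series]
    if len(cols) == 0:
        raise ValueError("at least one station series required")
    months = set(season)
    if not months:
        raise ValueError("season must be non-empty")
    df = pd.concat(cols, axis=1, join="outer")
    sel = df[df.index.month.isin(months)]
    if years is not None:
        sel = sel[(sel.index.year >= years[0]) & (sel.index.year <= years[1])]
    if sel.empty:
        raise ValueError("no data in the requested season/years")
    missing = float(sel.isna().to_numpy().mean())
    if missing > max_missing_frac:
        raise ValueError(
            f"{missing:.1%} of station-days missing exceeds tolerance {max_missing_frac:.1%}"
        )
    return float(sel.mean(axis=1).mean())


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs (stop exclusive)."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_events(avg_tmax: pd.Series, threshold: float,
                  min_run: int = 6) -> list[HeatwaveEvent]:
    """Maximal runs of consecutive days with tmax strictly above threshold.

    ``avg_tmax`` must be a contiguous daily series (station-averaged daily
    maximum temperature).  Runs lasting at least ``min_run`` days (default 6,
    i.e. episodes extending beyond 5 days) are returned as events; shorter
    exceedance runs are discarded.  Events separated by even a single
    non-exceedance day are never merged.
    """
    s = getattr(avg_tmax, "data", avg_tmax)
    idx = pd.DatetimeIndex(s.index)
    if len(s) > 1:
        deltas = np.diff(idx.values).astype("timedelta64[D]")
        if not np.all(deltas == np.timedelta64(1, "D")):
            raise ValueError("avg_tmax must be a contiguous daily series")
    mask = (s.to_numpy() > threshold)
    events = []
    for i, j in _runs(mask):
        if j - i < min_run:
            continue
        chunk = s.iloc[i:j]
        peak_pos = int(np.argmax(chunk.to_numpy()))
        events.append(HeatwaveEvent(
            start_date=idx[i],
            end_date=idx[j - 1],
            duration=j - i,
            peak_tmax=float(chunk.iloc[peak_pos]),
            peak_date=idx[i + peak_pos],
        ))
    return events


def select_severe(events: Sequence[HeatwaveEvent], min_peak: float = 35.1,
                  min_duration: int = 14) -> list[HeatwaveEvent]:
    """Keep events with peak strictly above ``min_peak`` degC and duration
    strictly beyond ``min_duration`` days."""
    return [e for e in events
            if e.peak_tmax > min_peak and e.duration > min_duration]


def wmo_check(event_window_tmax: pd.Series, avg_daily_max: float,
              delta: float = 5.0, min_run: int = 6) -> bool:
    """WMO heatwave test: more than 5 consecutive days exceeding the average
    daily maximum temperature by ``delta`` K.

    With Houston's average daily maximum of 25.6 degC and delta = 5 the
    exceedance level is 30.6 degC.
    """
    s = getattr(event_window_tmax, "data", event_window_tmax)
    mask = (s.to_numpy() > avg_daily_max + delta)
    return any(j - i >= min_run for i, j in _runs(mask))


def simulation_window(event: HeatwaveEvent, peak_hour_utc: int = 21,
                      half_width_h: int = 48) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Simulation window of +/- ``half_width_h`` hours around the event peak.

    The peak is anchored at ``peak_hour_utc`` (default 21Z, mid-afternoon
    local time in Houston) on the event's peak day.  The window is stored on
    the event and returned; it may extend before the event start.
    """
    peak = event.peak_date.normalize() + pd.Timedelta(hours=peak_hour_utc)
    start = peak - pd.Timedelta(hours=half_width_h)
    end = peak + pd.Timedelta(hours=half_width_h)
    event.window_start = start
    event.window_end = end
    return start, end


def events_to_jsonl(events: Sequence[HeatwaveEvent], path) -> None:
    """Write events as JSON lines (start, end, duration, peak, window)."""
    with open(path, "w") as fh:
        for e in events:
            fh.write(json.dumps({
                "start_date": str(e.start_date.date()),
                "end_date": str(e.end_date.date()),
                "duration": e.duration,
                "peak_tmax": e.peak_tmax,
                "peak_date": str(e.peak_date.date()),
                "window_start": e.window_start.isoformat() if e.window_start is not None else None,
                "window_end": e.window_end.isoformat() if e.window_end is not None else None,
            }) + "\n")


def events_table(events: Sequence[HeatwaveEvent]) -> str:
    """Human-readable event table."""
    rows = [f"{'start':>10} {'end':>10} {'days':>4} {'peak':>6} {'peak date':>10}"]
    for e in events:
        rows.append(f"{e.start_date.date()!s:>10} {e.end_date.date()!s:>10} "
                    f"{e.duration:>4d} {e.peak_tmax:>6.1f} {e.peak_date.date()!s:>10}")
    return "\n".join(rows)
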