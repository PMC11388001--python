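"""Cumulative heat-stress and equity metrics.

The exposure chain is: hourly heat-stress exceedance ``HS_t = max(UTCI - 26, 0)``
(K); its sum over a local day's 24 hours, the daily cumulative heat stress
DCH (K h); the mean of DCH over all simulated days and heatwave events,
ADCH (K h); and the vulnerability-weighted percent change

    VDCH_i = w * SVI * (ADCH_i - ADCH_CTL) / ADCH_CTL * 100  (%)

which weights each cell's relative heat-stress change by its social
vulnerability, so that equal cooling is rewarded more where vulnerability is
high.  Negative VDCH means improved community heat-stress resilience.

The module also provides the two interpretive equivalences used to give a
percent ADCH change a physical meaning (equivalent cooling depth over a day,
or equivalent minutes of exposure removed at a fixed UTCI), the SVI-binned
curve of ADCH changes with interquartile spread, and urban-averaged VDCH
summaries by whole-day/daytime/nighttime period.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "heat_stress",
    "daily_cumulative",
    "dch_by_day",
    "adch",
    "vdch",
    "required_adch_change",
    "duration_equivalent",
    "cooling_equivalent_pct",
    "adch_change_by_svi_bins",
    "urban_average_vdch",
]

HEAT_STRESS_THRESHOLD = 26.0  # degC UTCI, onset of heat stress


def heat_stress(utci, threshold: float = HEAT_STRESS_THRESHOLD):
    """Hourly heat-stress exceedance HS = max(UTCI - threshold, 0) in K."""
    out = np.maximum(np.asarray(utci, dtype=float) - threshold, 0.0)
    return out if out.ndim else float(out)


def daily_cumulative(hs_hourly) -> float | np.ndarray:
    """Daily cumulative heat stress DCH (K h): sum of one local day's 24
    hourly exceedances.

    The day is represented by 24 hourly samples (t = 0..23); a 25th sample
    would double-count midnight.  Input may have shape (..., 24); the sum is
    over the last axis.
    """
    hs = np.asarray(hs_hourly, dtype=float)
    if hs.shape[-1] != 24:
        raise ValueError(f"expected 24 hourly values per day, got {hs.shape[-1]}")
    if np.any(hs < 0.0):
        raise ValueError("heat-stress values must be >= 0")
    out = hs.sum(axis=-1)
    return out if out.ndim else float(out)


def dch_by_day(utci, times: pd.DatetimeIndex, threshold: float = HEAT_STRESS_THRESHOLD,
               hour_mask: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-day, per-cell cumulative heat stress from an hourly UTCI array.

    Parameters
    ----------
    utci : array (time, cell)
        Hourly midrange UTCI in degC.
    times : DatetimeIndex
        Hourly local timestamps matching the first axis.
    hour_mask : bool array (time,), optional
        Restricts the accumulation to selected hours (e.g. daytime hours with
        positive downwelling shortwave); by default all 24 hours count.

    Returns
    -------
    DataFrame indexed by date with one column per cell, values in K h.
    """
    u = np.asarray(utci, dtype=float)
    if u.shape[0] != len(times):
        raise ValueError("time axis mismatch")
    hs = heat_stress(u, threshold=threshold)
    if hour_mask is not None:
        hs = hs * np.asarray(hour_mask, dtype=float)[:, None]
    df = pd.DataFrame(hs, index=pd.DatetimeIndex(times))
    return df.groupby(df.index.normalize()).sum()


def adch(dch_by_day_event, n_events: Optional[int] = None,
         n_days: Optional[int] = None):
    """Averaged DCH: arithmetic mean over all simulated days and events.

    ``dch_by_day_event`` is a complete (event x day) table — a 2-D array or
    DataFrame, or for per-cell use an (event, day, cell) array averaged over
    the first two axes.  Missing cells raise ``ValueError``.
    """
    arr = np.asarray(getattr(dch_by_day_event, "values", dch_by_day_event), dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("day x event table contains missing values")
    if n_events is not None and arr.shape[0] != n_events:
        raise ValueError(f"expected {n_events} events, got {arr.shape[0]}")
    if n_days is not None and arr.ndim >= 2 and arr.shape[1] != n_days:
        raise ValueError(f"expected {n_days} days, got {arr.shape[1]}")
    if arr.ndim <= 2:
        return float(arr.mean())
    return arr.mean(axis=(0, 1))


def vdch(adch_i, adch_ctl, svi, w: float = 1.0):
    """Vulnerability-weighted percent change of ADCH relative to control.

    Returns ``w * svi * (adch_i - adch_ctl) / adch_ctl * 100`` (%).  Cells
    with ``adch_ctl == 0`` have no heat stress to mitigate and return 0 with
    a warning.
    """
    ai = np.asarray(adch_i, dtype=float)
    ac = np.asarray(adch_ctl, dtype=float)
    sv = np.asarray(svi, dtype=float)
    if np.any((sv < 0.0) | (sv > 1.0)):
        raise ValueError("svi must lie in [0, 1]")
    zero = ac == 0.0
    if np.any(zero):
        warnings.warn("ADCH_CTL = 0 in some cells; VDCH set to 0 there (no heat "
                      "stress to mitigate)", stacklevel=2)
    safe_ac = np.where(zero, 1.0, ac)
    out = np.where(zero, 0.0, w * sv * (ai - ac) / safe_ac * 100.0)
    return out if out.ndim else float(out)


def required_adch_change(target_vdch, svi, w: float = 1.0):
    """ADCH percent change needed to reach ``target_vdch`` at a given SVI.

    Inverts the VDCH definition: returns ``target_vdch / (w * svi)`` (%).
    A target of -1 % at SVI = 0.1 (w = 1) requires a -10 % ADCH change; at
    SVI = 1 it requires only -1 %.  Unreachable at svi = 0.
    """
    sv = np.asarray(svi, dtype=float)
    if w <= 0.0:
        raise ValueError("w must be > 0")
    if np.any(sv <= 0.0):
        raise ValueError("target unreachable where svi <= 0")
    out = np.asarray(target_vdch, dtype=float) / (w * sv)
    return out if out.ndim else float(out)


def duration_equivalent(dch: float, pct_reduction: float, utci_level: float,
                        threshold: float = HEAT_STRESS_THRESHOLD) -> float:
    """Minutes of exposure at a fixed UTCI equivalent to a percent DCH cut.

    A ``pct_reduction`` % decrease of ``dch`` expressed as a shortened
    duration while maintaining ``utci_level``:
    minutes = pct/100 * dch / (utci_level - threshold) * 60.
    E.g. 2 % of a 336 K h day at UTCI 40 degC is 28.8 min.
    """
    if utci_level <= threshold:
        raise ValueError("utci_level must exceed the heat-stress threshold")
    return pct_reduction / 100.0 * dch / (utci_level - threshold) * 60.0


def cooling_equivalent_pct(dch: float, delta_utci: float, hours: float) -> float:
    """Percent DCH reduction equivalent to sustained cooling by ``delta_utci``
    K over ``hours`` hours: 100 * delta_utci * hours / dch.

    E.g. cooling 24 h from UTCI 40 to 39.7 degC against a 336 K h day is a
    ~2 % reduction.
    """
    if dch == 0.0:
        raise ValueError("dch must be nonzero")
    return 100.0 * delta_utci * hours / dch


def adch_change_by_svi_bins(adch_change_pct, svi,
                            bins: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Median and interquartile range of ADCH percent change per SVI bin.

    Default bins are the deciles of [0, 1], so the extreme bins are the
    resilient (SVI < 0.1) and vulnerable (SVI > 0.9) neighbourhoods.  Bins
    are left-closed, with the last bin also right-closed.  Empty bins appear
    with NaN statistics (missing, not zero).

    Returns a DataFrame with columns bin_left, bin_right, n, median, q25, q75.
    """
    ch = np.asarray(adch_change_pct, dtype=float)
    sv = np.asarray(svi, dtype=float)
    if ch.shape != sv.shape:
        raise ValueError("adch_change_pct and svi must align")
    edges = np.asarray(bins if bins is not None else np.linspace(0.0, 1.0, 11), dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bins must be increasing edges")
    idx = np.digitize(sv, edges[1:-1], right=False)  # 0..nbins-1
    rows = []
    for k in range(len(edges) - 1):
        vals = ch[idx == k]
        if len(vals):
            rows.append((edges[k], edges[k + 1], len(vals),
                         float(np.median(vals)),
                         float(np.percentile(vals, 25)),
                         float(np.percentile(vals, 75))))
        else:
            rows.append((edges[k], edges[k + 1], 0, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "n",
                                       "median", "q25", "q75"])


def urban_average_vdch(vdch_per_cell, urban_mask) -> float:
    """Mean VDCH (%) over urban cells.

    Non-urban cells are excluded entirely; an empty mask is an error.
    Period resolution (whole day / daytime / nighttime) is handled upstream
    by computing ADCH over the period's hours before forming VDCH.
    """
    v = np.asarray(vdch_per_cell, dtype=float)
    m = np.asarray(urban_mask, dtype=bool)
    if v.shape != m.shape:
        raise ValueError("vdch_per_cell and urban_mask must align")
    if not m.any():
        raise ValueError("urban mask selects no cells")
    return float(v[m].mean())
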