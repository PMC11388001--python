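"""Universal Thermal Climate Index (UTCI) for pedestrian thermal comfort.

UTCI expresses the thermal load on a walking reference person as an
equivalent temperature.  The operational approximation is a complete
sixth-order polynomial in air temperature, water vapour pressure, 10-m wind
speed and the radiant excess ``Tmrt - Ta``; its published 210 coefficients
are vendored in :mod:`urbanheat._utci_coeffs` and evaluated here in a
vectorised form.

Because wind varies below the resolution of a gridded forcing product, a
per-cell distribution of UTCI is inferred by evaluating the polynomial across
quantiles of a subgrid wind distribution; its 10th/50th/90th percentiles are
the "cool spot", "midrange" and "hot spot" values.  The midrange feeds all
downstream heat-stress metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from ._utci_coeffs import UTCI_COEFFS, UTCI_EXPONENTS

__all__ = [
    "ComfortInputs",
    "saturation_vapor_pressure",
    "utci",
    "utci_percentiles",
    "utci_field",
]

logger = logging.getLogger(__name__)

# published validity domain of the operational polynomial
TA_RANGE = (-50.0, 50.0)
VA_RANGE = (0.5, 17.0)
DTMRT_RANGE = (-30.0, 70.0)
PA_MAX_KPA = 5.0

# saturation vapour pressure over water, ITS-90 formulation bundled with the
# UTCI operational procedure (Hardy 1998); es in Pa from T in K
_ES_G = (
    -2.8365744e3,
    -6.028076559e3,
    1.954263612e1,
    -2.737830188e-2,
    1.6261698e-5,
    7.0229056e-10,
    -1.8680009e-13,
)


@dataclass(frozen=True)
class ComfortInputs:
    """Scalar or array drivers of UTCI.

    ta: 2-m air temperature (degC); rh: 2-m relative humidity (%);
    va10: 10-m wind speed (m/s); tmrt: mean radiant temperature (degC).
    """

    ta: np.ndarray
    rh: np.ndarray
    va10: np.ndarray
    tmrt: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ta", "rh", "va10", "tmrt"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any((self.rh < 0.0) | (self.rh > 100.0)):
            raise ValueError("rh must lie in [0, 100] %")
        if np.any(self.va10 < 0.0):
            raise ValueError("va10 must be >= 0")


def saturation_vapor_pressure(ta) -> np.ndarray:
    """Saturation water-vapour pressure over water (hPa) at ``ta`` degC.

    Uses the ITS-90-based formulation distributed with the UTCI operational
    procedure; es(0 degC) is approximately 6.11 hPa and es is strictly
    increasing in temperature.
    """
    tk = np.asarray(ta, dtype=float) + 273.15
    if np.any(tk <= 0.0):
        raise ValueError("temperature below 0 K")
    es = 2.7150305 * np.log(tk)
    for i, g in enumerate(_ES_G):
        es = es + g * tk ** (i - 2)
    out = np.exp(es) * 0.01  # Pa -> hPa
    return out if out.ndim else float(out)


def _clamp(arr: np.ndarray, lo: float, hi: float, name: str) -> np.ndarray:
    if np.any(arr < lo) or np.any(arr > hi):
        logger.warning("%s outside UTCI polynomial domain [%g, %g]; clamping", name, lo, hi)
        return np.clip(arr, lo, hi)
    return arr


def _polynomial_offset(ta: np.ndarray, va: np.ndarray, dtmrt: np.ndarray,
                       pa_kpa: np.ndarray) -> np.ndarray:
    """Evaluate the 210-term offset polynomial (UTCI - Ta, in K)."""
    # precompute powers 0..6 of each driver once, then accumulate monomials
    shape = np.broadcast(ta, va, dtmrt, pa_kpa).shape
    powers = {}
    for key, arr in (("t", ta), ("v", va), ("d", dtmrt), ("p", pa_kpa)):
        a = np.broadcast_to(np.asarray(arr, dtype=float), shape)
        pw = np.empty((7,) + shape)
        pw[0] = 1.0
        for k in range(1, 7):
            pw[k] = pw[k - 1] * a
        powers[key] = pw
    off = np.zeros(shape)
    for c, (t, v, d, p) in zip(UTCI_COEFFS, UTCI_EXPONENTS):
        off += c * powers["t"][t] * powers["v"][v] * powers["d"][d] * powers["p"][p]
    return off


def utci(inputs: ComfortInputs | None = None, *, ta=None, rh=None, va10=None,
         tmrt=None, clamp: bool = True) -> np.ndarray:
    """UTCI (degC) from air temperature, humidity, wind and MRT.

    Accepts either a :class:`ComfortInputs` or the four drivers as keyword
    arguments; all broadcast together.  Inputs outside the published validity
    domain (ta in [-50, 50] degC, va in [0.5, 17] m/s, tmrt - ta in
    [-30, 70] K, vapour pressure <= 5 kPa) are clamped with a logged warning
    when ``clamp`` is true, else rejected.
    """
    if inputs is None:
        inputs = ComfortInputs(ta=ta, rh=rh, va10=va10, tmrt=tmrt)
    ta_, rh_, va_, tmrt_ = inputs.ta, inputs.rh, inputs.va10, inputs.tmrt
    if not (np.all(np.isfinite(ta_)) and np.all(np.isfinite(rh_))
            and np.all(np.isfinite(va_)) and np.all(np.isfinite(tmrt_))):
        raise ValueError("non-finite input to utci")
    pa_kpa = saturation_vapor_pressure(ta_) * rh_ / 100.0 / 10.0  # hPa -> kPa
    dtmrt = np.asarray(tmrt_) - np.asarray(ta_)
    if clamp:
        ta_ = _clamp(np.asarray(ta_, dtype=float), *TA_RANGE, name="ta")
        va_ = _clamp(np.asarray(va_, dtype=float), *VA_RANGE, name="va10")
        dtmrt = _clamp(np.asarray(dtmrt, dtype=float), *DTMRT_RANGE, name="tmrt - ta")
        pa_kpa = _clamp(np.asarray(pa_kpa, dtype=float), 0.0, PA_MAX_KPA, name="vapour pressure")
    else:
        for arr, (lo, hi), name in ((ta_, TA_RANGE, "ta"), (va_, VA_RANGE, "va10"),
                                    (dtmrt, DTMRT_RANGE, "tmrt - ta"),
                                    (pa_kpa, (0.0, PA_MAX_KPA), "vapour pressure")):
            if np.any(np.asarray(arr) < lo) or np.any(np.asarray(arr) > hi):
                raise ValueError(f"{name} outside UTCI polynomial domain")
    out = np.asarray(ta_) + _polynomial_offset(ta_, va_, dtmrt, pa_kpa)
    return out if out.ndim else float(out)


def utci_percentiles(ta, rh, va10, tmrt, wind_sigma: float = 0.4,
                     quantiles=(0.1, 0.5, 0.9)) -> tuple[np.ndarray, ...]:
    """Cool-spot / midrange / hot-spot UTCI from subgrid wind variability.

    The subgrid wind is modelled as lognormal with median ``va10`` and
    log-standard-deviation ``wind_sigma`` (dimensionless; 0 collapses the
    distribution to the point value).  The polynomial is evaluated at the
    wind quantiles matching ``quantiles`` and the results are sorted
    point-wise, so the returned triple is guaranteed non-decreasing:
    under hot radiant load UTCI falls with wind, hence the hot spot is the
    low-wind tail.

    Returns the tuple of UTCI arrays, one per requested quantile, ascending.
    """
    if wind_sigma < 0.0:
        raise ValueError("wind_sigma must be >= 0")
    qs = sorted(quantiles)
    va = np.asarray(va10, dtype=float)
    vals = []
    for q in qs:
        wind = va * np.exp(wind_sigma * ndtri(q)) if wind_sigma > 0.0 else va
        vals.append(np.asarray(utci(ta=ta, rh=rh, va10=wind, tmrt=tmrt)))
    stacked = np.sort(np.stack(vals, axis=0), axis=0)
    return tuple(stacked[i] for i in range(len(qs)))


def utci_field(met, wind_sigma: float = 0.4):
    """Attach utci_p10/p50/p90 variables to a meteorological field.

    ``met`` is an :class:`xarray.Dataset` (or an object with a ``.ds``
    Dataset attribute) with variables t2, rh2, ws10 and mrt over (time, cell).
    Returns a new Dataset with the three percentile variables added.
    """
    ds = getattr(met, "ds", met)
    p10, p50, p90 = utci_percentiles(
        ds["t2"].values, ds["rh2"].values, ds["ws10"].values, ds["mrt"].values,
        wind_sigma=wind_sigma,
    )
    out = ds.copy()
    dims = ds["t2"].dims
    for name, arr in (("utci_p10", p10), ("utci_p50", p50), ("utci_p90", p90)):
        out[name] = (dims, arr)
        out[name].attrs["units"] = "degC"
    return out
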