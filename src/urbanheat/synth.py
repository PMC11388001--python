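"""Seeded synthetic inputs for the heat-equity pipeline.

Every downstream stage (heatwave detection, scenario perturbation, UTCI,
equity metrics) is testable without any download: this module generates

* station daily-maximum temperature series with a seasonal cycle and
  optionally embedded exceedance runs (for the detection cascade);
* abstract urban grids whose statistical structure mirrors Houston —
  street fraction rising from ~30 % in resilient (low-SVI) to ~40 % in
  vulnerable (high-SVI) neighbourhoods, control tree cover declining with
  SVI, and a tree-equity target that adds more canopy where SVI is high;
* hourly sinusoid-plus-noise meteorological forcing over the grid with a
  clipped solar-elevation shortwave curve; and
* surrogate scenario perturbations emulating the mesoscale response to cool
  roofs, green roofs and street trees.  The roof strategies perturb 2-m
  temperature (and humidity) in proportion to roof fraction and insolation;
  the tree strategy perturbs mean radiant temperature through the canopy
  interception scheme in proportion to added canopy and street fraction.
  These effect models are deliberately simple, transparent surrogates for
  urban-canopy physics, with magnitudes chosen to reproduce the 0.2-0.3 K
  urban-average daytime UTCI responses typical of such strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .canopy import CanopyParams, mrt_adjustment, sw_ground

__all__ = [
    "StationSeries",
    "UrbanGrid",
    "ScenarioSpec",
    "MetField",
    "EffectModel",
    "gen_station_series",
    "gen_urban_grid",
    "gen_met_forcing",
    "apply_scenario_surrogate",
    "solar_cos_zenith",
]

STRATEGIES = ("control", "cool_roof", "green_roof", "urban_trees")
CONTROL_ROOF_ALBEDO = 0.19


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StationSeries:
    """Daily maximum temperature record of one station."""

    station_id: str
    data: pd.Series  # daily tmax in degC, DatetimeIndex

    def __post_init__(self) -> None:
        idx = pd.DatetimeIndex(self.data.index)
        if idx.has_duplicates:
            raise ValueError("duplicate dates in station series")
        if not idx.is_monotonic_increasing:
            raise ValueError("dates must be strictly increasing")
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValueError("daily_tmax must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "station_id": self.station_id,
            "date": self.data.index.strftime("%Y-%m-%d"),
            "tmax_c": self.data.to_numpy(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StationSeries":
        df = pd.read_csv(path, parse_dates=["date"])
        sid = str(df["station_id"].iloc[0])
        return cls(sid, pd.Series(df["tmax_c"].to_numpy(),
                                  index=pd.DatetimeIndex(df["date"])))


@dataclass
class UrbanGrid:
    """Per-cell urban descriptors on an abstract (non-geolocated) grid."""

    table: pd.DataFrame  # cell_id, svi, street_fraction, roof_fraction,
                         # tree_cover, tc_added_target, is_urban

    def __post_init__(self) -> None:
        t = self.table
        for col in ("svi", "street_fraction", "roof_fraction", "tree_cover",
                    "tc_added_target"):
            if np.any((t[col] < 0) | (t[col] > 1)):
                raise ValueError(f"{col} outside [0, 1]")
        urban = t["is_urban"].to_numpy(dtype=bool)
        ssum = (t["street_fraction"] + t["roof_fraction"]).to_numpy()
        if np.any(np.abs(ssum[urban] - 1.0) > 1e-9):
            raise ValueError("street + roof fractions must sum to 1 on urban cells")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def svi(self) -> np.ndarray:
        return self.table["svi"].to_numpy()

    @property
    def street_fraction(self) -> np.ndarray:
        return self.table["street_fraction"].to_numpy()

    @property
    def roof_fraction(self) -> np.ndarray:
        return self.table["roof_fraction"].to_numpy()

    @property
    def tree_cover(self) -> np.ndarray:
        return self.table["tree_cover"].to_numpy()

    @property
    def tc_added_target(self) -> np.ndarray:
        return self.table["tc_added_target"].to_numpy()

    @property
    def is_urban(self) -> np.ndarray:
        return self.table["is_urban"].to_numpy(dtype=bool)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "UrbanGrid":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the seven experiments: control or a mitigation strategy at
    low/high intensity.

    Intensities follow common programme guidelines: cool-roof albedo raised
    to 0.55 (low) or 0.70 (high) from a control value of ~0.19; green-roof
    coverage 30 % (low) or 80 % (high); urban trees planting 50 % (low) or
    100 % (high) of the tree-equity-targeted canopy addition.
    """

    strategy: str
    intensity: str = "high"
    roof_albedo: float = CONTROL_ROOF_ALBEDO
    green_roof_coverage: float = 0.0
    tc_target_multiplier: float = 0.0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; "
                             f"expected one of {STRATEGIES}")
        if self.intensity not in ("low", "high"):
            raise ValueError("intensity must be 'low' or 'high'")

    @property
    def name(self) -> str:
        return self.strategy if self.strategy == "control" \
            else f"{self.strategy}_{self.intensity}"

    @classmethod
    def named(cls, strategy: str, intensity: str = "high") -> "ScenarioSpec":
        presets = {
            ("control", "low"): dict(),
            ("control", "high"): dict(),
            ("cool_roof", "low"): dict(roof_albedo=0.55),
            ("cool_roof", "high"): dict(roof_albedo=0.70),
            ("green_roof", "low"): dict(green_roof_coverage=0.30),
            ("green_roof", "high"): dict(green_roof_coverage=0.80),
            ("urban_trees", "low"): dict(tc_target_multiplier=0.5),
            ("urban_trees", "high"): dict(tc_target_multiplier=1.0),
        }
        try:
            kw = presets[(strategy, intensity)]
        except KeyError:
            raise ValueError(f"unknown scenario {strategy!r}/{intensity!r}") from None
        return cls(strategy=strategy, intensity=intensity, **kw)

    @classmethod
    def experiment_suite(cls) -> list["ScenarioSpec"]:
        """The standard seven experiments: control plus three strategies at
        two intensities each."""
        out = [cls.named("control")]
        for strat in ("cool_roof", "green_roof", "urban_trees"):
            for inten in ("low", "high"):
                out.append(cls.named(strat, inten))
        return out


@dataclass
class MetField:
    """Hourly gridded meteorological forcing over (time, cell).

    Variables: t2 (degC), rh2 (%), ws10 (m/s), mrt (degC), sw_down (W/m2).
    """

    ds: xr.Dataset

    def __post_init__(self) -> None:
        for var in ("t2", "rh2", "ws10", "mrt", "sw_down"):
            if var not in self.ds:
                raise ValueError(f"missing variable {var}")
            if self.ds[var].dims != ("time", "cell"):
                raise ValueError(f"{var} must have dims (time, cell)")
        if np.any((self.ds["rh2"].values < 0) | (self.ds["rh2"].values > 100)):
            raise ValueError("rh2 outside [0, 100] %")
        if np.any(self.ds["ws10"].values < 0):
            raise ValueError("ws10 must be >= 0")
        if np.any(self.ds["sw_down"].values < 0):
            raise ValueError("sw_down must be >= 0")

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.ds["time"].values)

    def copy(self) -> "MetField":
        return MetField(self.ds.copy(deep=True))

    def to_netcdf(self, path) -> None:
        """Write as classic NetCDF (scipy backend; CF-style unit attrs)."""
        self.ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "MetField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls(ds.load())

    def to_csv(self, path) -> None:
        """Long-format CSV fallback: time, cell, t2, rh2, ws10, mrt, sw_down."""
        df = self.ds.to_dataframe().reset_index()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MetField":
        df = pd.read_csv(path, parse_dates=["time"])
        ds = df.set_index(["time", "cell"]).to_xarray()
        return cls(ds)


_UNITS = {"t2": "degC", "rh2": "%", "ws10": "m s-1", "mrt": "degC",
          "sw_down": "W m-2"}


def _make_dataset(times: pd.DatetimeIndex, n_cells: int, arrays: dict) -> xr.Dataset:
    ds = xr.Dataset(
        {k: (("time", "cell"), v) for k, v in arrays.items()},
        coords={"time": times, "cell": np.arange(n_cells)},
    )
    for k in arrays:
        ds[k].attrs["units"] = _UNITS[k]
    return ds


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

DEFAULT_CLIMATE = {
    # Houston-like: annual-mean daily maximum 25.6 degC with a seasonal
    # amplitude chosen so the JJA mean sits near 32.1 degC
    "mean_tmax": 25.6,
    "seasonal_amp": 7.2,
    "peak_doy": 196,
    "noise_sd": 1.5,
}


def gen_station_series(n_years: int = 30,
                       base_climate: Optional[dict] = None,
                       embedded_events: Sequence[tuple] = (),
                       seed: int = 0,
                       station_id: str = "SYN00001",
                       start_year: int = 1990) -> StationSeries:
    """Synthetic station daily-maximum series with optional embedded runs.

    The background is a sinusoidal seasonal cycle plus Gaussian noise.  Each
    embedded event ``(start, duration_days, peak_tmax)`` overwrites its run
    of days with the constant ``peak_tmax`` so a detector recovers it
    exactly.  Overlapping events are rejected.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    clim = dict(DEFAULT_CLIMATE)
    if base_climate:
        unknown = set(base_climate) - set(clim)
        if unknown:
            raise ValueError(f"unknown base_climate keys: {sorted(unknown)}")
        clim.update(base_climate)
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31",
                          freq="D")
    doy = dates.dayofyear.to_numpy()
    tmax = (clim["mean_tmax"]
            + clim["seasonal_amp"] * np.cos(2 * np.pi * (doy - clim["peak_doy"]) / 365.25)
            + rng.normal(0.0, clim["noise_sd"], len(dates)))
    s = pd.Series(tmax, index=dates)

    occupied: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    for start, duration_days, peak in embedded_events:
        if duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        t0 = pd.Timestamp(start)
        t1 = t0 + pd.Timedelta(days=duration_days - 1)
        for a, b in occupied:
            if t0 <= b and a <= t1:
                raise ValueError(f"embedded events overlap at {t0.date()}")
        occupied.append((t0, t1))
        s.loc[t0:t1] = float(peak)
    return StationSeries(station_id, s)


def gen_urban_grid(n_cells: int,
                   svi_street_slope: float = 0.125,
                   seed: int = 0,
                   street_base: float = 0.28,
                   street_noise_sd: float = 0.03,
                   tc_base: float = 0.28,
                   tc_svi_slope: float = -0.15,
                   tc_noise_sd: float = 0.04,
                   tc_add_base: float = 0.07,
                   tc_add_svi_slope: float = 0.06,
                   urban_fraction: float = 1.0) -> UrbanGrid:
    """Synthetic Houston-like urban grid.

    SVI is uniform on [0, 1] (it is a rank-based index by construction).
    Street fraction rises with SVI at ``svi_street_slope`` per unit SVI, from
    about 30 % in resilient cells to about 40 % in vulnerable cells at the
    defaults; roof fraction is its complement.  Control tree cover declines
    with SVI around a ~20 % mean; the tree-equity canopy addition target
    (``tc_added_target``) rises with SVI, averaging ~0.10.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    svi = rng.uniform(0.0, 1.0, n_cells)
    street = np.clip(street_base + svi_street_slope * svi
                     + rng.normal(0.0, street_noise_sd, n_cells), 0.05, 0.95)
    tc = np.clip(tc_base + tc_svi_slope * svi
                 + rng.normal(0.0, tc_noise_sd, n_cells), 0.01, 0.60)
    tc_add = np.clip(tc_add_base + tc_add_svi_slope * svi
                     + rng.normal(0.0, 0.01, n_cells), 0.0, 1.0)
    # trees live on streets: canopy fractions cannot exceed the street share
    tc = np.minimum(tc, street)
    tc_add = np.minimum(tc_add, np.clip(street - tc, 0.0, 1.0))
    is_urban = rng.uniform(0.0, 1.0, n_cells) < urban_fraction
    table = pd.DataFrame({
        "cell_id": np.arange(n_cells),
        "svi": svi,
        "street_fraction": street,
        "roof_fraction": 1.0 - street,
        "tree_cover": tc,
        "tc_added_target": tc_add,
        "is_urban": is_urban,
    })
    return UrbanGrid(table)


def solar_cos_zenith(hours, max_cos_zenith: float = 0.985,
                     sunrise: float = 6.0, sunset: float = 18.0) -> np.ndarray:
    """Cosine of the solar zenith angle from local hour of day.

    Half-sine arc between ``sunrise`` and ``sunset`` peaking at
    ``max_cos_zenith`` (high summer sun); zero at night.
    """
    h = np.asarray(hours, dtype=float)
    frac = (h - sunrise) / (sunset - sunrise)
    up = (frac > 0.0) & (frac < 1.0)
    return np.where(up, max_cos_zenith * np.sin(np.pi * np.clip(frac, 0.0, 1.0)), 0.0)


DEFAULT_DIURNAL = {
    # heatwave preset: daily maximum 2-m temperature ~37 degC (> 35.1)
    "t2_mean": 31.0, "t2_amp": 6.0,
    "rh2_mean": 55.0, "rh2_amp": 20.0,
    "ws_mean": 3.0, "ws_amp": 1.0,
    "s0": 950.0, "mrt_sw_coef": 0.035, "mrt_night_offset": -1.5,
    "peak_hour": 15.0, "noise_sd": 0.3, "cell_sd": 0.4,
}


def gen_met_forcing(grid: UrbanGrid, n_days: int = 3,
                    diurnal_params: Optional[dict] = None,
                    seed: int = 0,
                    start: str = "2019-08-08") -> MetField:
    """Hourly sinusoid-plus-noise heatwave forcing over the grid.

    2-m temperature peaks at ``peak_hour`` local time; relative humidity is
    in antiphase; shortwave follows the clipped solar-elevation curve (zero
    at night); MRT is air temperature plus a shortwave-proportional radiant
    load.  Under the default heatwave preset every cell's daily maximum
    exceeds 35.1 degC and afternoon UTCI exceeds the 26 degC heat-stress
    threshold.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    p = dict(DEFAULT_DIURNAL)
    if diurnal_params:
        unknown = set(diurnal_params) - set(p)
        if unknown:
            raise ValueError(f"unknown diurnal_params keys: {sorted(unknown)}")
        p.update(diurnal_params)
    rng = np.random.default_rng(seed)
    n_cells = len(grid)
    times = pd.date_range(start, periods=24 * n_days, freq="h")
    hod = (times.hour + times.minute / 60.0).to_numpy()

    diurnal = np.cos(2 * np.pi * (hod - p["peak_hour"]) / 24.0)[:, None]
    cell_offset = rng.normal(0.0, p["cell_sd"], n_cells)[None, :]

    t2 = (p["t2_mean"] + p["t2_amp"] * diurnal + cell_offset
          + rng.normal(0.0, p["noise_sd"], (len(times), n_cells)))
    rh2 = np.clip(p["rh2_mean"] - p["rh2_amp"] * diurnal
                  + rng.normal(0.0, 2.0 * p["noise_sd"], (len(times), n_cells)),
                  5.0, 98.0)
    ws10 = np.clip(p["ws_mean"] + p["ws_amp"] * diurnal
                   + rng.normal(0.0, p["noise_sd"], (len(times), n_cells)),
                   0.2, None)
    cosz = solar_cos_zenith(hod)[:, None]
    sw = np.clip(p["s0"] * cosz
                 * (1.0 + rng.normal(0.0, 0.01 * (p["noise_sd"] > 0),
                                     (len(times), n_cells))),
                 0.0, None)
    sw = np.where(cosz > 0.0, sw, 0.0)
    mrt = t2 + p["mrt_sw_coef"] * sw + p["mrt_night_offset"] * (sw == 0.0)
    return MetField(_make_dataset(times, n_cells, {
        "t2": t2, "rh2": rh2, "ws10": ws10, "mrt": mrt, "sw_down": sw,
    }))


# ---------------------------------------------------------------------------
# scenario surrogate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectModel:
    """Sensitivities of the surrogate mesoscale response.

    cool_roof_t2_sens
        Peak-insolation 2-m cooling (K) per unit of roof_fraction x delta
        albedo; scaled through the day by normalised insolation.
    green_roof_t2_sens
        Same, per unit of roof_fraction x green-roof coverage.
    green_roof_night_warm
        Additive nighttime 2-m warming (K) per unit of roof_fraction x
        coverage, active only while sw_down = 0 (soil heat released after
        dark).
    rh_per_t2
        Relative-humidity response (% per K) to a 2-m temperature change,
        opposite in sign (cooling moistens).
    """

    cool_roof_t2_sens: float = 1.15
    green_roof_t2_sens: float = 0.55
    green_roof_night_warm: float = 0.3
    rh_per_t2: float = 2.0


def apply_scenario_surrogate(met: MetField, grid: UrbanGrid,
                             scenario: ScenarioSpec,
                             effect_model: Optional[EffectModel] = None,
                             canopy: Optional[CanopyParams] = None) -> MetField:
    """Perturb the forcing as a mitigation scenario would.

    Control returns the input unchanged.  Roof strategies cool 2-m
    temperature in proportion to roof fraction, intervention magnitude and
    normalised insolation (green roofs additionally warm the night), with a
    humidity response of opposite sign.  The tree strategy leaves t2/rh2/ws10
    untouched and reduces MRT through the Beer's-law canopy scheme: the
    added street canopy intercepts shortwave otherwise reaching the ground,
    and the cell-mean radiant reduction scales with street fraction.
    """
    if scenario.strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {scenario.strategy!r}")
    if scenario.strategy == "control":
        return met.copy()
    em = effect_model if effect_model is not None else EffectModel()
    cp = canopy if canopy is not None else CanopyParams()
    ds = met.ds.copy(deep=True)
    sw = ds["sw_down"].values
    s0 = float(sw.max())
    sw_norm = sw / s0 if s0 > 0 else np.zeros_like(sw)
    roof = grid.roof_fraction[None, :]

    if scenario.strategy == "cool_roof":
        d_alb = scenario.roof_albedo - CONTROL_ROOF_ALBEDO
        dt2 = -em.cool_roof_t2_sens * roof * d_alb * sw_norm
        ds["t2"].values += dt2
        ds["rh2"].values = np.clip(ds["rh2"].values - em.rh_per_t2 * dt2, 0.0, 100.0)
        ds["mrt"].values += dt2  # radiant environment tracks the cooled air
    elif scenario.strategy == "green_roof":
        cov = scenario.green_roof_coverage
        dt2 = -em.green_roof_t2_sens * roof * cov * sw_norm
        night = (sw == 0.0)
        dt2 = dt2 + em.green_roof_night_warm * roof * cov * night
        ds["t2"].values += dt2
        ds["rh2"].values = np.clip(ds["rh2"].values - em.rh_per_t2 * dt2, 0.0, 100.0)
        ds["mrt"].values += dt2
    else:  # urban_trees
        added_tc = scenario.tc_target_multiplier * grid.tc_added_target
        hod = (met.times.hour + met.times.minute / 60.0).to_numpy()
        cosz = solar_cos_zenith(hod)
        zenith = np.arccos(np.clip(cosz, -1.0, 1.0))  # pi/2 at night
        # shortwave reduction at street level per unit added canopy:
        # Beer's-law interception of the flux otherwise reaching the ground
        state = sw_ground(sw, 0.0, cp, zenith[:, None])
        intercept_per_tc = state.sw_ground_sun - state.sw_ground_tree
        d_sw = intercept_per_tc * added_tc[None, :]
        # cell-mean radiant response: streets occupy street_fraction of plan
        ds["mrt"].values += mrt_adjustment(d_sw, cp.mrt_sensitivity) \
            * grid.street_fraction[None, :]
    return MetField(ds)
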