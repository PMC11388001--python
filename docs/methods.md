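# Methods

This note documents the models implemented in `urbanheat`, the defaults and
why they were chosen, what the synthetic study conditions emulate, and the
numerical choices that matter.

## Street-tree radiation scheme (`urbanheat.canopy`)

Direct shortwave reaching the street under a tree canopy follows Beer's law

    SW_ground_tree = SW_ground_sun · exp(−Ω · G · LAI / cos φ),

with clumping coefficient Ω = 0.5, leaf-orientation factor G = 0.5 and
LAI = 3 by default — representative of the evergreen broadleaf/needleleaf
canopies common around a Gulf-coast city, where street-tree LAI near 3 is a
reasonable single value (LAI in reality varies by species and season; that
variation is a documented limitation, not modelled). A cell's street surface
is a two-component mixture of shaded and open ground:

    SW_ground = (1 − tc) · SW_ground_sun + tc · SW_ground_tree,

so the canopy absorbs `enloss = SW_ground_sun − SW_ground ≥ 0`. All absorbed
energy is re-emitted as turbulent flux split by a fixed Bowen ratio β = 2.0
(Houston-like): `LH = enloss/(β+1)`, `SH = β·enloss/(β+1)`. The sensible
term is computed as the residual `enloss − LH`, so the budget closes to
machine precision for any β. This partition is equivalent to assuming zero
net longwave exchange of foliage and no foliage heat storage. Tree drag on
wind and species-specific transpiration are deliberately out of scope.

**Zenith convention.** The optical path `1/cos φ` diverges at φ = 90°; for
φ ≥ 90° there is no direct beam and transmission (and hence `enloss`) is set
to 0. Whether the attenuation should also apply to diffuse shortwave is not
specified by the underlying scheme; it is applied to the total flux as the
equations are written.

**MRT adjustment.** The in-canyon mean-radiant-temperature computation is
out of scope (MRT arrives as an input); the tree scenario instead uses a
linear adjustment ΔMRT = −s · ΔSW_ground with sensitivity s in K/(W m⁻²).
The operation itself takes s as an argument (e.g. 0.025 K/(W m⁻²) converts a
200 W m⁻² shading into a 5 K radiant cooling, the magnitude reported for
comparable canyon models). The *default* carried by `CanopyParams`
(`mrt_sensitivity = 0.09`) is larger because in the pipeline the cell-mean
radiant perturbation is additionally scaled by street fraction; 0.09 places
the high-intensity tree scenario's urban-average daytime UTCI reduction in
the 0.2–0.3 K range expected of such strategies. It is exposed in config.

## UTCI (`urbanheat.comfort`)

The operational UTCI approximation is a complete polynomial of total degree
six in air temperature Ta (°C), wind va (m/s), radiant excess
D = Tmrt − Ta (K) and vapour pressure Pa (kPa) — 210 published coefficients,
vendored in `_utci_coeffs.py` in the canonical listing order and evaluated
with precomputed power tables. Saturation vapour pressure uses the ITS-90
(Hardy) formulation bundled with the operational procedure
(es(0 °C) ≈ 6.112 hPa).

Inputs are clamped to the polynomial's published validity domain
(Ta ∈ [−50, 50] °C, va ∈ [0.5, 17] m/s, D ∈ [−30, 70] K, Pa ≤ 5 kPa) with a
logged warning; `clamp=False` rejects out-of-domain input instead. The test
suite checks the implementation two independent ways: against documented
spot values of the published reference implementation (e.g. 30.3 °C at
Ta = 29, RH = 60 %, va = 1, Tmrt = 30), and against a second, independent
scalar evaluation route (compensated summation, independent power
computation) on 10⁴ random in-domain points at 10⁻⁴ K.

**Subgrid wind.** The within-cell wind distribution is not prescribed by the
source analysis; it is modelled as lognormal with median `va10` and
configurable log-spread (default σ = 0.4, a moderate urban gustiness). UTCI
is evaluated at the 10th/50th/90th wind quantiles and the results sorted
point-wise, giving cool-spot/midrange/hot-spot values with a guaranteed
ordering; the midrange (which equals UTCI at the median wind) feeds all
downstream metrics, representing average conditions.

## Heatwave detection (`urbanheat.heatwave`)

The cascade works on station daily-maximum series: (1) threshold = plain
mean over JJA days of the across-station-averaged daily maximum (no
trimming); (2) hot days are days *strictly* above the threshold; (3) maximal
consecutive runs lasting ≥ 6 days ("extending beyond 5 days") are heatwave
cases, never merged across a cool day; (4) severe cases keep peak > 35.1 °C
and duration > 14 d; (5) the WMO check asks for more than 5 consecutive days
exceeding the average daily maximum by 5 K; (6) the simulation window is
±48 h around 21Z on the peak day (Houston afternoon, UTC−6). Missing
station-days fail fast by default, with a configurable tolerated fraction.
"Surpassing"/"beyond" are read as strict inequalities throughout.

## Equity metrics (`urbanheat.metrics`)

Hourly heat stress is the exceedance above the 26 °C UTCI onset (32 °C is
supported as a sensitivity setting); DCH sums the 24 hourly samples of a
local day (t = 0..23 — a 25th sample would double-count midnight); ADCH
averages DCH over all simulated days and events; and

    VDCH_i = w · SVI · (ADCH_i − ADCH_CTL)/ADCH_CTL · 100 %

with w = 1 weighting vulnerability and heat-stress change equally. Cells
with ADCH_CTL = 0 have nothing to mitigate and return VDCH = 0 with a
warning. Negative VDCH = improved community resilience. Two desk
equivalences give percent changes physical meaning: a 2 % cut of a
336 K·h day (24 h at UTCI 40) equals 28.8 min less exposure at UTCI 40, or
cooling 40 → 39.7 °C sustained for 24 h.

SVI-binned curves use decile bins of [0, 1] (left-closed, last bin closed),
reporting per-bin median and interquartile range; the extreme bins are the
resilient (SVI < 0.1) and vulnerable (SVI > 0.9) neighbourhoods. Empty bins
are reported missing, not zero. Whether deciles or only the named extremes
are intended by the source analysis is ambiguous; deciles are the documented
default. Urban averages are plain means over urban-flagged cells. The
daytime/nighttime split for period summaries is "hours with any positive
downwelling shortwave" vs the rest — the natural boundary in forcing data —
with a config override, since no explicit hour boundary is prescribed.

## Synthetic study conditions (`urbanheat.synth`)

The generators reproduce the statistical structure the analysis assumes,
not any real city's geography (cells are abstract, no rasters):

- **Station series**: seasonal sinusoid + Gaussian noise; defaults
  (annual-mean daily max 25.6 °C, amplitude 7.2 K, noise 1.5 K) put the JJA
  mean near 32.1 °C, so the detection threshold lands where the Houston
  climatology puts it. Embedded exceedance runs are written in verbatim so a
  detector must recover them exactly; overlapping runs are rejected.
- **Urban grid**: SVI ~ U(0, 1) (it is a rank index by construction); street
  fraction = 0.28 + 0.125·SVI + N(0, 0.03), clipped — ≈ 0.40 above SVI 0.9
  and < 0.30 below SVI 0.1; roof fraction is the complement (urban cell =
  roof + street); control tree cover 0.28 − 0.15·SVI + N(0, 0.04) (≈ 20 %
  mean, declining with SVI); the tree-equity canopy addition target
  0.07 + 0.06·SVI (≈ 0.10 mean, rising with SVI), capped by available street
  space.
- **Forcing**: hourly sinusoid + Gaussian noise; the heatwave preset
  (mean 31 °C, amplitude 6 K, afternoon peak at 15:00) puts every cell's
  daily maximum above 35.1 °C and afternoon midrange UTCI above 26 °C so DCH
  is nonzero. Shortwave follows a clipped half-sine solar-elevation curve
  (zero at night); MRT is air temperature plus 0.035 K per W m⁻² of
  insolation, minus a small nocturnal sky-cooling offset.
- **Scenario surrogates**: the mesoscale response to each strategy is
  emulated, not simulated. Cool/green roofs cool 2-m temperature in
  proportion to roof fraction × intervention magnitude × normalised
  insolation, with humidity responding at −2 % per K (cooling moistens) and
  MRT tracking the cooled air; green roofs add a +0.3 K × roof fraction ×
  coverage nighttime term, active only while shortwave is zero (soil heat
  released after dark). Trees act only through the canopy scheme: added
  canopy (multiplier × equity target) intercepts the flux otherwise reaching
  the ground, and the cell-mean MRT falls by sensitivity × interception ×
  street fraction — temperature, humidity and wind are untouched. The linear
  surrogate sensitivities (1.15 and 0.55 K per unit of roof-fraction-scaled
  forcing) are free parameters documented as surrogates for urban-canopy
  physics; their defaults place the high-intensity urban-average daytime
  UTCI responses at ≈ 0.30 K (cool roof), ≈ 0.26 K (trees) and ≈ 0.22 K
  (green roof), the magnitudes such strategies produce in mesoscale studies.

**What passing tests show — and do not.** The suite demonstrates that the
metric chain recovers the expected equity ordering (trees ahead of cool
roofs ahead of green roofs by daytime VDCH, in ≥ 95 of 100 seeds) *given*
the encoded morphology–vulnerability correlations and effect structure. It
does not validate those correlations for any real city, nor the surrogates
against a mesoscale model: real heatwaves have synoptic variability,
sea-breeze modulation and spatially correlated forcing that the independent
Gaussian noise here does not represent.

## Numerical and design choices

- Problem sizes: default suite 500 cells × 3 days × 7 experiments (< 1 s);
  tests use 200–300 cells × 2 days, and the 100-seed ordering check runs in
  about half a minute.
- Determinism: every generator takes a seed (`numpy.random.default_rng`);
  fixed seeds give byte-identical report CSVs.
- Albedo: broadband = 0.443·blue + 0.317·green + 0.240·red (weights sum to
  1.000, so a flat spectrum is a fixed point and output is bounded by the
  band extrema); per-class aggregation is a plain mean over masked pixels.
- Control roof albedo 0.19 (typical observed dark roofing); scenario
  intensities 0.55/0.70 (cool-roof programmes), 30 %/80 % (green-roof
  programmes), 50 %/100 % of the equity canopy target.
- I/O: forcing as classic NetCDF via the scipy backend (CF-style unit
  attributes) with a long-format CSV fallback; grids and station series as
  CSV; events as JSON lines; suite reports as CSV + JSON.
- Degenerate inputs: zero-variance wind collapses the UTCI percentiles to a
  point; `adch` rejects incomplete day×event tables; empty urban masks and
  non-contiguous daily series raise immediately.

## Known limitations

Single-event averaging in the bundled pipeline (ADCH over one synthetic
episode; the `adch` operation itself accepts multi-event tables); no
longwave or storage terms in the canopy budget; the subgrid-wind family is a
configurable assumption; surrogate scenario physics (no advection, no
inter-cell interaction); abstract cells without geography.
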