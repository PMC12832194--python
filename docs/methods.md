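# Methods

This note documents the models, conventions and numerical choices behind the
package, and what the synthetic scenarios do and do not establish.

## SPEI construction

**Potential evapotranspiration.** PET uses the Thornthwaite method because the
station inputs are monthly mean temperature and precipitation only. The annual
heat index is computed from the series' per-calendar-month mean temperatures
(freezing months contribute zero); the exponent is the standard cubic in the
heat index; the day-length correction uses the FAO-56 solar declination at
mid-month and the month's day count. Months with mean temperature ≤ 0 °C get
PET = 0; temperatures ≥ 26.5 °C use the high-temperature polynomial
(−415.85 + 32.24 T − 0.43 T²). Physically based alternatives
(Hargreaves, Penman–Monteith) need radiation/humidity inputs the station
schema does not carry; the PET step is isolated behind `thornthwaite_pet` as
the extension hook. Results are therefore comparable to, but not identical
with, SPEI products built on other PET formulations.

**Aggregation and fitting.** The water balance D = P − PET is summed over
k = 6 months (`D₆`), undefined for the first k−1 months and wherever any
contributing month is missing — no imputation. Each calendar month's `D₆`
sample over the calibration period (the full record by default) is fitted
with a three-parameter log-logistic via unbiased probability-weighted moments
`w_s = E[X(1−F)^s]`:

    β = (2w₁ − w₀) / (6w₁ − w₀ − 6w₂)
    α = (w₀ − 2w₁) β / (Γ(1+1/β) Γ(1−1/β))
    γ = w₀ − α Γ(1+1/β) Γ(1−1/β)

Samples with negative L-skewness (for which this parameterization has no
valid solution) are fitted on their negation and the CDF mirrored back — the
generalized-logistic view of the same family. This keeps standardization
defined and monotone for every non-degenerate sample; the `reflected` flag is
recorded on the fit. Fitting requires ≥ 10 non-constant samples.

**Standardization.** SPEI = Φ⁻¹(F(D₆)) using the month's fitted CDF.
Probabilities are clipped to [1e−6, 1 − 1e−6] before the normal quantile so
values at or below the fitted origin map to a finite lower-tail value
(≈ ±4.75) rather than ±∞. The inverse normal is scipy's exact `norm.ppf`
rather than the legacy rational approximation; the difference is below 1e−3
SPEI units. Under self-calibration on 21 years the per-calendar-month mean is
within ±0.1 of 0 and the sd within [0.85, 1.15] (plotting-position noise at
n = 21 prevents exact unit variance).

## Drought events

A drought month has SPEI-6 ≤ −1.0 (threshold inclusive). Run theory extracts
maximal sub-threshold runs; runs separated by at most one non-drought month
are pooled into one event, the gap month counting toward duration and toward
the event-month mask; pooled events shorter than 2 months are discarded. At
monthly resolution a "separation of less than one month" is read as the
standard one-month pooling convention, and "longer than one month" as
duration ≥ 2. Event severity is the class of the peak (minimum) SPEI.
Severity bounds: mild (−1.0, −0.5], moderate (−1.5, −1.0], severe
(−2.0, −1.5], extreme ≤ −2.0. Seasons are meteorological (MAM, JJA, SON,
DJF), with the winter of year Y spanning December Y to February Y+1; the
seasonal SPEI is the arithmetic mean of the three member months, missing if
any member is undefined.

## Baselines and anomalies

Monthly NDVI is the per-cell maximum over the month's 16-day composites
(maximum-value compositing suppresses cloud-depressed values); a composite
belongs to the month containing its start date. Baselines are
per-calendar-month means over the years whose month lies outside any
identified drought event — exclusion follows event months (including pooled
gaps), not merely sub-threshold months, so the baseline describes non-drought
conditions. A calendar month with every year masked yields a missing baseline
(an all-years fallback exists but is off by default). Anomalies are
observed − baseline with percent = 100·absolute/baseline; percent is
undefined where |baseline| < ε (ε = 0.01 NDVI units; 1e−6 in variable units
for hydrothermal fields). By construction the mean anomaly over exactly the
contributing years is zero per calendar month. Regional series are
equal-weight means over valid cells (cellwise anomalies averaged, rather
than anomalies of the regional mean; the two differ only through missing-cell
patterns). Seasonal anomalies average the member months' absolute anomalies,
with percent against the mean seasonal baseline. The lag diagnostic
`minimum_shift` is the signed difference (months) between the observed and
baseline annual-minimum positions over a shared 12-month window, ties broken
toward the earliest month with a warning.

## Stratification

Zonal summaries report n, mean, sd, min, max per class over cells valid in
every layer of the comparison (listwise deletion). The OTH class (croplands,
urban, barren) is excluded from vegetation-response summaries by default and
includable by flag. Count-weighted recombination of stratum means equals the
global mean to 1e−9 — this is the invariant the tests enforce against a
brute-force loop. Cross-classification (vegetation × landform) reports every
non-empty pair and omits empty intersections with a warning.

## Interpolation

Ordinary kriging with an exponential variogram is the default
(γ(h) = nugget + (sill − nugget)(1 − e^{−3h/range}), `range` the effective
range; γ(0) is reported as the nugget while the kriging system uses zero on
its diagonal, the standard convention giving exact interpolation at stations
when the nugget is zero). The empirical semivariogram uses 15 bins up to a
third of the maximum pair separation; the fit is weighted least squares with
N/h² bin weights so the short lags that carry the range information dominate.
Single-realization range estimates at n = 200 stations are noisy
(roughly ±25% realization scatter); the fitted range should be read as
order-of-magnitude structure, which is all kriging needs here. A constant
field degenerates to a pure-nugget model (equal weights, station mean
everywhere). A singular kriging system is retried once with a 1e−10 diagonal
jitter, then raised. Coordinates are planar; CRS transforms are out of scope.
IDW (power 2) is the fast fallback and the default for the per-month SPEI
grids inside the synthetic pipeline.

## Synthetic scenarios

The generator emulates a subtropical monsoon domain: temperature a seasonal
sinusoid (mean 15 °C, amplitude 9.5 °C, January minimum) plus station offsets
and noise; precipitation gamma-distributed per calendar month with means
(28, 32, 58, 92, 160, 195, 175, 140, 95, 72, 52, 28) mm — ≈ 1130 mm/yr with
≈ 82% falling April–October — and CV 0.45. The default domain is a 60 × 60
grid of 250 m cells with 25 stations and 21 years, sized so the full
pipeline runs in seconds while leaving ≥ 21 samples per calendar-month fit.
Droughts are planted as multiplicative precipitation deficits (default: ×0.4
over October 2009 – May 2010, +1 °C); vegetation masks grow contiguous
quota-limited patches matching the configured class shares (3/12/32/2/16/35%
for BDF/NDF/SCR/MDW/GRA/OTH; 73% karst); NDVI per cell is a class seasonal
curve plus sensitivity × min(0, SPEI lagged 2 months), the sensitivity
multiplied by 1.5 on karst cells, plus noise — wet anomalies deliberately do
not boost NDVI, keeping the planted signal one-sided. Two composites per
month are emitted with the first carrying the monthly value, so MVC recovers
it exactly. Hydrothermal grids follow the station-mean climate with smooth
spatial patterns; shortwave radiation is anticorrelated with the
precipitation anomaly; surface and root-zone soil moisture are first-order
low-pass filters of the water balance (memories 0.7 and 0.9), giving the
root zone the longer drawdown lag.

**Ground truth for detection.** A k-month index responds to a deficit window
with onset delay and persistence, so judging detection against the raw
forcing window would penalize correct behavior. The recorded ground-truth
drought window is the *expected response window*: the months where the
planted deficit removed from the 6-month precipitation sum is at least one
standard deviation of that sum (sd = CV·√Σ mean², from the gamma model).
For the default scenario this is January–August 2010, 8 months. The raw
forcing window is recorded alongside.

**What passing tests show — and don't.** Recovery of the planted event,
ordering and karst contrast demonstrates that the pipeline's machinery is
correct and unbiased under the generator's assumptions (shared regional
forcing, additive class response, independent station noise, no cloud/QA
artifacts, no greening trend, no spatially correlated NDVI noise). It does
not validate the ecological claims on real MODIS/GLDAS/station data, where
retrieval artifacts, trends and confounded strata exist.

## Numerical conventions and degenerate inputs

- Missing values are NaN throughout; any missing contributor voids the
  derived quantity (water-balance windows, seasonal means) rather than being
  imputed.
- Station QC: a station is dropped when more than 5% of the months in its
  own first-to-last span have a missing temperature or precipitation value.
- Probability clipping at 1e−6 bounds |SPEI| at ≈ 4.75.
- Severity boundaries are closed on the dry side (−2.0 is extreme, −1.0 is
  moderate, −0.5 is mild).
- MVC of an all-missing month is a missing layer with a warning; NDVI outside
  [−1, 1] is flagged invalid before compositing.
- All generator randomness derives from one scenario seed through fixed
  per-product streams; identical seeds give bit-identical outputs on one
  platform and agreement to 1e−12 across platforms.

## Known limitations

- Thornthwaite PET underestimates evaporative demand in warm, humid winters;
  trend-aware (nonstationary) standardization is not implemented.
- Run-theory events are regional (one series), not tracked as spatial
  patches.
- The kriging implementation is isotropic, single-variable ordinary kriging;
  no co-kriging with elevation and no anisotropy.
- Daily inputs, daily-scale indices and cartographic output are out of scope.
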