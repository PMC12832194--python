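"""Seeded synthetic study scenarios: monsoon station climate, categorical
masks, lagged drought-sensitive NDVI composites and hydrothermal grids.

The generator emulates a subtropical monsoon domain on a small planar grid:
mean annual temperature near 15 °C with a ~19 °C seasonal swing, annual
precipitation near 1100 mm of which roughly 80% falls April–October, a
karst-dominated landform mosaic, and six vegetation classes in contiguous
patches.  Droughts are planted as multiplicative precipitation deficits (plus
a warm offset) over chosen month windows, and NDVI responds to the lagged
negative part of SPEI-6 with class-specific sensitivities amplified on karst.
Every product is a deterministic function of the scenario seed.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .interp import StationField, idw
from .rasters import GridSpec, MonthlyStack
from .spei import ClimateSeries, fit_spei, thornthwaite_pet
from .stratify import CategoricalMask, LANDFORM_LABELS, VEG_LABELS

__all__ = [
    "PlantedDrought",
    "ScenarioConfig",
    "GroundTruth",
    "Scenario",
    "simulate_climate",
    "simulate_masks",
    "simulate_ndvi",
    "simulate_hydrothermal",
    "station_spei_grid",
    "generate_scenario",
]

# monthly precipitation means (mm), Jan..Dec: ~1127 mm/yr, ~82% in Apr–Oct
DEFAULT_PRECIP_MEANS = (28.0, 32.0, 58.0, 92.0, 160.0, 195.0,
                        175.0, 140.0, 95.0, 72.0, 52.0, 28.0)

# class-specific NDVI drought sensitivities (NDVI units per unit SPEI deficit);
# ordering MDW > SCR > BDF > GRA > NDF mirrors the imposed response contrast
DEFAULT_SENSITIVITY = {
    "MDW": 0.26, "SCR": 0.19, "BDF": 0.15, "GRA": 0.115, "NDF": 0.07,
    "OTH": 0.10,
}

# per-class NDVI seasonal curve: (annual mean, seasonal amplitude)
DEFAULT_NDVI_CURVE = {
    "BDF": (0.62, 0.23), "NDF": (0.60, 0.18), "SCR": (0.52, 0.20),
    "MDW": (0.42, 0.22), "GRA": (0.46, 0.18), "OTH": (0.38, 0.12),
}

DEFAULT_VEG_SHARES = {
    "BDF": 0.03, "NDF": 0.12, "SCR": 0.32, "MDW": 0.02, "GRA": 0.16,
    "OTH": 0.35,
}


@dataclass(frozen=True)
class PlantedDrought:
    """A planted deficit window: precipitation is multiplied by
    ``precip_multiplier`` (< 1) and temperature offset upward."""

    start: str          # first month, e.g. "2009-10"
    months: int = 8
    precip_multiplier: float = 0.4
    temp_offset: float = 1.0

    def window(self) -> pd.PeriodIndex:
        start = pd.Period(self.start, freq="M")
        return pd.period_range(start, periods=self.months, freq="M")

    def __post_init__(self) -> None:
        if not 0.0 < self.precip_multiplier <= 1.0:
            raise ValueError("precip_multiplier must be in (0, 1]")


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic study scenario; the seed is mandatory."""

    seed: int
    nrows: int = 60
    ncols: int = 60
    cell_size: float = 250.0
    n_stations: int = 25
    start_year: int = 2001
    years: int = 21
    base_latitude: float = 26.5
    temp_mean: float = 15.0
    temp_amplitude: float = 9.5
    temp_noise_sd: float = 0.8
    precip_means: tuple = DEFAULT_PRECIP_MEANS
    precip_cv: float = 0.45
    droughts: tuple = (PlantedDrought(start="2009-10"),)
    veg_shares: dict = field(default_factory=lambda: dict(DEFAULT_VEG_SHARES))
    karst_share: float = 0.73
    ndvi_curve: dict = field(default_factory=lambda: dict(DEFAULT_NDVI_CURVE))
    sensitivity: dict = field(default_factory=lambda: dict(DEFAULT_SENSITIVITY))
    response_lag: int = 2
    karst_amplification: float = 1.5
    ndvi_noise_sd: float = 0.015

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.nrows, self.ncols, self.cell_size)

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(
            pd.Period(year=self.start_year, month=1, freq="M"),
            periods=self.years * 12,
            freq="M",
        )

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream (0 climate, 1 masks, 2 NDVI,
        3 hydrothermal)."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) % 2**31, int(stream)])
        )


@dataclass
class GroundTruth:
    """What was planted, recorded alongside every generated dataset.

    ``forcing_windows`` are the raw multiplier windows; ``drought_windows``
    are the expected SPEI-6 response windows — the months where the planted
    deficit drives the 6-month aggregated balance below the −1 threshold in
    expectation.  A k-month index responds to a deficit with onset delay and
    persistence, so detection is judged against the response window.
    """

    drought_windows: list
    forcing_windows: list
    sensitivity_order: list
    karst_amplification: float

    def to_dict(self) -> dict:
        return {
            "drought_windows": [
                [str(w[0]), str(w[-1])] for w in self.drought_windows
            ],
            "forcing_windows": [
                [str(w[0]), str(w[-1])] for w in self.forcing_windows
            ],
            "sensitivity_order": list(self.sensitivity_order),
            "karst_amplification": self.karst_amplification,
        }


def expected_response_windows(config: ScenarioConfig, k: int = 6,
                              threshold: float = -1.0) -> list[pd.PeriodIndex]:
    """Deterministic expected drought windows of the k-month index.

    For each month, the planted deficit removed from the k-month precipitation
    sum is compared with that sum's standard deviation under the gamma
    precipitation model (sd = cv · sqrt(sum of squared monthly means)); months
    whose expected standardized deficit is at or below ``threshold`` form the
    response windows (maximal runs).
    """
    months = config.months
    month_of = months.month.values
    means = np.asarray(config.precip_means)[month_of - 1]
    removal = np.zeros(len(months))
    for dr in config.droughts:
        sel = months.isin(dr.window())
        removal[sel] += (1.0 - dr.precip_multiplier) * means[sel]

    z = np.full(len(months), 0.0)
    for i in range(k - 1, len(months)):
        window = slice(i - k + 1, i + 1)
        sd = config.precip_cv * np.sqrt(np.sum(means[window] ** 2))
        z[i] = -removal[window].sum() / sd
    below = z <= threshold
    runs, start = [], None
    for i, flag in enumerate(below):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append(pd.period_range(months[start], months[i - 1], freq="M"))
            start = None
    if start is not None:
        runs.append(pd.period_range(months[start], months[-1], freq="M"))
    return runs


def simulate_climate(config: ScenarioConfig):
    """Monsoon station climate with planted deficits.

    Temperature is a seasonal sinusoid (January minimum) plus station offsets
    and noise; precipitation is gamma-distributed per calendar month with the
    configured monthly means and coefficient of variation, scaled by the
    planted multiplier inside drought windows.  Returns
    ``(stations, ground_truth)``.
    """
    if config.years < 15:
        import warnings

        warnings.warn("fewer than 15 years: SPEI calibration will be unstable")
    rng = config.rng(0)
    months = config.months
    month_of = months.month.values
    n_m = len(months)

    grid = config.grid
    width = grid.ncols * grid.cell_size
    height = grid.nrows * grid.cell_size
    xs = rng.uniform(0, width, config.n_stations)
    ys = rng.uniform(-height, 0, config.n_stations)
    elevs = rng.uniform(400.0, 2000.0, config.n_stations)
    lats = config.base_latitude + ys / 111_000.0

    # planted deficit factors, shared across stations
    p_factor = np.ones(n_m)
    t_offset = np.zeros(n_m)
    windows = []
    for dr in config.droughts:
        w = dr.window()
        sel = months.isin(w)
        p_factor[sel] *= dr.precip_multiplier
        t_offset[sel] += dr.temp_offset
        windows.append(w)

    seasonal_t = config.temp_mean - config.temp_amplitude * np.cos(
        2.0 * np.pi * (month_of - 1) / 12.0
    )
    p_means = np.asarray(config.precip_means)[month_of - 1]
    shape = 1.0 / config.precip_cv**2

    stations = []
    for i in range(config.n_stations):
        station_t_offset = rng.normal(0.0, 0.5) - 0.0065 * (elevs[i] - 1100.0) * 0.3
        t = (
            seasonal_t
            + station_t_offset
            + t_offset
            + rng.normal(0.0, config.temp_noise_sd, n_m)
        )
        p = rng.gamma(shape, p_means / shape) * p_factor
        stations.append(
            ClimateSeries(
                station_id=f"S{i + 1:03d}",
                latitude=float(lats[i]),
                longitude=106.0 + xs[i] / 111_000.0,
                elevation=float(elevs[i]),
                t=pd.Series(t, index=months),
                p=pd.Series(p, index=months),
            )
        )
    # station planar coordinates ride along for interpolation
    for st, x, y in zip(stations, xs, ys):
        st.x, st.y = float(x), float(y)

    gt = GroundTruth(
        drought_windows=expected_response_windows(config),
        forcing_windows=windows,
        sensitivity_order=sorted(
            (k for k in config.sensitivity if k != "OTH"),
            key=lambda k: -config.sensitivity[k],
        ),
        karst_amplification=config.karst_amplification,
    )
    return stations, gt


def _grow_regions(rng: np.random.Generator, shape: tuple[int, int],
                  quotas: dict[int, int]) -> np.ndarray:
    """Quota-limited multi-source region growth: each class grows contiguous
    patches from random seed cells until its cell quota is filled."""
    nrows, ncols = shape
    out = np.full(shape, -1, dtype=int)
    remaining = dict(quotas)
    heap: list[tuple[float, int, int, int]] = []

    n_cells = nrows * ncols
    seed_plan = []
    for code, quota in sorted(quotas.items()):
        n_seeds = max(1, int(round(30 * quota / n_cells)))
        seed_plan.extend([code] * n_seeds)
    seed_cells = rng.choice(n_cells, size=len(seed_plan), replace=False)
    # seed cells are claimed up front so every class survives
    for code, flat in zip(seed_plan, seed_cells):
        r, c = divmod(int(flat), ncols)
        if remaining[code] <= 0:
            continue
        out[r, c] = code
        remaining[code] -= 1
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and out[rr, cc] == -1:
                heapq.heappush(heap, (rng.random(), rr, cc, code))

    while True:
        while heap:
            _, r, c, code = heapq.heappop(heap)
            if out[r, c] != -1 or remaining[code] <= 0:
                continue
            out[r, c] = code
            remaining[code] -= 1
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols and out[rr, cc] == -1:
                    heapq.heappush(heap, (rng.random(), rr, cc, code))
        # enclosed classes with unfilled quotas restart in unassigned space
        unfilled = [code for code, left in remaining.items() if left > 0]
        free = np.flatnonzero(out.ravel() == -1)
        if not unfilled or len(free) == 0:
            break
        for code in unfilled:
            flat = int(rng.choice(free))
            r, c = divmod(flat, ncols)
            heapq.heappush(heap, (rng.random(), r, c, code))

    # leftovers (quota exhaustion islands): attach to a neighbouring class
    while (out == -1).any():
        changed = False
        rs, cs = np.where(out == -1)
        for r, c in zip(rs, cs):
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols and out[rr, cc] != -1:
                    out[r, c] = out[rr, cc]
                    changed = True
                    break
        if not changed:  # pragma: no cover - cannot happen with >=1 seed
            out[out == -1] = max(quotas, key=quotas.get)
    return out


def simulate_masks(config: ScenarioConfig):
    """Vegetation-type and karst/non-karst masks as contiguous seeded patches.

    Realized class shares track the configured shares to within a few
    percentage points.  Returns ``(veg_mask, karst_mask)``.
    """
    grid = config.grid
    n = grid.n_cells
    if n < 10 * len(config.veg_shares):
        raise ValueError("domain too small for the requested class count")
    rng = config.rng(1)

    code_of = {lab: code for code, lab in VEG_LABELS.items()}
    quotas = {}
    for lab, share in config.veg_shares.items():
        quotas[code_of[lab]] = int(round(share * n))
    # make quotas sum exactly to n
    diff = n - sum(quotas.values())
    quotas[code_of["OTH"]] += diff
    veg = _grow_regions(rng, grid.shape, quotas)

    k_quota = int(round(config.karst_share * n))
    karst = _grow_regions(rng, grid.shape, {1: k_quota, 2: n - k_quota})

    return (
        CategoricalMask(veg, dict(VEG_LABELS), grid),
        CategoricalMask(karst, dict(LANDFORM_LABELS), grid),
    )


def station_spei_grid(stations, grid: GridSpec, k: int = 6,
                      method: str = "idw") -> MonthlyStack:
    """Fit SPEI per station and interpolate each month onto the grid (IDW by
    default; kriging via :mod:`.interp` is the heavier alternative)."""
    from .interp import interpolate_stack

    spei_by_station = [fit_spei(st, k=k).spei for st in stations]
    months = spei_by_station[0].index
    vals = np.column_stack([s.to_numpy() for s in spei_by_station]).T  # (st, t)
    xy = np.array([[st.x, st.y] for st in stations])
    layers = interpolate_stack(xy, vals.T, grid, method=method)
    return MonthlyStack(layers, months, grid, name=f"spei{k}")


def _ndvi_seasonal(curve: tuple[float, float], month_of: np.ndarray) -> np.ndarray:
    mean, amp = curve
    # minimum in January, peak in July
    return mean - amp * np.cos(2.0 * np.pi * (month_of - 1) / 12.0)


def simulate_ndvi(config: ScenarioConfig, spei_grid: MonthlyStack,
                  veg_mask: CategoricalMask, karst_mask: CategoricalMask):
    """16-day NDVI composite stack with a lagged, class-specific drought
    response.

    Monthly NDVI per cell = class seasonal curve + sensitivity × min(0,
    SPEI lagged by ``response_lag``) × karst amplification (karst cells) +
    noise, clipped to [−1, 1].  Two composites per month are emitted (nominal
    days 1 and 17); the first carries the monthly value so the maximum-value
    composite recovers it exactly.  Returns
    ``(composites, dates, ground_truth_info)``.
    """
    missing = set(veg_mask.labels.values()) - set(config.sensitivity)
    if missing:
        raise ValueError(f"no sensitivity configured for classes {sorted(missing)}")
    rng = config.rng(2)
    months = config.months
    month_of = months.month.values
    grid = config.grid

    sens = np.zeros(grid.shape)
    curve_mean = np.zeros(grid.shape)
    curve_amp = np.zeros(grid.shape)
    for code, lab in veg_mask.labels.items():
        sel = veg_mask.classes == code
        sens[sel] = config.sensitivity[lab]
        m, a = config.ndvi_curve[lab]
        curve_mean[sel] = m
        curve_amp[sel] = a
    karst = karst_mask.classes == karst_mask.code_of("K")
    sens = sens * np.where(karst, config.karst_amplification, 1.0)

    # lagged SPEI deficit aligned to the scenario months
    spei = spei_grid.values
    spei_months = spei_grid.months
    deficit = np.zeros((len(months), *grid.shape))
    for i, per in enumerate(months):
        lagged = per - config.response_lag
        if lagged in spei_months:
            layer = spei[spei_months.get_loc(lagged)]
            deficit[i] = np.minimum(0.0, np.nan_to_num(layer, nan=0.0))

    composites, dates = [], []
    for i, per in enumerate(months):
        seasonal = curve_mean + curve_amp * (
            -np.cos(2.0 * np.pi * (month_of[i] - 1) / 12.0)
        )
        value = np.clip(
            seasonal + sens * deficit[i]
            + rng.normal(0.0, config.ndvi_noise_sd, grid.shape),
            -1.0, 1.0,
        )
        depressed = np.clip(
            value - np.abs(rng.normal(0.04, 0.03, grid.shape)), -1.0, 1.0
        )
        ts = per.to_timestamp()
        composites.extend([value, depressed])
        dates.extend([ts, ts + pd.Timedelta(days=16)])
    return composites, dates


def simulate_hydrothermal(config: ScenarioConfig, stations) -> dict[str, MonthlyStack]:
    """Gridded hydrothermal stacks: TMP (°C), PRE (mm), SR (W m⁻²), SM and RM
    (volumetric fraction).

    TMP and PRE follow the station-mean climate plus smooth spatial patterns;
    net shortwave radiation is anticorrelated with the precipitation anomaly
    (wetter months are cloudier); surface (SM) and root-zone (RM) soil
    moisture are first-order low-pass filters of the monthly water balance,
    the root zone with the longer memory, so planted deficits draw them down
    with a lag.
    """
    rng = config.rng(3)
    months = config.months
    month_of = months.month.values
    grid = config.grid
    n_m = len(months)

    t_reg = np.mean([st.t.to_numpy() for st in stations], axis=0)
    p_reg = np.mean([st.p.to_numpy() for st in stations], axis=0)
    pet_reg = thornthwaite_pet(
        pd.Series(t_reg, index=months), config.base_latitude
    ).to_numpy()

    def smooth_field(scale: float) -> np.ndarray:
        coarse = rng.normal(0.0, scale, (6, 6))
        reps = (int(np.ceil(grid.nrows / 6)), int(np.ceil(grid.ncols / 6)))
        return np.kron(coarse, np.ones(reps))[: grid.nrows, : grid.ncols]

    t_pat = smooth_field(0.6)
    p_pat = np.exp(smooth_field(0.12))

    tmp = t_reg[:, None, None] + t_pat + rng.normal(0.0, 0.3, (n_m, *grid.shape))
    pre = np.maximum(
        p_reg[:, None, None] * p_pat
        * np.exp(rng.normal(0.0, 0.08, (n_m, *grid.shape))),
        0.0,
    )

    p_clim = np.array([p_reg[month_of == m].mean() for m in range(1, 13)])
    p_anom = pre - p_clim[month_of - 1][:, None, None]
    sr_seasonal = 165.0 + 55.0 * (-np.cos(2.0 * np.pi * (month_of - 1) / 12.0))
    sr = (
        sr_seasonal[:, None, None]
        - 0.25 * p_anom
        + rng.normal(0.0, 4.0, (n_m, *grid.shape))
    )

    wb = pre - pet_reg[:, None, None]
    supply = 1.0 / (1.0 + np.exp(-wb / 60.0))  # water balance → [0, 1]
    sm = np.empty_like(supply)
    rm = np.empty_like(supply)
    sm[0] = rm[0] = supply[0]
    for i in range(1, n_m):
        sm[i] = 0.70 * sm[i - 1] + 0.30 * supply[i]
        rm[i] = 0.90 * rm[i - 1] + 0.10 * supply[i]
    sm = np.clip(sm * 0.5 + 0.1, 0.0, 1.0)   # map to plausible vol. fractions
    rm = np.clip(rm * 0.45 + 0.12, 0.0, 1.0)

    def stack(arr, name, units):
        return MonthlyStack(arr, months, grid, name=name, units=units)

    return {
        "TMP": stack(tmp, "TMP", "degC"),
        "PRE": stack(pre, "PRE", "mm"),
        "SR": stack(sr, "SR", "W m-2"),
        "SM": stack(sm, "SM", "m3 m-3"),
        "RM": stack(rm, "RM", "m3 m-3"),
    }


@dataclass
class Scenario:
    """A fully generated scenario bundle."""

    config: ScenarioConfig
    stations: list
    veg_mask: CategoricalMask
    karst_mask: CategoricalMask
    spei_grid: MonthlyStack
    composites: list
    composite_dates: list
    hydrothermal: dict
    ground_truth: GroundTruth


def generate_scenario(config: ScenarioConfig,
                      with_hydrothermal: bool = True) -> Scenario:
    """Generate the full scenario: climate → masks → station SPEI on the grid
    → NDVI composites (→ hydrothermal stacks)."""
    stations, gt = simulate_climate(config)
    veg, karst = simulate_masks(config)
    spei_grid = station_spei_grid(stations, config.grid)
    composites, dates = simulate_ndvi(config, spei_grid, veg, karst)
    hydro = simulate_hydrothermal(config, stations) if with_hydrothermal else {}
    return Scenario(
        config=config,
        stations=stations,
        veg_mask=veg,
        karst_mask=karst,
        spei_grid=spei_grid,
        composites=composites,
        composite_dates=dates,
        hydrothermal=hydro,
        ground_truth=gt,
    )
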