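"""Pipeline orchestration: station QC, stage sequencing, file I/O and the run
report.

The full analysis runs station climate → per-station SPEI-6 → regional
run-theory events → (optional) station-to-grid interpolation → NDVI maximum
value compositing → drought-excluded baselines and anomalies → zonal
summaries by vegetation type and landform → hydrothermal anomaly series.
Stages whose inputs are not configured are skipped with a warning, so a
stations-only configuration still yields SPEI and event outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import greenness as gr
from . import stratify as st
from .interp import StationField, fit_variogram, idw, ordinary_kriging
from .rasters import (GridSpec, MonthlyStack, read_dated_rasters,
                      read_grid_spec, read_raster, write_dated_rasters,
                      write_grid_spec, write_raster)
from .spei import ClimateSeries, fit_spei
from .stratify import CategoricalMask

__all__ = [
    "PipelineConfig",
    "RunReport",
    "read_station_csv",
    "write_station_csv",
    "analyze_scenario",
    "run_pipeline",
]

log = logging.getLogger("drought_greenness")

STATION_COLUMNS = ["station_id", "lat", "lon", "elev_m", "year", "month",
                   "tmp_c", "pre_mm"]

_KNOWN_KEYS = {
    "stations", "ndvi_dir", "hydrothermal_dir", "veg_mask", "karst_mask",
    "out_dir", "k", "calibration_period", "threshold", "min_duration",
    "merge_gap", "max_missing_fraction", "interpolation", "idw_power",
    "ndvi_eps", "strata", "seed",
}


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown configuration keys are rejected."""

    out_dir: str
    stations: str | None = None
    ndvi_dir: str | None = None
    hydrothermal_dir: str | None = None
    veg_mask: str | None = None
    karst_mask: str | None = None
    k: int = 6
    calibration_period: tuple | None = None
    threshold: float = -1.0
    min_duration: int = 2
    merge_gap: int = 1
    max_missing_fraction: float = 0.05
    interpolation: str = "kriging"
    idw_power: float = 2.0
    ndvi_eps: float = 0.01
    strata: tuple = ("BDF", "NDF", "SCR", "MDW", "GRA")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ValueError("configuration must set out_dir")
        cfg = cls(**raw)
        if cfg.interpolation not in ("kriging", "idw"):
            raise ValueError(f"unknown interpolation {cfg.interpolation!r}")
        if cfg.k < 1 or cfg.min_duration < 1 or cfg.merge_gap < 0:
            raise ValueError("invalid k / min_duration / merge_gap")
        return cfg


@dataclass
class RunReport:
    """Per-stage provenance: parameters, outputs (with checksums), warnings."""

    parameters: dict
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    event_table: list = field(default_factory=list)

    def add_output(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def write(self, path: Path) -> None:
        payload = {
            "parameters": self.parameters,
            "stages": self.stages,
            "event_table": self.event_table,
            "warnings": self.warnings,
            "outputs": self.outputs,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def read_station_csv(
    path: str | Path, max_missing_fraction: float = 0.05
):
    """Read the station climate CSV and apply the missing-data QC rule.

    Schema: ``station_id, lat, lon, elev_m, year, month, tmp_c, pre_mm`` with
    missing values as empty fields.  A station is excluded when the fraction
    of months (over its own first-to-last span) with any missing value exceeds
    ``max_missing_fraction``.  Returns ``(stations, exclusion_log)``.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"station_id": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty station file") from None
    if list(frame.columns) != STATION_COLUMNS:
        raise ValueError(
            f"{path}: header {list(frame.columns)} != expected {STATION_COLUMNS}"
        )
    if len(frame) == 0:
        raise ValueError(f"{path}: no station rows")
    for col in ("year", "month"):
        bad = frame[frame[col].isna() | (frame[col] % 1 != 0)]
        if len(bad):
            raise ValueError(
                f"{path}: malformed {col} at line {int(bad.index[0]) + 2}"
            )
    dup = frame.duplicated(subset=["station_id", "year", "month"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (station, year, month) row at line "
            f"{int(frame.index[dup.argmax()]) + 2}"
        )

    stations, exclusions = [], []
    for sid, g in frame.groupby("station_id", sort=True):
        g = g.sort_values(["year", "month"])
        idx = pd.PeriodIndex.from_fields(
            year=g["year"].astype(int), month=g["month"].astype(int), freq="M"
        )
        span = pd.period_range(idx[0], idx[-1], freq="M")
        t = pd.Series(g["tmp_c"].to_numpy(float), index=idx).reindex(span)
        p = pd.Series(g["pre_mm"].to_numpy(float), index=idx).reindex(span)
        missing_frac = float((t.isna() | p.isna()).mean())
        if missing_frac > max_missing_fraction:
            exclusions.append(
                {"station_id": sid, "missing_fraction": missing_frac}
            )
            continue
        cs = ClimateSeries(
            station_id=str(sid),
            latitude=float(g["lat"].iloc[0]),
            longitude=float(g["lon"].iloc[0]),
            elevation=float(g["elev_m"].iloc[0]),
            t=t,
            p=p,
        )
        stations.append(cs)
    if exclusions:
        log.info("excluded %d stations by the %.0f%% missing-data rule",
                 len(exclusions), 100 * max_missing_fraction)
    return stations, exclusions


def write_station_csv(path: str | Path, stations, coords: bool = True) -> None:
    """Write stations in the documented CSV schema (missing as empty)."""
    rows = []
    for stn in stations:
        for per in stn.t.index:
            rows.append(
                {
                    "station_id": stn.station_id,
                    "lat": stn.latitude,
                    "lon": stn.longitude,
                    "elev_m": stn.elevation,
                    "year": per.year,
                    "month": per.month,
                    "tmp_c": stn.t[per],
                    "pre_mm": stn.p[per],
                }
            )
    pd.DataFrame(rows, columns=STATION_COLUMNS).to_csv(path, index=False)


def station_xy(stations) -> np.ndarray:
    """Planar station coordinates: generator-attached (x, y) when present,
    otherwise an equirectangular projection of (lon, lat) in metres."""
    out = []
    for stn in stations:
        if hasattr(stn, "x") and hasattr(stn, "y"):
            out.append((stn.x, stn.y))
        else:
            lat0 = np.mean([s.latitude for s in stations])
            out.append((
                stn.longitude * 111_000.0 * np.cos(np.deg2rad(lat0)),
                stn.latitude * 111_000.0,
            ))
    return np.asarray(out, dtype=float)


def _read_mask(path: str | Path) -> CategoricalMask:
    path = Path(path)
    labels = {
        int(k): v
        for k, v in json.loads(path.with_suffix(".json").read_text()).items()
    }
    grid = read_grid_spec(path.parent)
    return CategoricalMask(read_raster(path), labels, grid)


def write_mask(path: str | Path, mask: CategoricalMask) -> None:
    path = Path(path)
    write_grid_spec(path.parent, mask.grid)
    write_raster(path, mask.classes, dtype="int16")
    path.with_suffix(".json").write_text(
        json.dumps({str(k): v for k, v in mask.labels.items()}, indent=2)
    )


@dataclass
class AnalysisResult:
    """In-memory results of the full analysis (used by the file pipeline and
    directly by tests and the acceptance script)."""

    spei_by_station: dict
    regional_spei: pd.Series
    events: list
    event_month_mask: pd.Series
    ndvi_monthly: MonthlyStack | None = None
    climatology: gr.Climatology | None = None
    anomaly_abs: MonthlyStack | None = None
    anomaly_pct: MonthlyStack | None = None
    drought_window_anomaly: np.ndarray | None = None
    veg_summaries: list = field(default_factory=list)
    landform_summaries: list = field(default_factory=list)
    cross_summaries: list = field(default_factory=list)
    hydrothermal: dict = field(default_factory=dict)


def analyze_scenario(
    stations,
    composites=None,
    composite_dates=None,
    grid: GridSpec | None = None,
    veg_mask: CategoricalMask | None = None,
    karst_mask: CategoricalMask | None = None,
    hydrothermal: dict | None = None,
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Run the full in-memory analysis on already-loaded inputs.

    The regional SPEI series is the station mean per month; events are
    identified on it by run theory; NDVI anomalies use baselines excluding
    event months; summaries stratify the drought-window mean anomaly.
    """
    cfg = config or PipelineConfig(out_dir=".")

    spei_by_station = {
        s.station_id: fit_spei(s, k=cfg.k,
                               calibration_period=cfg.calibration_period)
        for s in stations
    }
    spei_frame = pd.DataFrame(
        {sid: res.spei for sid, res in spei_by_station.items()}
    )
    regional = spei_frame.mean(axis=1, skipna=False)
    regional.name = f"spei{cfg.k}"

    evs = ev.identify_events(
        regional.dropna(),
        threshold=cfg.threshold,
        min_duration=cfg.min_duration,
        merge_gap=cfg.merge_gap,
    )
    emask = ev.event_mask(evs, regional.index)

    result = AnalysisResult(
        spei_by_station=spei_by_station,
        regional_spei=regional,
        events=evs,
        event_month_mask=emask,
    )
    if composites is None:
        return result

    ndvi = gr.mvc_monthly(composites, composite_dates, grid)
    clim = gr.baseline_climatology(ndvi, emask)
    anom_abs, anom_pct = gr.monthly_anomalies(ndvi, clim, eps=cfg.ndvi_eps)
    result.ndvi_monthly = ndvi
    result.climatology = clim
    result.anomaly_abs = anom_abs
    result.anomaly_pct = anom_pct

    # drought-window mean cellwise anomaly (all event months pooled)
    in_event = emask.reindex(ndvi.months, fill_value=False).to_numpy()
    if in_event.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            result.drought_window_anomaly = np.nanmean(
                anom_abs.values[in_event], axis=0
            )
    if veg_mask is not None and result.drought_window_anomaly is not None:
        result.veg_summaries = st.zonal_summary(
            result.drought_window_anomaly, veg_mask,
            include=list(cfg.strata), scope="drought-window",
        )
        if karst_mask is not None:
            result.landform_summaries = st.zonal_summary(
                result.drought_window_anomaly, karst_mask, exclude=(),
                scope="drought-window",
            )
            result.cross_summaries = st.cross_stratify(
                result.drought_window_anomaly, veg_mask, karst_mask,
                include=list(cfg.strata), scope="drought-window",
            )

    for name, stack in (hydrothermal or {}).items():
        result.hydrothermal[name] = st.hydrothermal_summary(
            stack, emask, mask=None, eps=1e-6
        )
    return result


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages against files on disk and write all
    outputs (CSV/JSON/TIFF) plus a provenance report with checksums."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(parameters=asdict(config))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            result, grid, veg, karst = _run_stages(config, report, out_dir)
        except Exception as exc:
            stage = report.stages[-1] if report.stages else "setup"
            report.warnings.append(f"aborted in stage {stage}: {exc}")
            report.write(out_dir / "run_report.json")
            raise
        report.warnings.extend(str(w.message) for w in caught)

    report.write(out_dir / "run_report.json")
    return report


def _run_stages(config: PipelineConfig, report: RunReport, out_dir: Path):
    if config.stations is None:
        raise ValueError("configuration must point to a station CSV")
    report.stages.append("stations")
    stations, excluded = read_station_csv(
        config.stations, config.max_missing_fraction
    )
    for e in excluded:
        report.warnings.append(
            f"station {e['station_id']} excluded "
            f"({100 * e['missing_fraction']:.2f}% missing)"
        )
    if not stations:
        raise ValueError("no stations survive the missing-data rule")

    composites = dates = grid = veg = karst = None
    hydro = {}
    if config.ndvi_dir is not None:
        report.stages.append("ndvi-read")
        arrays, dts, grid = read_dated_rasters(config.ndvi_dir)
        composites, dates = arrays, dts
    else:
        report.warnings.append("no NDVI directory configured; greenness stages skipped")
    if config.veg_mask is not None:
        veg = _read_mask(config.veg_mask)
        grid = grid or veg.grid
    if config.karst_mask is not None:
        karst = _read_mask(config.karst_mask)
    if config.hydrothermal_dir is not None:
        report.stages.append("hydrothermal-read")
        hdir = Path(config.hydrothermal_dir)
        hgrid = read_grid_spec(hdir)
        for sub in sorted(hdir.glob("*_stack")):
            name = sub.name.replace("_stack", "")
            arrays, dts, _ = read_dated_rasters(sub)
            months = pd.PeriodIndex([pd.Period(d, freq="M") for d in dts])
            hydro[name] = MonthlyStack(np.stack(arrays), months, hgrid, name=name)

    report.stages.append("analysis")
    result = analyze_scenario(
        stations, composites, dates, grid, veg, karst, hydro or None, config
    )

    report.stages.append("write-outputs")
    # SPEI per station
    spei_rows = []
    for sid, res in result.spei_by_station.items():
        for per, val in res.spei.items():
            if pd.isna(val):
                continue
            from .spei import classify_severity
            spei_rows.append(
                {"station_id": sid, "year": per.year, "month": per.month,
                 f"spei{config.k}": val,
                 "severity_class": str(classify_severity(val))}
            )
    spei_path = out_dir / "spei_stations.csv"
    pd.DataFrame(spei_rows).to_csv(spei_path, index=False)
    report.add_output(spei_path)

    regional_path = out_dir / "spei_regional.csv"
    result.regional_spei.rename_axis("month").to_csv(regional_path)
    report.add_output(regional_path)

    events_frame = ev.events_to_frame(result.events)
    events_path = out_dir / "drought_events.csv"
    events_frame.to_csv(events_path, index=False)
    report.add_output(events_path)
    report.event_table = events_frame.to_dict("records")
    events_json = out_dir / "drought_events.json"
    events_json.write_text(json.dumps(
        [
            {
                "event_id": i + 1,
                "onset": str(e.onset),
                "termination": str(e.termination),
                "duration_months": e.duration,
                "peak_spei": e.peak_spei,
                "event_class": str(e.event_class),
                "month_classes": {str(m): str(c)
                                  for m, c in e.month_classes.items()},
            }
            for i, e in enumerate(result.events)
        ],
        indent=2,
    ))
    report.add_output(events_json)

    if grid is not None and result.events:
        report.stages.append("interpolation")
        xy = station_xy(stations)
        for e in result.events:
            peak_month = min(
                (m for m in e.months if m in result.regional_spei.index),
                key=lambda m: result.regional_spei[m],
            )
            vals = np.array(
                [res.spei.get(peak_month, np.nan)
                 for res in result.spei_by_station.values()]
            )
            sf = StationField(xy[:, 0], xy[:, 1], vals)
            if config.interpolation == "kriging":
                fld, _ = ordinary_kriging(sf, grid, fit_variogram(sf))
            else:
                fld = idw(sf, grid, power=config.idw_power)
            p = out_dir / f"spei_grid_{peak_month.strftime('%Y%m')}.tif"
            write_raster(p, fld)
            report.add_output(p)

    if result.anomaly_abs is not None:
        write_grid_spec(out_dir, result.anomaly_abs.grid)
        for stack, stem in ((result.anomaly_abs, "ndvi_anom"),
                            (result.anomaly_pct, "ndvi_anom_pct")):
            sel = result.event_month_mask.reindex(
                stack.months, fill_value=False
            )
            for per in stack.months[sel.to_numpy()]:
                p = out_dir / f"{stem}_{per.strftime('%Y%m')}.tif"
                write_raster(p, stack.layer(per))
                report.add_output(p)
        frames = []
        for name, summaries in (("veg", result.veg_summaries),
                                ("landform", result.landform_summaries),
                                ("veg_x_landform", result.cross_summaries)):
            f = st.summaries_to_frame(summaries)
            f.insert(0, "axis", name)
            frames.append(f)
        summary_path = out_dir / "anomaly_summaries.csv"
        pd.concat(frames, ignore_index=True).to_csv(summary_path, index=False)
        report.add_output(summary_path)

    for name, frame in result.hydrothermal.items():
        p = out_dir / f"hydrothermal_{name.lower()}_anomalies.csv"
        frame.to_csv(p, index=False)
        report.add_output(p)

    return result, grid, veg, karst
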