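"""Station-to-grid interpolation: inverse-distance weighting and ordinary
kriging with an exponential variogram.

Kriging is the default interpolator for SPEI and climate fields; IDW is the
fast fallback for degenerate station sets.  Coordinates are planar (projected
metres); CRS transforms are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve, LinAlgError
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .rasters import GridSpec

__all__ = [
    "StationField",
    "VariogramModel",
    "idw",
    "fit_variogram",
    "ordinary_kriging",
    "interpolate_stack",
]


@dataclass
class StationField:
    """Per-station (x, y, value) triples for one time slice."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.values)):
            raise ValueError("x, y, values must have equal length")
        keep = np.isfinite(self.values)
        if not keep.all():
            self.x, self.y, self.values = self.x[keep], self.y[keep], self.values[keep]
        if len(self.values) == 0:
            raise ValueError("need at least one non-missing station")
        coords = np.column_stack([self.x, self.y])
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ValueError("duplicate station coordinates")

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class VariogramModel:
    """Exponential semivariogram with effective range ``range_``:

        gamma(h) = nugget + (sill − nugget) · (1 − exp(−3h / range_)),  h > 0

    with the nugget discontinuity at the origin (gamma(0) = nugget by
    convention here; the kriging system uses 0 on its diagonal)."""

    nugget: float
    sill: float
    range_: float
    model: str = "exponential"

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.sill < self.nugget or self.range_ <= 0:
            raise ValueError(
                f"invalid variogram (nugget={self.nugget}, sill={self.sill}, "
                f"range={self.range_})"
            )

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        return self.nugget + (self.sill - self.nugget) * (
            1.0 - np.exp(-3.0 * h / self.range_)
        )


def _grid_coords(grid: GridSpec) -> np.ndarray:
    gx, gy = grid.cell_centers()
    return np.column_stack([gx.ravel(), gy.ravel()])


def idw(stations: StationField, grid: GridSpec, power: float = 2.0) -> np.ndarray:
    """Inverse-distance-power weighted interpolation onto the grid.

    Exact at cells colocated with a station; output is bounded by the station
    value range.
    """
    pts = _grid_coords(grid)
    d = cdist(pts, stations.coords)
    colocated = d < 1e-9
    with np.errstate(divide="ignore"):
        w = d ** -power
    w[np.isinf(w)] = 0.0
    # colocated cells take the station value exactly
    hit = colocated.any(axis=1)
    w[hit] = 0.0
    w[colocated] = 1.0
    field = (w @ stations.values) / w.sum(axis=1)
    return field.reshape(grid.shape)


def _empirical_variogram(stations: StationField, n_bins: int = 15,
                         max_dist: float | None = None):
    d = cdist(stations.coords, stations.coords)
    iu = np.triu_indices_from(d, k=1)
    h = d[iu]
    sq = 0.5 * (stations.values[:, None] - stations.values[None, :])[iu] ** 2
    if max_dist is None:
        # short lags carry the range information; long-lag bins only add noise
        max_dist = h.max() / 3.0
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (h > lo) & (h <= hi)
        if sel.sum() < 5:
            continue
        centers.append(h[sel].mean())
        gammas.append(sq[sel].mean())
        counts.append(sel.sum())
    return np.array(centers), np.array(gammas), np.array(counts)


def fit_variogram(stations: StationField, n_bins: int = 15,
                  max_dist: float | None = None) -> VariogramModel:
    """Weighted least-squares fit of the exponential model to the empirical
    semivariogram, with N/h² bin weights so the short lags that carry the
    range information dominate.

    A constant field yields a degenerate pure-nugget model with a warning.
    """
    if len(stations.values) < 10:
        raise ValueError("variogram fitting needs >= 10 stations")
    if np.ptp(stations.values) == 0.0:
        warnings.warn("all station values equal; returning pure-nugget model")
        return VariogramModel(nugget=0.0, sill=0.0, range_=1.0)

    h, g, n = _empirical_variogram(stations, n_bins=n_bins, max_dist=max_dist)
    if len(h) < 3:
        raise ValueError("too few usable distance bins for variogram fitting")
    var = stations.values.var()
    w = np.sqrt(n) / np.maximum(h, 1e-9)

    def residuals(theta):
        nugget, psill, rng = theta
        model = nugget + psill * (1.0 - np.exp(-3.0 * h / rng))
        return w * (model - g)

    res = least_squares(
        residuals,
        x0=[0.0, var, h.max() / 2.0],
        bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
    )
    nugget, psill, rng = res.x
    return VariogramModel(nugget=float(nugget), sill=float(nugget + psill),
                          range_=float(rng))


def ordinary_kriging(
    stations: StationField,
    grid: GridSpec,
    variogram: VariogramModel,
    return_weights: bool = False,
):
    """Ordinary kriging of station values onto the grid.

    Solves the standard semivariance system with the unbiasedness constraint
    (weights sum to 1).  Exact at stations when the nugget is zero.  Returns
    ``(field, variance)``; the kriging variance is clipped at 0 against
    round-off.  A singular system triggers one jittered retry, then an error.
    """
    n = len(stations.values)
    d = cdist(stations.coords, stations.coords)

    def build(dmat):
        a = np.zeros((n + 1, n + 1))
        a[:n, :n] = variogram(dmat)
        np.fill_diagonal(a[:n, :n], 0.0)
        a[n, :n] = 1.0
        a[:n, n] = 1.0
        return a

    def factor(a):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            lu = lu_factor(a)
        if np.abs(np.diag(lu[0])).min() < 1e-12 or not np.all(np.isfinite(lu[0])):
            raise LinAlgError("singular kriging system")
        return lu

    a = build(d)
    try:
        lu = factor(a)
    except (LinAlgError, Warning):
        warnings.warn("singular kriging system; retrying with jitter")
        a = build(d)
        a[:n, :n] += 1e-10 * np.eye(n)
        lu = factor(a)

    pts = _grid_coords(grid)
    d0 = cdist(stations.coords, pts)
    b = np.vstack([variogram(d0), np.ones(len(pts))])
    b[:n][d0 < 1e-12] = 0.0  # gamma(0) = 0 at colocated targets
    sol = lu_solve(lu, b)
    weights, mu = sol[:n], sol[n]
    field = (weights * stations.values[:, None]).sum(axis=0)
    variance = np.maximum((weights * b[:n]).sum(axis=0) + mu, 0.0)
    out = (field.reshape(grid.shape), variance.reshape(grid.shape))
    if return_weights:
        return out + (weights,)
    return out


def interpolate_stack(
    station_xy: np.ndarray,
    values_by_time: np.ndarray,
    grid: GridSpec,
    method: str = "idw",
    power: float = 2.0,
) -> np.ndarray:
    """Interpolate a (time, station) value matrix to (time, rows, cols).

    ``method`` is ``idw`` or ``kriging`` (per-slice variogram fit); time
    slices with no finite station value come back all-NaN.
    """
    out = np.full((len(values_by_time), *grid.shape), np.nan)
    for i, vals in enumerate(values_by_time):
        if not np.isfinite(vals).any():
            continue
        sf = StationField(station_xy[:, 0], station_xy[:, 1], vals)
        if method == "idw":
            out[i] = idw(sf, grid, power=power)
        elif method == "kriging":
            vg = fit_variogram(sf)
            out[i] = ordinary_kriging(sf, grid, vg)[0]
        else:
            raise ValueError(f"unknown interpolation method {method!r}")
    return out
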