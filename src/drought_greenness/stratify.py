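"""Zonal summaries over categorical strata.

Summaries of anomaly or hydrothermal fields are reported by vegetation type
(BDF broadleaf forest, NDF needleleaf forest, SCR scrubland, MDW meadow, GRA
grassland; OTH — human-modified or sparse classes — is excluded by default),
by karst vs non-karst landform, and by their cross-classification.  Cells
invalid in any layer of a comparison are dropped listwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .greenness import baseline_climatology, monthly_anomalies
from .rasters import GridSpec, MonthlyStack

__all__ = [
    "CategoricalMask",
    "StratumSummary",
    "VEG_LABELS",
    "LANDFORM_LABELS",
    "zonal_summary",
    "cross_stratify",
    "hydrothermal_summary",
    "summaries_to_frame",
]

VEG_LABELS = {1: "BDF", 2: "NDF", 3: "SCR", 4: "MDW", 5: "GRA", 6: "OTH"}
LANDFORM_LABELS = {1: "K", 2: "NK"}

#: integer code marking cells outside the valid domain
INVALID = -1


@dataclass
class CategoricalMask:
    """Grid-aligned integer class raster with a code → label map."""

    classes: np.ndarray
    labels: dict[int, str]
    grid: GridSpec

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=int)
        if self.classes.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.classes.shape} != grid {self.grid.shape}"
            )
        present = set(np.unique(self.classes)) - {INVALID}
        unknown = present - set(self.labels)
        if unknown:
            raise ValueError(f"codes {sorted(unknown)} missing from label map")

    @property
    def label_of(self) -> dict[int, str]:
        return self.labels

    def code_of(self, label: str) -> int:
        for code, lab in self.labels.items():
            if lab == label:
                return code
        raise KeyError(label)

    def shares(self) -> dict[str, float]:
        """Class shares as fractions of valid cells."""
        valid = self.classes != INVALID
        n = valid.sum()
        return {
            lab: float(np.sum(self.classes == code) / n)
            for code, lab in sorted(self.labels.items())
        }


@dataclass
class StratumSummary:
    stratum: str
    n: int
    mean: float
    sd: float
    min: float
    max: float
    scope: str = ""


def _summarize(values: np.ndarray, stratum: str, scope: str) -> StratumSummary:
    return StratumSummary(
        stratum=stratum,
        n=int(values.size),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        min=float(values.min()),
        max=float(values.max()),
        scope=scope,
    )


def zonal_summary(
    field: np.ndarray,
    mask: CategoricalMask,
    include: list[str] | None = None,
    exclude: tuple[str, ...] = ("OTH",),
    scope: str = "",
) -> list[StratumSummary]:
    """Per-class statistics of a 2-D field over valid (finite, labelled) cells.

    ``include`` restricts to the listed labels; otherwise all labels except
    ``exclude`` are reported.  A requested class absent from the mask is
    omitted with a warning.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != mask.grid.shape:
        raise ValueError("field and mask grids differ")
    wanted = include if include is not None else [
        lab for _, lab in sorted(mask.labels.items()) if lab not in exclude
    ]
    out = []
    for label in wanted:
        code = mask.code_of(label)
        cells = field[(mask.classes == code) & np.isfinite(field)]
        if cells.size == 0:
            warnings.warn(f"class {label} has no valid cells; omitted")
            continue
        out.append(_summarize(cells, label, scope))
    return out


def cross_stratify(
    field: np.ndarray,
    veg_mask: CategoricalMask,
    landform_mask: CategoricalMask,
    include: list[str] | None = None,
    exclude: tuple[str, ...] = ("OTH",),
    scope: str = "",
) -> list[StratumSummary]:
    """Vegetation × landform summaries; empty intersections are omitted with a
    warning.  Stratum labels are ``VEG/LANDFORM`` (e.g. ``MDW/K``)."""
    field = np.asarray(field, dtype=float)
    veg_wanted = include if include is not None else [
        lab for _, lab in sorted(veg_mask.labels.items()) if lab not in exclude
    ]
    out = []
    for vlab in veg_wanted:
        vcode = veg_mask.code_of(vlab)
        for lcode, llab in sorted(landform_mask.labels.items()):
            sel = (
                (veg_mask.classes == vcode)
                & (landform_mask.classes == lcode)
                & np.isfinite(field)
            )
            cells = field[sel]
            if cells.size == 0:
                warnings.warn(f"empty stratum {vlab}/{llab}; omitted")
                continue
            out.append(_summarize(cells, f"{vlab}/{llab}", scope))
    return out


def hydrothermal_summary(
    stack: MonthlyStack,
    drought_month_mask: pd.Series,
    mask: CategoricalMask | None = None,
    eps: float = 1e-6,
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-month anomaly series of a gridded variable, optionally per stratum.

    Applies the drought-excluded baseline and anomaly machinery to the stack,
    then reduces each month to stratum means: the absolute column is the mean
    cellwise absolute anomaly; percent is taken against the stratum-mean
    baseline.  With no mask a single ``ALL`` stratum covers the domain.
    Returns a tidy frame (month, stratum, absolute, percent, baseline, n).
    """
    clim = baseline_climatology(stack, drought_month_mask)
    abs_stack, _ = monthly_anomalies(stack, clim, eps=eps)
    month_of = stack.months.month.values
    base_layers = clim.baseline[month_of - 1]

    if mask is None:
        strata = {"ALL": np.ones(stack.grid.shape, dtype=bool)}
    else:
        if mask.grid.shape != stack.grid.shape:
            raise ValueError("variable stack and mask grids differ")
        strata = {
            lab: mask.classes == code
            for code, lab in sorted(mask.labels.items())
            if lab not in exclude
        }

    rows = []
    for i, per in enumerate(stack.months):
        for lab, sel in strata.items():
            cells = sel & np.isfinite(abs_stack.values[i]) & np.isfinite(base_layers[i])
            if not cells.any():
                continue
            mean_abs = float(abs_stack.values[i][cells].mean())
            mean_base = float(base_layers[i][cells].mean())
            pct = (
                100.0 * mean_abs / mean_base if abs(mean_base) >= eps else float("nan")
            )
            rows.append(
                {
                    "month": per,
                    "stratum": lab,
                    "absolute": mean_abs,
                    "percent": pct,
                    "baseline": mean_base,
                    "n": int(cells.sum()),
                }
            )
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: list[StratumSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scope": s.scope,
                "stratum": s.stratum,
                "n": s.n,
                "mean": s.mean,
                "sd": s.sd,
                "min": s.min,
                "max": s.max,
            }
            for s in summaries
        ]
    )
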