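"""Pair records with climate and human-population-density covariates.

Each record gets the mean annual temperature and precipitation of its
collection year (value of the grid cell containing the point) and the
natural-log human population density of its collection decade, optionally
after block-mean aggregation of the density raster to coarser scales.
Continuous predictors are mean-centered and scaled to unit (sample) SD
before modelling, with the means/SDs kept so fitted coefficients can be
expressed per natural unit (degC, mm, log persons/km^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridGeometry, RasterStack, aggregate_blocks
from .synth import DENSITY_FLOOR

__all__ = [
    "extract_climate",
    "extract_density",
    "aggregate_density",
    "standardize",
    "unstandardize",
    "Standardization",
]


def _sample_by_time(records: pd.DataFrame, stack: RasterStack,
                    time_col: str, nearest: bool) -> np.ndarray:
    lon = records["decimal_longitude"].to_numpy(float)
    lat = records["decimal_latitude"].to_numpy(float)
    times = records[time_col].to_numpy(int)
    out = np.full(len(records), np.nan)
    for t in np.unique(times):
        sel = times == t
        out[sel] = stack.sample(lon[sel], lat[sel], int(t), nearest=nearest)
    return out


def extract_climate(records: pd.DataFrame, mat_stack: RasterStack,
                    map_stack: RasterStack, audit=None) -> pd.DataFrame:
    """Add MAT/MAP of each record's collection year.

    Points outside the raster extent are excluded (with an audit entry
    when an audit log is given).
    """
    out = records.copy()
    out["MAT"] = _sample_by_time(out, mat_stack, "year", nearest=True)
    out["MAP"] = _sample_by_time(out, map_stack, "year", nearest=True)
    keep = out["MAT"].notna() & out["MAP"].notna()
    if audit is not None:
        audit.add("climate_extent", len(out), int((~keep).sum()))
    return out[keep]


def aggregate_density(stack: RasterStack, factor: int) -> RasterStack:
    """Block-mean aggregation of every layer by ``factor`` in each axis."""
    data = {t: aggregate_blocks(arr, factor) for t, arr in stack.data.items()}
    g = stack.geometry
    nr, nc = next(iter(data.values())).shape
    geom = GridGeometry(g.west, g.south, g.cell_size * factor, nr, nc)
    return RasterStack(stack.variable, stack.units, geom, data)


def extract_density(records: pd.DataFrame, density_stack: RasterStack,
                    scale_factor: int = 1, audit=None,
                    column: str = "log_density") -> pd.DataFrame:
    """Add log population density of each record's decade.

    ``scale_factor`` block-aggregates the base raster first (e.g. 4 and 10
    for the coarser assessment scales).  Records dated outside the stack's
    decade coverage use the nearest available decade layer.  The value is
    ln(density + floor) with a 0.01 persons/km^2 floor.
    """
    stack = aggregate_density(density_stack, scale_factor) if scale_factor > 1 \
        else density_stack
    out = records.copy()
    dens = _sample_by_time(out, stack, "decade_start", nearest=True)
    out[column] = np.log(dens + DENSITY_FLOOR)
    keep = out[column].notna()
    if audit is not None:
        audit.add(f"density_extent_{column}", len(out), int((~keep).sum()))
    return out[keep]


@dataclass
class Standardization:
    """Per-variable centering/scaling metadata (sample SD, ddof=1)."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def coefficient_per_unit(self, variable: str, beta_std: float) -> float:
        """Back-transform a standardized coefficient to natural units."""
        return beta_std / self.sds[variable]


def standardize(dataset: pd.DataFrame, variables: list[str],
                suffix: str = "_std") -> tuple[pd.DataFrame, Standardization]:
    """Mean-center and scale each variable to unit sample SD.

    Adds ``<var><suffix>`` columns; raises on zero-variance input.
    """
    out = dataset.copy()
    meta = Standardization()
    for var in variables:
        x = pd.to_numeric(out[var], errors="coerce")
        mu = float(x.mean())
        sd = float(x.std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"variable {var!r} has zero variance")
        out[var + suffix] = (x - mu) / sd
        meta.means[var] = mu
        meta.sds[var] = sd
    return out, meta


def unstandardize(values, variable: str, meta: Standardization):
    """Inverse of :func:`standardize` for one variable."""
    return np.asarray(values, dtype=float) * meta.sds[variable] + meta.means[variable]
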