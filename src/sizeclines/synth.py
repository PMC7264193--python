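"""Synthetic study system with fully known generative truth.

Emulates the inputs of a continental body-size-cline study of the deer
mouse: year-indexed climate surfaces (MAT, MAP), decade-indexed human
population density, an ecoregion map, and a multi-source trait-record
table with realistic contamination (juveniles, implausible masses,
placeholder dates, ambiguous sexes, gross outliers) plus a known
measurement bias for live-capture head-body lengths.

Every random draw is bounded (normal deviates truncated at 2.5 SD):
mouse masses and lengths are biologically bounded quantities, and
boundedness gives the downstream filtering steps unambiguous ground
truth — a clean record can never stray past the outlier threshold or
below the 9 g adult mass floor under the default parameters.

The generator knows each record's zone membership from a fixed 200 km
lattice (independent of the zonation optimizer), each drawn random
effect, and each injected contaminant, so recovery and audit tests have
exact expectations.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .grids import GridGeometry, RasterStack
from .harmonize import assign_season, assign_decade
from .zonation import EcoregionMap, albers_forward, albers_inverse, make_band_ecoregions

__all__ = [
    "GenerativeTruth",
    "SimulationResult",
    "make_climate_surfaces",
    "make_density_stack",
    "make_ecoregions",
    "simulate_records",
    "default_decade_weights",
]

DENSITY_FLOOR = 0.01  # persons/km^2, keeps log finite
_TRUNC = 2.5  # all Gaussian draws truncated at +-2.5 SD

Bounds = tuple[float, float, float, float]  # west, south, east, north
DEFAULT_BOUNDS: Bounds = (-120.0, 30.0, -80.0, 48.0)

# Fixed affine scaling for the decade covariate: centered and scaled over
# the temporal-analysis window (bins 6..13, i.e. 1945-2019), so the
# generator's decade trend and zone slopes live in the same
# parameterization the temporal models estimate.
DECADE_CENTER = 9.5
DECADE_SCALE = float(np.sqrt(5.25))


@dataclass
class GenerativeTruth:
    """Known parameters of the simulator.

    Continuous-effect betas are on standardized covariates, in grams.
    ``sex_offset`` is the female minus male difference (females larger
    when positive); ``season_offsets`` are additive shifts relative to
    fall, the leanest season.  ``source_hb_bias`` is the additive
    head-body-length bias (mm) of live-census (NEON) records.
    """

    intercept: float = 20.0
    beta_mat: float = -0.5
    beta_map: float = -0.5
    beta_density: float = -0.15
    beta_decade: float = -0.2
    sex_offset: float = 0.6
    season_offsets: dict = field(default_factory=lambda: {
        "Fall": 0.0, "Spring": 1.8, "Summer": 0.8, "Winter": 0.9})
    sigma_ecoregion: float = 1.2
    sigma_source: float = 0.2
    sigma_zone_intercept: float = 0.8
    sigma_zone_slope: float = 0.25
    rho_slope_intercept: float = -0.9
    sigma_resid: float = 2.0
    source_hb_bias: float = -4.0
    juvenile_frac: float = 0.02
    sub9g_frac: float = 0.01
    bad_date_frac: float = 0.02
    ambig_sex_frac: float = 0.01
    outlier_frac: float = 0.005

    def __post_init__(self) -> None:
        for name in ("sigma_ecoregion", "sigma_source", "sigma_zone_intercept",
                     "sigma_zone_slope", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.rho_slope_intercept <= 1.0:
            raise ValueError("rho_slope_intercept must lie in [-1, 1]")
        for name in ("juvenile_frac", "sub9g_frac", "bad_date_frac",
                     "ambig_sex_frac", "outlier_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def null(cls) -> "GenerativeTruth":
        """All effects and random-effect SDs zero, no contamination."""
        return cls(beta_mat=0, beta_map=0, beta_density=0, beta_decade=0,
                   sex_offset=0, season_offsets={s: 0.0 for s in
                                                 ("Fall", "Spring", "Summer", "Winter")},
                   sigma_ecoregion=0, sigma_source=0, sigma_zone_intercept=0,
                   sigma_zone_slope=0, rho_slope_intercept=0,
                   source_hb_bias=0, juvenile_frac=0, sub9g_frac=0,
                   bad_date_frac=0, ambig_sex_frac=0, outlier_frac=0)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationResult:
    """Simulated record table plus the hidden truth tables."""

    records: pd.DataFrame
    truth_records: pd.DataFrame  # per-record class, true zone, true covariates
    zone_effects: pd.DataFrame  # drawn (intercept, slope) per lattice zone
    truth: GenerativeTruth
    seed: int
    # (mean, sd) used to standardize each covariate inside the generator;
    # lets tests express the betas per natural unit (degC, mm, ...)
    covariate_scaling: dict[str, tuple[float, float]] = None


def _check_bounds(bounds: Bounds) -> Bounds:
    west, south, east, north = bounds
    if not (east > west and north > south):
        raise ValueError(f"inverted bounds: {bounds}")
    return bounds


def _tnorm(rng: np.random.Generator, size, sd: float = 1.0):
    """Mean-zero truncated-normal draws (cut at +-2.5 SD)."""
    if sd == 0:
        return np.zeros(size)
    return sd * stats.truncnorm.rvs(-_TRUNC, _TRUNC, size=size, random_state=rng)


def _smooth_field(rng: np.random.Generator, lon, lat, amplitude: float,
                  n_waves: int = 4):
    """Smooth random surface: superposition of random-phase plane waves."""
    out = np.zeros_like(lon)
    for _ in range(n_waves):
        kx, ky = rng.uniform(0.05, 0.4, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        out += np.sin(2 * np.pi * (kx * lon + ky * lat) + phase)
    return amplitude * out / np.sqrt(n_waves)


def make_climate_surfaces(region_bounds: Bounds, years, seed: int,
                          warming_trend: float = 0.0,
                          cell_size: float = 0.25) -> tuple[RasterStack, RasterStack]:
    """MAT (degC) and MAP (mm) stacks over ``years`` on one grid.

    MAT declines with latitude (the Bergmann-relevant gradient) plus a
    smooth spatial field and an optional linear warming trend
    (degC/year, relative to the first listed year).  MAP follows an
    independent west-east gradient plus its own smooth field.
    """
    _check_bounds(region_bounds)
    years = sorted(int(y) for y in years)
    if not years:
        raise ValueError("years must be non-empty")
    west, south, east, north = region_bounds
    geom = GridGeometry(west, south, cell_size,
                        n_rows=int(np.ceil((north - south) / cell_size)),
                        n_cols=int(np.ceil((east - west) / cell_size)))
    rng = np.random.default_rng(seed)
    lon, lat = geom.cell_centers()
    mat_base = 24.0 - 0.7 * (lat - south) + _smooth_field(rng, lon, lat, 1.5)
    map_base = 300.0 + 900.0 * (lon - west) / (east - west) \
        + _smooth_field(rng, lon, lat, 120.0)
    map_base = np.clip(map_base, 50.0, None)
    y0 = years[0]
    mat = RasterStack("MAT", "degC", geom,
                      {y: mat_base + warming_trend * (y - y0) for y in years})
    mp = RasterStack("MAP", "mm", geom, {y: map_base.copy() for y in years})
    return mat, mp


def make_density_stack(region_bounds: Bounds, decades, n_cities: int = 25,
                       seed: int = 0, cell_size: float = 0.1) -> RasterStack:
    """Decadal human population density (persons/km^2).

    Density is a strictly positive floor plus exponentially decaying
    kernels around fixed city locations whose amplitudes grow
    monotonically over the decades (urbanization only intensifies).
    """
    _check_bounds(region_bounds)
    decades = [int(d) for d in decades]
    if decades != sorted(decades):
        raise ValueError("decades must be sorted ascending")
    if n_cities < 0:
        raise ValueError("n_cities must be >= 0")
    west, south, east, north = region_bounds
    geom = GridGeometry(west, south, cell_size,
                        n_rows=int(np.ceil((north - south) / cell_size)),
                        n_cols=int(np.ceil((east - west) / cell_size)))
    rng = np.random.default_rng(seed)
    lon, lat = geom.cell_centers()
    city_lon = rng.uniform(west, east, n_cities)
    city_lat = rng.uniform(south, north, n_cities)
    amp0 = rng.lognormal(mean=4.0, sigma=1.0, size=n_cities)
    growth = rng.uniform(1.2, 1.6, n_cities)  # per-decade amplitude factor
    scale = rng.uniform(0.2, 0.6, n_cities)  # kernel e-folding, degrees
    data = {}
    for k, dec in enumerate(decades):
        field_ = np.full(lon.shape, DENSITY_FLOOR)
        for c in range(n_cities):
            dist = np.hypot(lon - city_lon[c], lat - city_lat[c])
            field_ = field_ + amp0[c] * growth[c] ** k * np.exp(-dist / scale[c])
        data[dec] = field_
    return RasterStack("density", "persons/km2", geom, data)


def make_ecoregions(region_bounds: Bounds = DEFAULT_BOUNDS) -> EcoregionMap:
    """Synthetic stand-in ecoregion map (longitudinal bands, 42N splits)."""
    return make_band_ecoregions(_check_bounds(region_bounds))


def default_decade_weights() -> dict[int, float]:
    """Relative record density per decade bin: sparse early collecting,
    a mid-century census pulse, and a present-day survey pulse."""
    starts = range(1895, 2016, 10)
    w = [1, 1, 2, 2, 3, 8, 10, 6, 5, 5, 6, 8, 10]
    return dict(zip(starts, w))


def _zone_lattice(bounds: Bounds, n_zones: int, rng: np.random.Generator,
                  cell_km: float = 200.0):
    """Pick ``n_zones`` distinct 200 km lattice cells inside the region."""
    west, south, east, north = bounds
    L = cell_km * 1000.0
    gx, gy = albers_forward(*np.meshgrid(np.linspace(west, east, 60),
                                         np.linspace(south, north, 60)))
    x_anchor, y_anchor = gx.min(), gy.min()
    cand = []
    i_max = int((gx.max() - x_anchor) // L) + 1
    j_max = int((gy.max() - y_anchor) // L) + 1
    margin = 0.25
    for i in range(i_max):
        for j in range(j_max):
            # whole cell must sit inside the region, not just its center
            cx = x_anchor + (i + np.array([0.0, 1.0, 0.0, 1.0])) * L
            cy = y_anchor + (j + np.array([0.0, 0.0, 1.0, 1.0])) * L
            clon, clat = albers_inverse(cx, cy)
            if (clon.min() >= west + margin and clon.max() <= east - margin
                    and clat.min() >= south + margin and clat.max() <= north - margin):
                cand.append((i, j))
    if n_zones > len(cand):
        raise ValueError(f"region holds only {len(cand)} lattice cells")
    chosen = [cand[k] for k in rng.choice(len(cand), size=n_zones, replace=False)]
    return x_anchor, y_anchor, L, chosen


def _doy_to_date(year: int, doy: int) -> tuple[int, int]:
    month = 1
    days = [31, 29 if calendar.isleap(year) else 28, 31, 30, 31, 30,
            31, 31, 30, 31, 30, 31]
    for dm in days:
        if doy <= dm:
            return month, doy
        doy -= dm
        month += 1
    return 12, 31


def simulate_records(truth: GenerativeTruth,
                     climate: tuple[RasterStack, RasterStack],
                     density: RasterStack,
                     ecoregions: EcoregionMap,
                     n: int,
                     year_range: tuple[int, int] = (1895, 2019),
                     seed: int = 0,
                     n_zones: int = 40,
                     scatter_frac: float = 0.1,
                     mass_missing_frac: float = 0.08,
                     length_missing_frac: float = 0.15,
                     decade_weights: dict[int, float] | None = None,
                     bounds: Bounds = DEFAULT_BOUNDS) -> SimulationResult:
    """Draw ``n`` trait records under the generative model.

    Body mass (g) is the structural response:

        mass = intercept + beta . z(covariates) + sex/season offsets
               + ecoregion + source + zone intercept
               + (beta_decade + zone slope) * z(decade) + residual,

    with the per-zone (intercept, slope) pair drawn from a bivariate
    normal with correlation ``rho_slope_intercept`` on a fixed 200 km
    lattice.  Head-body length tracks mass through a cube-root allometry
    with multiplicative noise; NEON records receive ``source_hb_bias``.
    Contaminants are injected at the stated rates, at most one class per
    record, and labelled in the hidden truth table.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    y_lo, y_hi = int(year_range[0]), int(year_range[1])
    mat_stack, map_stack = climate
    for stack, nm in ((mat_stack, "MAT"), (map_stack, "MAP")):
        ts = stack.times
        if min(ts) > y_lo or max(ts) < y_hi:
            raise ValueError(f"{nm} stack ({min(ts)}-{max(ts)}) does not cover "
                             f"year range {y_lo}-{y_hi}")
    rng = np.random.default_rng(seed)

    # --- locations on the fixed zone lattice -----------------------------
    x_anchor, y_anchor, L, zones = _zone_lattice(bounds, n_zones, rng)
    zone_of = rng.integers(0, n_zones, size=n)
    scatter = rng.random(n) < scatter_frac
    zi = np.array([zones[k][0] for k in zone_of], dtype=float)
    zj = np.array([zones[k][1] for k in zone_of], dtype=float)
    px = x_anchor + (zi + rng.random(n)) * L
    py = y_anchor + (zj + rng.random(n)) * L
    lon, lat = albers_inverse(px, py)
    if scatter.any():
        ns = int(scatter.sum())
        west, south, east, north = bounds
        lon[scatter] = rng.uniform(west + 0.2, east - 0.2, ns)
        lat[scatter] = rng.uniform(south + 0.2, north - 0.2, ns)
        sx, sy = albers_forward(lon[scatter], lat[scatter])
        px[scatter], py[scatter] = sx, sy
    zone_i = ((px - x_anchor) // L).astype(int)
    zone_j = ((py - y_anchor) // L).astype(int)
    true_zone = np.array([f"z{i}_{j}" for i, j in zip(zone_i, zone_j)])

    # --- dates ------------------------------------------------------------
    if decade_weights is None:
        decade_weights = default_decade_weights()
    starts = np.array(sorted(decade_weights))
    usable = [(s, decade_weights[s]) for s in starts
              if s + 9 >= y_lo and s <= y_hi]
    dec_starts = np.array([s for s, _ in usable])
    w = np.array([wt for _, wt in usable], dtype=float)
    w /= w.sum()
    dec_pick = dec_starts[rng.choice(len(dec_starts), size=n, p=w)]
    lo = np.maximum(dec_pick, y_lo)
    hi = np.minimum(dec_pick + 9, y_hi)
    year = (lo + (rng.random(n) * (hi - lo + 1)).astype(int)).astype(int)
    doy = rng.integers(2, 366, size=n)  # 1 avoided: Jan 1 is a contaminant code
    month = np.empty(n, dtype=int)
    day = np.empty(n, dtype=int)
    for i in range(n):
        month[i], day[i] = _doy_to_date(int(year[i]), int(doy[i]))

    # --- source, sex, life stage -----------------------------------------
    source = np.full(n, "VertNet", dtype=object)
    nacsm_era = (year >= 1948) & (year <= 1952)
    source[nacsm_era & (rng.random(n) < 0.5)] = "NACSM"
    neon_era = year >= 2013
    source[neon_era & (rng.random(n) < 0.4)] = "NEON"
    sex = np.where(rng.random(n) < 0.5, "female", "male").astype(object)
    life_stage = np.where(rng.random(n) < 0.75, "adult", "unknown").astype(object)

    season = np.array([assign_season(m, d) for m, d in zip(month, day)])
    dec_idx = np.array([assign_decade(y)[0] for y in year], dtype=float)

    # --- covariates at location/time -------------------------------------
    mat = np.empty(n)
    mp = np.empty(n)
    for y in np.unique(year):
        sel = year == y
        mat[sel] = mat_stack.sample(lon[sel], lat[sel], int(y), nearest=True)
        mp[sel] = map_stack.sample(lon[sel], lat[sel], int(y), nearest=True)
    dens = np.empty(n)
    for d in np.unique(dec_pick):
        sel = dec_pick == d
        dens[sel] = density.sample(lon[sel], lat[sel], int(d), nearest=True)
    if not (np.isfinite(mat).all() and np.isfinite(mp).all()
            and np.isfinite(dens).all()):
        raise ValueError("covariate layers do not cover all record locations")
    log_dens = np.log(dens + DENSITY_FLOOR)

    scaling: dict[str, tuple[float, float]] = {}

    def z(name, v):
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:  # degenerate (e.g. single year)
            scaling[name] = (float(v.mean()), 1.0)
            return np.zeros_like(v)
        scaling[name] = (float(v.mean()), float(sd))
        return (v - v.mean()) / sd

    z_mat, z_map, z_dens = z("MAT", mat), z("MAP", mp), z("log_density", log_dens)
    # decade uses a fixed scaling (temporal-analysis window), not the sample
    scaling["decade"] = (DECADE_CENTER, DECADE_SCALE)
    z_dec = (dec_idx - DECADE_CENTER) / DECADE_SCALE

    # --- random effects ---------------------------------------------------
    eco_label = ecoregions.label(lon, lat)
    eco_levels = pd.unique(eco_label)
    eco_eff = dict(zip(eco_levels, _tnorm(rng, len(eco_levels), truth.sigma_ecoregion)))
    src_levels = ["VertNet", "NACSM", "NEON"]
    src_eff = dict(zip(src_levels, _tnorm(rng, 3, truth.sigma_source)))
    zone_levels = pd.unique(true_zone)
    u1 = _tnorm(rng, len(zone_levels))
    u2 = _tnorm(rng, len(zone_levels))
    rho = truth.rho_slope_intercept
    z_int = truth.sigma_zone_intercept * u1
    z_slp = truth.sigma_zone_slope * (rho * u1 + np.sqrt(1 - rho**2) * u2)
    zone_int = dict(zip(zone_levels, z_int))
    zone_slp = dict(zip(zone_levels, z_slp))

    # --- response ---------------------------------------------------------
    eta = (truth.intercept
           + truth.beta_mat * z_mat + truth.beta_map * z_map
           + truth.beta_density * z_dens + truth.beta_decade * z_dec
           + truth.sex_offset * (sex == "female")
           + np.array([truth.season_offsets[s] for s in season])
           + np.array([eco_eff[e] for e in eco_label])
           + np.array([src_eff[s] for s in source])
           + np.array([zone_int[zn] for zn in true_zone])
           + np.array([zone_slp[zn] for zn in true_zone]) * z_dec)
    mass = eta + _tnorm(rng, n, truth.sigma_resid)

    # cube-root allometry with enough independent length variation that
    # the log-log fit is moderate (adj R2 ~ 0.45), not collinear
    hb = 92.0 * np.cbrt(np.maximum(mass, 1.0) / truth.intercept) \
        * np.exp(_tnorm(rng, n, 0.05))
    hb = hb + np.where(source == "NEON", truth.source_hb_bias, 0.0)
    tail = 70.0 + _tnorm(rng, n, 5.0)
    total = hb + tail

    mass = np.round(mass, 2).astype(object)
    total = np.round(total, 1).astype(object)
    tail = np.round(tail, 1).astype(object)

    # --- missingness ------------------------------------------------------
    miss_mass = rng.random(n) < mass_missing_frac
    miss_len = rng.random(n) < length_missing_frac
    miss_mass &= ~miss_len  # never drop both
    mass[miss_mass] = None
    total[miss_len] = None
    tail[miss_len] = None

    # --- contamination ----------------------------------------------------
    classes = ["clean", "juvenile", "sub9g", "bad_date", "ambig_sex", "outlier"]
    probs = np.array([0.0, truth.juvenile_frac, truth.sub9g_frac,
                      truth.bad_date_frac, truth.ambig_sex_frac,
                      truth.outlier_frac])
    if probs.sum() > 1:
        raise ValueError("contamination fractions sum to more than 1")
    probs[0] = 1.0 - probs.sum()
    truth_class = np.array(classes, dtype=object)[
        rng.choice(len(classes), size=n, p=probs)]

    month_out = month.astype(object)
    day_out = day.astype(object)
    for i in np.flatnonzero(truth_class == "juvenile"):
        life_stage[i] = "juvenile"
        if mass[i] is not None:
            mass[i] = round(float(mass[i]) * 0.55, 2)
    for i in np.flatnonzero(truth_class == "sub9g"):
        mass[i] = round(float(rng.uniform(4.0, 8.5)), 2)
        total[i] = None
        tail[i] = None
        life_stage[i] = "adult"
    for i in np.flatnonzero(truth_class == "bad_date"):
        variant = rng.integers(0, 3)
        if variant == 0:
            month_out[i] = None
            day_out[i] = None
        elif variant == 1:
            month_out[i], day_out[i] = 1, 1
        else:
            year[i] = int(rng.integers(1850, 1895))
    for i in np.flatnonzero(truth_class == "ambig_sex"):
        sex[i] = rng.choice(["female?", "male?", "undetermined", ""])
    for i in np.flatnonzero(truth_class == "outlier"):
        if mass[i] is None:
            mass[i] = round(float(eta[i]), 2)
        if total[i] is None:
            total[i], tail[i] = round(float(hb[i] + 70.0), 1), 70.0
        mass[i] = round(float(mass[i]) * 3.0, 2)
        total[i] = round(float(total[i]) * 2.5, 1)

    record_id = np.array([f"r{i:06d}" for i in range(n)])
    records = pd.DataFrame({
        "record_id": record_id,
        "source": source,
        "decimal_latitude": np.round(lat, 5),
        "decimal_longitude": np.round(lon, 5),
        "year": year,
        "month": month_out,
        "day": day_out,
        "sex": sex,
        "life_stage": life_stage,
        "body_mass": mass,
        "total_length": total,
        "tail_length": tail,
    })
    truth_records = pd.DataFrame({
        "record_id": record_id,
        "truth_class": truth_class,
        "true_zone": true_zone,
        "ecoregion": eco_label,
        "z_mat": z_mat, "z_map": z_map, "z_density": z_dens, "z_decade": z_dec,
        "linear_predictor": eta,
    })
    zone_effects = pd.DataFrame({
        "zone": zone_levels,
        "intercept_effect": z_int,
        "slope_effect": z_slp,
    })
    return SimulationResult(records, truth_records, zone_effects, truth, seed,
                            covariate_scaling=scaling)
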