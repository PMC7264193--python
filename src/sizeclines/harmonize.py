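"""Trait-record harmonization: derivation, filtering, binning, audit.

Multi-source small-mammal trait records (digitized museum specimens,
historical census data, live-capture surveys) arrive with heterogeneous
quality: juveniles, implausible masses, placeholder dates, ambiguous sex
strings, and gross measurement outliers.  This module implements the
cleaning pipeline that turns a raw record table into the two model-ready
datasets (body mass, head-body length), with an audit trail recording how
many records each step removed and why.

Records are pandas DataFrames with (at least) the columns::

    record_id, source, decimal_latitude, decimal_longitude,
    year, month, day, sex, life_stage, body_mass, total_length, tail_length

Derived columns added here: ``hb_length`` (mm), ``season``,
``decade_start`` and ``decade_index``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AuditLog",
    "PipelineConfig",
    "PipelineResult",
    "derive_hb_length",
    "filter_coordinates",
    "filter_dates",
    "filter_sex",
    "filter_lifestage",
    "filter_mass_floor",
    "flag_outliers",
    "assign_season",
    "assign_decade",
    "run_pipeline",
]

FIRST_YEAR = 1895
N_DECADE_BINS = 13

# Season boundaries, fixed calendar dates (astronomical equinox/solstice
# dates wander by at most a day across years; a fixed table keeps the
# binning deterministic).  Intervals are inclusive of both endpoints.
SEASON_STARTS = {
    "Spring": (3, 20),
    "Summer": (6, 21),
    "Fall": (9, 22),
    "Winter": (12, 21),
}

_DAYS_IN_MONTH = [31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]


@dataclass
class AuditLog:
    """Ordered record of filtering steps: (step, n_in, n_removed, n_out)."""

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, step: str, n_in: int, n_removed: int) -> None:
        self.steps.append((step, n_in, n_removed, n_in - n_removed))

    def removed(self, step: str) -> int:
        for name, _, n_removed, _ in self.steps:
            if name == step:
                return n_removed
        raise KeyError(step)

    def total_removed(self) -> int:
        return sum(s[2] for s in self.steps)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["step", "n_in", "n_removed", "n_out"]
        )

    def validate(self) -> None:
        """Check per-step conservation and step chaining."""
        prev_out = None
        for name, n_in, n_removed, n_out in self.steps:
            if n_out != n_in - n_removed:
                raise ValueError(f"audit step {name!r} does not conserve records")
            if prev_out is not None and n_in != prev_out:
                raise ValueError(f"audit step {name!r} does not chain")
            prev_out = n_out


def _audited(audit: AuditLog | None, step: str, df: pd.DataFrame, keep: pd.Series):
    kept = df[keep]
    if audit is not None:
        audit.add(step, len(df), int((~keep).sum()))
    return kept


# ---------------------------------------------------------------------------
# individual steps


def derive_hb_length(records: pd.DataFrame) -> pd.DataFrame:
    """Head-body length = total length − tail length, where both exist.

    A negative difference is anatomically impossible (tail longer than the
    whole animal): those derivations are nulled and flagged rather than
    propagated.
    """
    out = records.copy()
    total = pd.to_numeric(out["total_length"], errors="coerce")
    tail = pd.to_numeric(out["tail_length"], errors="coerce")
    hb = total - tail
    negative = hb.notna() & (hb < 0)
    out["hb_length"] = hb.where(~negative)
    out["flag_negative_hb"] = negative
    return out


def filter_coordinates(records: pd.DataFrame, audit: AuditLog | None = None):
    """Drop records without usable coordinates (cannot be georeferenced)."""
    lat = pd.to_numeric(records["decimal_latitude"], errors="coerce")
    lon = pd.to_numeric(records["decimal_longitude"], errors="coerce")
    keep = lat.notna() & lon.notna() & lat.between(-90, 90) & lon.between(-180, 180)
    return _audited(audit, "coordinates", records, keep)


def _valid_date(year, month, day) -> pd.Series:
    ok = year.notna() & month.notna() & day.notna()
    m = month.fillna(0).astype(int)
    d = day.fillna(0).astype(int)
    ok &= (m >= 1) & (m <= 12)
    dmax = pd.Series(np.where((m >= 1) & (m <= 12), [_DAYS_IN_MONTH[i - 1] if 1 <= i <= 12 else 0 for i in m], 0), index=month.index)
    ok &= (d >= 1) & (d <= dmax)
    # February 29 only in leap years
    y = year.fillna(0).astype(int)
    leap = (y % 4 == 0) & ((y % 100 != 0) | (y % 400 == 0))
    ok &= ~((m == 2) & (d == 29) & ~leap)
    return ok


def filter_dates(records: pd.DataFrame, audit: AuditLog | None = None, first_year: int = FIRST_YEAR):
    """Date filters: complete, possible, not 1 January, and year >= 1895.

    "1 January" dates are removed because they commonly encode year-only
    reporting, not a real collection event.
    """
    year = pd.to_numeric(records["year"], errors="coerce")
    month = pd.to_numeric(records["month"], errors="coerce")
    day = pd.to_numeric(records["day"], errors="coerce")
    keep = _valid_date(year, month, day)
    keep &= ~((month == 1) & (day == 1))
    keep &= year >= first_year
    return _audited(audit, "dates", records, keep)


def filter_sex(records: pd.DataFrame, audit: AuditLog | None = None):
    """Keep only unambiguous female/male records.

    Matching is case-insensitive; anything else (empty, "undetermined",
    trailing "?", etc.) counts as ambiguous and is removed.
    """
    sex = records["sex"].astype("string").str.strip().str.lower()
    keep = sex.isin(["female", "male"]).fillna(False)
    out = _audited(audit, "sex", records, keep)
    out = out.copy()
    out["sex"] = out["sex"].astype("string").str.strip().str.lower()
    return out


def filter_lifestage(records: pd.DataFrame, include_juveniles: bool = False,
                     audit: AuditLog | None = None):
    """Remove records explicitly labelled juvenile (unknown stays)."""
    if include_juveniles:
        keep = pd.Series(True, index=records.index)
    else:
        stage = records["life_stage"].astype("string").str.strip().str.lower()
        keep = ~(stage == "juvenile").fillna(False)
    return _audited(audit, "lifestage", records, keep)


def filter_mass_floor(records: pd.DataFrame, floor: float = 9.0,
                      audit: AuditLog | None = None):
    """Remove known-implausible adult masses, strictly below ``floor`` grams.

    Records with missing mass are untouched (they may still carry lengths).
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    mass = pd.to_numeric(records["body_mass"], errors="coerce")
    keep = mass.isna() | (mass >= floor)
    return _audited(audit, "mass_floor", records, keep)


def flag_outliers(records: pd.DataFrame, k: float = 3.0,
                  measurements: tuple[str, ...] = ("body_mass", "tail_length", "total_length"),
                  audit: AuditLog | None = None):
    """Single-pass k-SD outlier removal across all measurements.

    For each measurement the mean and (sample) SD are computed once over
    the current dataset; a record outlying in *any* measurement is removed.
    A measurement with zero SD (or < 2 values) removes nothing.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    keep = pd.Series(True, index=records.index)
    for col in measurements:
        if col not in records.columns:
            continue
        vals = pd.to_numeric(records[col], errors="coerce")
        present = vals.dropna()
        if len(present) < 2:
            continue
        mu, sd = present.mean(), present.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        keep &= vals.isna() | ((vals - mu).abs() <= k * sd)
    return _audited(audit, "outliers", records, keep)


# ---------------------------------------------------------------------------
# binning


def assign_season(month: int, day: int) -> str:
    """Season of a calendar date, fixed equinox/solstice boundaries.

    Spring [Mar 20, Jun 20], Summer [Jun 21, Sep 21],
    Fall [Sep 22, Dec 20], Winter [Dec 21, Mar 19].
    """
    month, day = int(month), int(day)
    if not (1 <= month <= 12 and 1 <= day <= _DAYS_IN_MONTH[month - 1]):
        raise ValueError(f"invalid date: month={month}, day={day}")
    md = (month, day)
    if SEASON_STARTS["Spring"] <= md < SEASON_STARTS["Summer"]:
        return "Spring"
    if SEASON_STARTS["Summer"] <= md < SEASON_STARTS["Fall"]:
        return "Summer"
    if SEASON_STARTS["Fall"] <= md < SEASON_STARTS["Winter"]:
        return "Fall"
    return "Winter"


def assign_decade(year: int) -> tuple[int, int]:
    """(bin index, bin start year) for ten-year bins anchored at 1895.

    Bin k (1-based) spans [1895+10(k−1), 1904+10(k−1)]; the record range
    1895–2019 yields 13 bins, the last covering only 2015–2019.
    """
    year = int(year)
    if year < FIRST_YEAR:
        raise ValueError(f"year {year} precedes {FIRST_YEAR}")
    idx = (year - FIRST_YEAR) // 10 + 1
    return idx, FIRST_YEAR + 10 * (idx - 1)


def add_season_decade(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["season"] = [
        assign_season(m, d) for m, d in zip(out["month"].astype(int), out["day"].astype(int))
    ]
    bins = [assign_decade(y) for y in out["year"].astype(int)]
    out["decade_index"] = [b[0] for b in bins]
    out["decade_start"] = [b[1] for b in bins]
    return out


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineConfig:
    include_juveniles: bool = False
    include_neon: bool = True
    temporal: bool = False
    floor: float = 9.0
    k: float = 3.0
    temporal_first_year: int = 1945

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineResult:
    mass: pd.DataFrame
    hb: pd.DataFrame
    audit_mass: AuditLog
    audit_hb: AuditLog


def run_pipeline(records: pd.DataFrame, config: PipelineConfig | dict | None = None) -> PipelineResult:
    """Apply the full harmonization pipeline.

    Order: coordinates → dates → sex → life stage → HB derivation →
    (per dataset) measurement presence → mass floor → outliers →
    season/decade binning → temporal year filter → source exclusion.
    The outlier statistics are computed on each dataset separately, after
    all other filters.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)

    shared = AuditLog()
    df = filter_coordinates(records, shared)
    df = filter_dates(df, shared)
    df = filter_sex(df, shared)
    df = filter_lifestage(df, config.include_juveniles, shared)
    df = derive_hb_length(df)

    def branch(measure: str) -> tuple[pd.DataFrame, AuditLog]:
        audit = AuditLog()
        audit.steps = list(shared.steps)
        vals = pd.to_numeric(df[measure], errors="coerce")
        sub = _audited(audit, f"has_{measure}", df, vals.notna())
        if measure == "body_mass":
            sub = filter_mass_floor(sub, config.floor, audit)
        sub = flag_outliers(sub, config.k, audit=audit)
        sub = add_season_decade(sub)
        if config.temporal:
            keep = sub["year"].astype(int) >= config.temporal_first_year
            sub = _audited(audit, "temporal_window", sub, keep)
        if not config.include_neon:
            keep = sub["source"].astype("string").str.upper() != "NEON"
            sub = _audited(audit, "drop_neon", sub, keep)
        return sub, audit

    mass_df, audit_mass = branch("body_mass")
    hb_df, audit_hb = branch("hb_length")
    return PipelineResult(mass_df, hb_df, audit_mass, audit_hb)
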