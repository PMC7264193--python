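"""Spatial stratification: ecoregion membership and grid-cell zonation.

Two binning schemes stratify the records.  Ecoregions (broad, named
polygons, with three of them split at 42 deg N into Northern/Southern
daughters) serve as random-intercept groups in the spatial models.  The
grid zonation selects non-overlapping 200 x 200 km squares, each densely
sampled across decades, to act as spatiotemporal replicates for the
temporal models.

Cell placement is optimized stochastically: candidate squares are drawn
uniformly over the projected bounding box for up to ``max_iter``
iterations; a candidate that meets the sampling criteria is added if it
overlaps no retained cell, and replaces the cells it overlaps when it
contains strictly more records than they do combined.  That replacement
rule makes the total number of zoned records non-decreasing over
iterations.

Coordinates are projected with an Albers equal-area conic (standard
parallels 29.5/45.5 deg, origin 23 deg N 96 deg W, spherical earth), the
conventional conterminous-US equal-area choice, so "200 km" is metrically
meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box, mapping

__all__ = [
    "albers_forward",
    "albers_inverse",
    "EcoregionMap",
    "assign_ecoregion",
    "ZoneCriteria",
    "cell_satisfies",
    "GridZonation",
    "optimize_grid_zones",
    "zonation_summary",
]

# Albers equal-area conic, spherical form (Snyder 1987, eqs. 14-1..14-11)
_R = 6_371_000.0
_PHI1, _PHI2 = np.radians(29.5), np.radians(45.5)
_PHI0, _LAM0 = np.radians(23.0), np.radians(-96.0)
_N = (np.sin(_PHI1) + np.sin(_PHI2)) / 2.0
_C = np.cos(_PHI1) ** 2 + 2.0 * _N * np.sin(_PHI1)
_RHO0 = _R * np.sqrt(_C - 2.0 * _N * np.sin(_PHI0)) / _N


def albers_forward(lon, lat):
    """Geographic degrees -> projected metres (x east, y north)."""
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    rho = _R * np.sqrt(_C - 2.0 * _N * np.sin(phi)) / _N
    theta = _N * (lam - _LAM0)
    return rho * np.sin(theta), _RHO0 - rho * np.cos(theta)


def albers_inverse(x, y):
    """Projected metres -> geographic degrees (lon, lat)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = np.hypot(x, _RHO0 - y)
    theta = np.arctan2(x, _RHO0 - y)
    phi = np.arcsin((_C - (rho * _N / _R) ** 2) / (2.0 * _N))
    lam = _LAM0 + theta / _N
    return np.degrees(lam), np.degrees(phi)


# ---------------------------------------------------------------------------
# ecoregions


@dataclass
class EcoregionMap:
    """Named polygons plus latitude split rules.

    ``splits`` lists (region name, split latitude); a point in a split
    region is labelled "Northern <name>" at or above the split latitude
    and "Southern <name>" below it.
    """

    regions: list[tuple[str, Polygon]]
    splits: list[tuple[str, float]] = field(default_factory=list)

    def label(self, lon, lat):
        """Ecoregion label per point; None where no polygon contains it.

        Points on a shared edge resolve to the lexicographically first
        region name (regions are tested in sorted-name order with
        boundary-inclusive containment).
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        pts = shapely.points(lon, lat)
        labels = np.full(lon.shape, None, dtype=object)
        split_lat = dict(self.splits)
        for name, poly in sorted(self.regions, key=lambda r: r[0]):
            todo = labels == None  # noqa: E711 — elementwise
            if not todo.any():
                break
            inside = shapely.covers(poly, pts[todo])
            idx = np.flatnonzero(todo)[inside]
            if name in split_lat:
                cut = split_lat[name]
                north = lat[idx] >= cut
                labels[idx[north]] = f"Northern {name}"
                labels[idx[~north]] = f"Southern {name}"
            else:
                labels[idx] = name
        return labels

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"name": name},
                "geometry": mapping(poly),
            }
            for name, poly in self.regions
        ]
        obj = {
            "type": "FeatureCollection",
            "features": features,
            "properties": {"splits": [[n, s] for n, s in self.splits]},
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "EcoregionMap":
        obj = json.loads(Path(path).read_text())
        regions = [
            (f["properties"]["name"], shapely.geometry.shape(f["geometry"]))
            for f in obj["features"]
        ]
        splits = [(n, float(s)) for n, s in obj.get("properties", {}).get("splits", [])]
        return cls(regions, splits)


def assign_ecoregion(records: pd.DataFrame, eco_map: EcoregionMap,
                     audit=None) -> pd.DataFrame:
    """Add an ``ecoregion`` column; drop (and audit) points in no polygon."""
    labels = eco_map.label(
        records["decimal_longitude"].to_numpy(float),
        records["decimal_latitude"].to_numpy(float),
    )
    out = records.copy()
    out["ecoregion"] = labels
    keep = pd.Series(labels != None, index=out.index)  # noqa: E711
    if audit is not None:
        audit.add("ecoregion", len(out), int((~keep).sum()))
    return out[keep]


# ---------------------------------------------------------------------------
# grid zonation


@dataclass(frozen=True)
class ZoneCriteria:
    """Retention criteria for a candidate cell: at least ``min_total``
    records, with at least ``min_decades`` decade bins each holding at
    least ``min_per_decade`` records."""

    min_total: int = 75
    min_decades: int = 4
    min_per_decade: int = 10


def cell_satisfies(decades, criteria: ZoneCriteria = ZoneCriteria()) -> bool:
    """Whether a cell's member records meet the sampling criteria.

    ``decades`` is the decade bin of each member record (any hashable
    labels).  A decade "counts" when it holds >= min_per_decade records.
    """
    decades = pd.Series(list(decades))
    if len(decades) < criteria.min_total:
        return False
    counts = decades.value_counts()
    return int((counts >= criteria.min_per_decade).sum()) >= criteria.min_decades


@dataclass
class GridZonation:
    """Final set of retained non-overlapping square cells.

    Corners are lower-left, in projected metres; ``members`` maps cell id
    to the positional indices (into the optimizer's input) of its records.
    """

    cell_size_m: float
    corners: np.ndarray  # (n_cells, 2)
    totals: np.ndarray  # (n_cells,)
    members: list[np.ndarray]
    decade_counts: list[dict]
    iterations: int
    seed: int
    history: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return len(self.corners)

    def total_zoned(self) -> int:
        return int(self.totals.sum())

    def label_records(self, n_records: int) -> np.ndarray:
        """Zone id per record position (-1 = unzoned)."""
        labels = np.full(n_records, -1, dtype=int)
        for cid, idx in enumerate(self.members):
            labels[idx] = cid
        return labels

    def to_geojson(self, path: str | Path) -> None:
        L = self.cell_size_m
        features = []
        for cid, ((x0, y0), total) in enumerate(zip(self.corners, self.totals)):
            xs = [x0, x0 + L, x0 + L, x0, x0]
            ys = [y0, y0, y0 + L, y0 + L, y0]
            lon, lat = albers_inverse(np.array(xs), np.array(ys))
            features.append({
                "type": "Feature",
                "properties": {
                    "cell_id": cid,
                    "total": int(total),
                    "x0_m": float(x0),
                    "y0_m": float(y0),
                    "decade_counts": {str(k): int(v) for k, v in self.decade_counts[cid].items()},
                },
                "geometry": {"type": "Polygon",
                             "coordinates": [list(zip(lon.tolist(), lat.tolist()))]},
            })
        obj = {"type": "FeatureCollection", "features": features,
               "properties": {"cell_size_m": self.cell_size_m,
                              "iterations": self.iterations, "seed": self.seed}}
        Path(path).write_text(json.dumps(obj))


def optimize_grid_zones(records: pd.DataFrame, cell_km: float = 200.0,
                        criteria: ZoneCriteria = ZoneCriteria(),
                        max_iter: int = 200_000, seed: int = 0,
                        replacement: str = "combined",
                        record_history: bool = False) -> GridZonation:
    """Stochastic placement of non-overlapping, well-sampled square cells.

    Each iteration draws a candidate lower-left corner uniformly over the
    projected bounding box (expanded by one cell width so edge clusters
    are coverable), keeps the candidate only if its member records meet
    ``criteria``, and then either adds it (no overlap) or applies the
    replacement rule.  ``replacement='combined'`` (default) replaces the
    overlapped cells iff the candidate holds strictly more records than
    their combined total, which guarantees monotone growth of the zoned
    record count; ``'per_cell'`` compares against each overlapped cell
    individually.

    Requires columns ``decimal_longitude``/``decimal_latitude`` (or
    precomputed ``x_albers``/``y_albers``) and ``decade_start``.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if replacement not in ("combined", "per_cell"):
        raise ValueError("replacement must be 'combined' or 'per_cell'")
    if len(records) == 0:
        raise ValueError("no records to zone")

    if "x_albers" in records.columns:
        px = records["x_albers"].to_numpy(float)
        py = records["y_albers"].to_numpy(float)
    else:
        px, py = albers_forward(
            records["decimal_longitude"].to_numpy(float),
            records["decimal_latitude"].to_numpy(float),
        )
    if not np.isfinite(px).any():
        raise ValueError("no record has usable projected coordinates")
    dec_codes, dec_labels = pd.factorize(records["decade_start"])
    n_dec = len(dec_labels)
    L = cell_km * 1000.0

    # sort by x so candidate membership is a binary-search slice + y mask
    order = np.argsort(px, kind="stable")
    xs, ys_s, dec_s = px[order], py[order], dec_codes[order]

    xmin, xmax = xs[0], xs[-1]
    ymin, ymax = ys_s.min(), ys_s.max()

    # coarse count grid (summed-area table) for O(1) upper-bound rejection
    bs = L / 4.0
    nbx = int(np.ceil((xmax - xmin) / bs)) + 1
    nby = int(np.ceil((ymax - ymin) / bs)) + 1
    bx = np.clip(((xs - xmin) / bs).astype(int), 0, nbx - 1)
    by = np.clip(((ys_s - ymin) / bs).astype(int), 0, nby - 1)
    hist = np.zeros((nbx + 1, nby + 1), dtype=np.int64)
    np.add.at(hist, (bx + 1, by + 1), 1)
    sat = hist.cumsum(axis=0).cumsum(axis=1)

    def upper_bound(x0, y0):
        i0 = max(int((x0 - xmin) // bs), 0)
        j0 = max(int((y0 - ymin) // bs), 0)
        i1 = min(int((x0 + L - xmin) // bs) + 1, nbx)
        j1 = min(int((y0 + L - ymin) // bs) + 1, nby)
        if i1 <= i0 or j1 <= j0:
            return 0
        return sat[i1, j1] - sat[i0, j1] - sat[i1, j0] + sat[i0, j0]

    rng = np.random.default_rng(seed)
    ret_x: list[float] = []
    ret_y: list[float] = []
    ret_total: list[int] = []
    ret_members: list[np.ndarray] = []
    ret_deccounts: list[np.ndarray] = []
    history = np.empty(max_iter, dtype=np.int64) if record_history else None
    current_total = 0

    lo_x, hi_x = xmin - L, xmax
    lo_y, hi_y = ymin - L, ymax

    for it in range(max_iter):
        x0 = rng.uniform(lo_x, hi_x)
        y0 = rng.uniform(lo_y, hi_y)
        accepted = False
        if upper_bound(x0, y0) >= criteria.min_total:
            lo = np.searchsorted(xs, x0, side="left")
            hi = np.searchsorted(xs, x0 + L, side="left")
            if hi - lo >= criteria.min_total:
                yy = ys_s[lo:hi]
                mask = (yy >= y0) & (yy < y0 + L)
                total = int(mask.sum())
                if total >= criteria.min_total:
                    dcounts = np.bincount(dec_s[lo:hi][mask], minlength=n_dec)
                    if int((dcounts >= criteria.min_per_decade).sum()) >= criteria.min_decades:
                        members = np.arange(lo, hi)[mask]
                        accepted = _try_place(
                            x0, y0, total, members, dcounts, L, replacement,
                            ret_x, ret_y, ret_total, ret_members, ret_deccounts,
                        )
        if accepted:
            current_total = int(sum(ret_total))
        if history is not None:
            history[it] = current_total

    # map sorted-order member indices back to input positions
    members_out = [order[m] for m in ret_members]
    dec_out = [
        {int(dec_labels[i]): int(c) for i, c in enumerate(dc) if c > 0}
        for dc in ret_deccounts
    ]
    return GridZonation(
        cell_size_m=L,
        corners=np.column_stack([ret_x, ret_y]) if ret_x else np.empty((0, 2)),
        totals=np.asarray(ret_total, dtype=int),
        members=members_out,
        decade_counts=dec_out,
        iterations=max_iter,
        seed=seed,
        history=history,
    )


def _try_place(x0, y0, total, members, dcounts, L, replacement,
               ret_x, ret_y, ret_total, ret_members, ret_deccounts) -> bool:
    """Add/replace logic; returns True when the retained set changed."""
    if ret_x:
        rx = np.asarray(ret_x)
        ry = np.asarray(ret_y)
        # positive-area intersection only: edge-touching does not conflict
        over = np.flatnonzero((np.abs(rx - x0) < L) & (np.abs(ry - y0) < L))
    else:
        over = np.empty(0, dtype=int)
    if over.size:
        existing = [ret_total[i] for i in over]
        if replacement == "combined":
            ok = total > sum(existing)
        else:
            ok = all(total > t for t in existing)
        if not ok:
            return False
        for i in sorted(over, reverse=True):
            del ret_x[i], ret_y[i], ret_total[i], ret_members[i], ret_deccounts[i]
    ret_x.append(x0)
    ret_y.append(y0)
    ret_total.append(total)
    ret_members.append(members)
    ret_deccounts.append(dcounts)
    return True


def zonation_summary(z: GridZonation, n_records: int | None = None) -> pd.DataFrame:
    """Per-cell totals and decade counts; attrs carry overall coverage."""
    rows = []
    for cid in range(z.n_cells):
        row = {"cell_id": cid, "total": int(z.totals[cid]),
               "n_decades": len(z.decade_counts[cid])}
        for d, c in z.decade_counts[cid].items():
            row[f"decade_{d}"] = c
        rows.append(row)
    out = pd.DataFrame(rows)
    if n_records:
        out.attrs["coverage"] = z.total_zoned() / n_records
    return out


def make_band_ecoregions(bounds: tuple[float, float, float, float],
                         names: list[str] | None = None,
                         splits: list[tuple[str, float]] | None = None) -> EcoregionMap:
    """Simple longitudinal-band ecoregion map over a lat/lon box.

    Stand-in geometry for a Level-I ecoregion map: vertical bands spanning
    the full latitude range, optionally with 42 deg N split rules.
    """
    west, south, east, north = bounds
    if names is None:
        names = ["Pacific Coast", "Cordilleras", "Deserts", "Great Plains",
                 "Eastern Forests"]
    if splits is None:
        splits = [("Cordilleras", 42.0), ("Deserts", 42.0), ("Great Plains", 42.0)]
    n = len(names)
    edges = np.linspace(west, east, n + 1)
    regions = [
        (name, box(edges[i], south, edges[i + 1], north))
        for i, name in enumerate(names)
    ]
    return EcoregionMap(regions, splits)
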