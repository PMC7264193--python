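"""Independent oracles used by the tests.

Deliberately naive implementations (lookup tables, closed-form normal
equations, brute-force likelihood maximization, exhaustive interval
scheduling) kept free of any code path they are used to check.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
from scipy.optimize import minimize

# --- calendar binning -------------------------------------------------------

# (start month-day, end month-day, season); winter wraps the year end
_SEASON_TABLE = [
    ((3, 20), (6, 20), "Spring"),
    ((6, 21), (9, 21), "Summer"),
    ((9, 22), (12, 20), "Fall"),
]


def season_oracle(month: int, day: int) -> str:
    md = (month, day)
    for start, end, name in _SEASON_TABLE:
        if start <= md <= end:
            return name
    return "Winter"


# explicit 13-bin table for 1895-2019
DECADE_TABLE = [(k, 1895 + 10 * (k - 1), 1904 + 10 * (k - 1)) for k in range(1, 14)]


def decade_oracle(year: int) -> tuple[int, int]:
    for k, start, end in DECADE_TABLE:
        if start <= year <= end:
            return k, start
    raise ValueError(year)


def all_calendar_days():
    """Every (month, day) of a leap year: 366 days."""
    d = dt.date(2000, 1, 1)
    while d.year == 2000:
        yield d.month, d.day
        d += dt.timedelta(days=1)


# --- ordinary least squares -------------------------------------------------


def ols_line(x, y):
    """Slope/intercept by explicit normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    return slope, y.mean() - slope * x.mean()


# --- brute-force ML for the crossed two-factor mixed model ------------------


def crossed_lmm_ml_oracle(y, factor_a, factor_b):
    """Maximize the exact Gaussian marginal likelihood of
    y = mu + a_i + b_j + e over (var_a, var_b, var_e), profiling mu by GLS.

    Returns (llf, var_a, var_b, var_e).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    za = _dummies(factor_a)
    zb = _dummies(factor_b)
    X = np.ones((n, 1))

    def negll(logp):
        va, vb, ve = np.exp(logp)
        V = va * za @ za.T + vb * zb @ zb.T + ve * np.eye(n)
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            return 1e10
        Viy = np.linalg.solve(V, y)
        ViX = np.linalg.solve(V, X)
        beta = np.linalg.solve(X.T @ ViX, X.T @ Viy)
        r = y - X @ beta
        return 0.5 * (logdet + r @ np.linalg.solve(V, r) + n * np.log(2 * np.pi))

    best = None
    for a0 in (-4, -1, 1):
        for b0 in (-4, -1, 1):
            for e0 in (-2, 0):
                res = minimize(negll, [a0, b0, e0], method="Nelder-Mead",
                               options={"xatol": 1e-12, "fatol": 1e-14,
                                        "maxiter": 10000})
                if best is None or res.fun < best.fun:
                    best = res
    va, vb, ve = np.exp(best.x)
    return -best.fun, va, vb, ve


def _dummies(labels):
    labels = list(labels)
    levels = sorted(set(labels))
    out = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(labels):
        out[i, levels.index(lab)] = 1.0
    return out


# --- brute-force 1-D zonation ----------------------------------------------


def best_line_zonation(x, decades, cell_m, min_total, min_decades,
                       min_per_decade, step_m=5000.0):
    """Exact optimum of total zoned records for points on a line.

    Enumerates candidate cells on a fine corner lattice, keeps those
    meeting the criteria, and solves max-weight non-overlapping selection
    by weighted interval scheduling (DP).  Valid oracle when all points
    share one y-band narrower than the cell.
    """
    x = np.asarray(x, dtype=float)
    decades = np.asarray(decades)
    corners = np.arange(x.min() - cell_m, x.max() + step_m, step_m)
    cands = []
    for x0 in corners:
        sel = (x >= x0) & (x < x0 + cell_m)
        total = int(sel.sum())
        if total < min_total:
            continue
        _, counts = np.unique(decades[sel], return_counts=True)
        if (counts >= min_per_decade).sum() < min_decades:
            continue
        cands.append((x0, x0 + cell_m, total))
    cands.sort(key=lambda c: c[1])
    ends = [c[1] for c in cands]
    best = [0] * (len(cands) + 1)
    import bisect

    for i, (s, e, w) in enumerate(cands, start=1):
        j = bisect.bisect_right(ends, s, hi=i - 1)  # strict overlap only
        best[i] = max(best[i - 1], best[j] + w)
    return best[-1]
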