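"""Model suite: allometry, mixed-model candidates, AICc, diagnostics.

The spatial suite models body size (mass in g, or head-body length in mm)
with fixed effects drawn from {MAT, MAP, sex, season, population density}
and crossed random intercepts for ecoregion and data source.  The
temporal suite adds a decade fixed effect and replaces the random part
with a correlated random (intercept, decade-slope) pair per spatial
zone, the structure that exposes whether large- and small-bodied
populations trend differently over time.

All candidate fits use maximum likelihood (not REML) so their AICc values
are comparable across fixed-effect structures; the top model can be
refit by REML for reporting.  Variance-explained summaries follow the
Nakagawa decomposition into marginal (fixed-effects-only) and
conditional (fixed plus random) R^2.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AllometryFit",
    "ModelSpec",
    "FitResult",
    "SelectionTable",
    "fit_allometry",
    "enumerate_candidates",
    "fit_lmm",
    "aicc",
    "rank_models",
    "nakagawa_r2",
    "random_effect_diagnostics",
    "fit_per_zone_trends",
]

# canonical fixed-effect term names -> formula fragments
FIXED_TERMS = {
    "MAT": "MAT_std",
    "MAP": "MAP_std",
    "log_density": "log_density_std",
    "decade": "decade_std",
    "sex": "C(sex, Treatment(reference='female'))",
    "season": "C(season, Treatment(reference='Fall'))",
}
SPATIAL_GLOBAL = ("MAT", "MAP", "sex", "season", "log_density")
TEMPORAL_GLOBAL = SPATIAL_GLOBAL + ("decade",)


# ---------------------------------------------------------------------------
# allometry


@dataclass
class AllometryFit:
    slope: float
    intercept: float
    r2_adj: float
    n: int


def fit_allometry(records: pd.DataFrame, length_col: str = "hb_length",
                  mass_col: str = "body_mass") -> AllometryFit:
    """OLS of log(mass) on log(head-body length).

    A weak fit licenses analysing the two size proxies separately; a
    near-perfect cube-law fit would signal collinearity.  Adjusted
    R^2 = 1 − (1 − R^2)(n − 1)/(n − 2).
    """
    df = records[[length_col, mass_col]].apply(pd.to_numeric, errors="coerce").dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete (length, mass) records")
    if (df <= 0).any().any():
        raise ValueError("traits must be positive for log transformation")
    x = np.log(df[length_col].to_numpy(float))
    y = np.log(df[mass_col].to_numpy(float))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    n = len(df)
    r2_adj = 1.0 - (1.0 - res.rsquared) * (n - 1) / (n - 2)
    return AllometryFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                        r2_adj=float(r2_adj), n=n)


# ---------------------------------------------------------------------------
# model specification and fitting


@dataclass(frozen=True)
class ModelSpec:
    """One candidate: response, fixed-term subset, random structure."""

    response: str
    fixed: tuple[str, ...]
    random: str  # "spatial" (ecoregion+source intercepts) or "temporal"

    def __post_init__(self) -> None:
        if self.random not in ("spatial", "temporal"):
            raise ValueError("random structure must be 'spatial' or 'temporal'")
        unknown = set(self.fixed) - set(FIXED_TERMS)
        if unknown:
            raise ValueError(f"unknown fixed terms: {sorted(unknown)}")
        if self.random == "spatial" and "decade" in self.fixed:
            raise ValueError("spatial models never include decade")

    @property
    def name(self) -> str:
        fx = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.response} ~ {fx} [{self.random}]"

    @property
    def formula(self) -> str:
        rhs = " + ".join(FIXED_TERMS[t] for t in self.fixed) or "1"
        return f"{self.response} ~ {rhs}"


def enumerate_candidates(response: str, mode: str,
                         global_fixed: tuple[str, ...] | None = None,
                         explicit: list[tuple[str, ...]] | None = None) -> list[ModelSpec]:
    """Candidate set: all subsets of the global fixed-effect set.

    The published candidate suites (29 spatial, 44 temporal) are not
    itemized anywhere, so the default is the full subset lattice of the
    global model (including the intercept-only model); ``explicit``
    overrides it with a hand-picked list of fixed-term tuples.
    """
    if mode not in ("spatial", "temporal"):
        raise ValueError("mode must be 'spatial' or 'temporal'")
    if explicit is not None:
        return [ModelSpec(response, tuple(fx), mode) for fx in explicit]
    if global_fixed is None:
        global_fixed = SPATIAL_GLOBAL if mode == "spatial" else TEMPORAL_GLOBAL
    specs = []
    for r in range(len(global_fixed) + 1):
        for subset in itertools.combinations(global_fixed, r):
            specs.append(ModelSpec(response, subset, mode))
    return specs


@dataclass
class FitResult:
    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series  # Wald z on fixed effects
    n_fixed: int
    vcomp: dict[str, float]  # variance per named random term
    cov_re: np.ndarray | None  # 2x2 (intercept, slope) covariance, temporal
    sigma2_resid: float
    llf: float
    k: int
    n: int
    aic: float
    aicc: float
    converged: bool
    random_effects: dict  # group -> conditional modes (BLUPs)
    fixed_predictor_var: float

    @property
    def slope_intercept_corr(self) -> float | None:
        if self.cov_re is None:
            return None
        v0, v1 = self.cov_re[0, 0], self.cov_re[1, 1]
        if v0 <= 0 or v1 <= 0:
            return float("nan")
        return float(self.cov_re[0, 1] / math.sqrt(v0 * v1))


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: AIC + 2k(k+1)/(n−k−1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    aic = -2.0 * loglik + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_lmm(dataset: pd.DataFrame, spec: ModelSpec,
            reml: bool = False) -> FitResult:
    """Fit one candidate Gaussian linear mixed model.

    Spatial specs use crossed random intercepts (ecoregion, source) via
    the single-group variance-components formulation; temporal specs use
    a correlated random intercept + decade slope per zone.  Estimation is
    ML by default so log-likelihoods are comparable across fixed
    structures; ML and REML likelihoods are never mixed because the
    estimator choice is fixed per call, not per candidate.

    Non-convergence triggers one retry from a perturbed start; a fit that
    still fails is returned with ``converged=False`` (and excluded, with
    a log entry, by :func:`rank_models`).
    """
    data = dataset.copy()
    data[spec.response] = pd.to_numeric(data[spec.response], errors="coerce")
    data = data[data[spec.response].notna()]
    if spec.random == "spatial":
        for col in ("ecoregion", "source"):
            if data[col].nunique() < 2:
                raise ValueError(f"grouping factor {col!r} needs >= 2 levels")
        data["_all"] = 1
        model = smf.mixedlm(
            spec.formula, data, groups="_all",
            vc_formula={"ecoregion": "0 + C(ecoregion)", "source": "0 + C(source)"},
        )
        n_var_par = 2
    else:
        if data["zone"].nunique() < 2:
            raise ValueError("grouping factor 'zone' needs >= 2 levels")
        model = smf.mixedlm(spec.formula, data, groups="zone",
                            re_formula="1 + decade_std")
        n_var_par = 3  # var(int), var(slope), cov

    # gradient methods can stall on variance boundaries (a component at 0);
    # powell is slower but reliable there, so it is the fallback
    result = None
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for kwargs in ({"reml": reml}, {"reml": reml, "method": "powell"}):
            try:
                attempt_res = model.fit(**kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if result is None or attempt_res.llf > result.llf:
                result = attempt_res
                converged = bool(attempt_res.converged)
            if converged:
                break

    if result is None:
        raise RuntimeError(f"mixed model failed outright: {spec.name}")

    fe_names = list(result.model.exog_names)
    p = len(fe_names)
    n = int(result.model.nobs)
    k = p + n_var_par + 1  # fixed + variance/covariance params + residual
    llf = float(result.llf)

    if spec.random == "spatial":
        vc = {name: float(v) for name, v in
              zip(result.model.exog_vc.names, np.atleast_1d(result.vcomp))}
        cov_re = None
    else:
        cov_re = np.asarray(result.cov_re)
        vc = {"zone_intercept": float(cov_re[0, 0]),
              "zone_slope": float(cov_re[1, 1]),
              "zone_cov": float(cov_re[0, 1])}

    eta = result.model.exog @ result.fe_params
    re_modes = {g: np.asarray(v, dtype=float) for g, v in result.random_effects.items()}

    return FitResult(
        spec=spec,
        params=result.fe_params,
        bse=result.bse_fe,
        pvalues=result.pvalues[:p],
        n_fixed=p,
        vcomp=vc,
        cov_re=cov_re,
        sigma2_resid=float(result.scale),
        llf=llf,
        k=k,
        n=n,
        aic=-2.0 * llf + 2.0 * k,
        aicc=aicc(llf, k, n),
        converged=converged,
        random_effects=re_modes,
        fixed_predictor_var=float(np.var(eta)),
    )


# ---------------------------------------------------------------------------
# selection and variance decomposition


@dataclass
class SelectionTable:
    """AICc-ranked candidates with Akaike weights."""

    table: pd.DataFrame  # columns: name, k, n, aicc, delta_aicc, weight
    fits: list[FitResult]
    excluded: list[str] = field(default_factory=list)

    @property
    def best(self) -> FitResult:
        return self.fits[0]


def rank_models(fits: list[FitResult]) -> SelectionTable:
    """Rank converged fits by AICc; ties break on spec name.

    Akaike weight w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2).
    """
    ok = [f for f in fits if f.converged]
    excluded = [f.spec.name for f in fits if not f.converged]
    if not ok:
        raise ValueError("no converged fits to rank")
    ok.sort(key=lambda f: (f.aicc, f.spec.name))
    a = np.array([f.aicc for f in ok])
    delta = a - a[0]
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    table = pd.DataFrame({
        "name": [f.spec.name for f in ok],
        "k": [f.k for f in ok],
        "n": [f.n for f in ok],
        "aicc": a,
        "delta_aicc": delta,
        "weight": w,
    })
    return SelectionTable(table=table, fits=ok, excluded=excluded)


def _mean_random_variance(fit: FitResult, dataset: pd.DataFrame | None) -> float:
    """Average model-implied random-effect variance per observation."""
    if fit.cov_re is None:
        return float(sum(fit.vcomp.values()))
    v0, c01, v1 = fit.cov_re[0, 0], fit.cov_re[0, 1], fit.cov_re[1, 1]
    if dataset is not None and "decade_std" in dataset:
        zv = dataset["decade_std"].to_numpy(float)
        return float(v0 + 2.0 * c01 * zv.mean() + v1 * np.mean(zv**2))
    return float(v0 + v1)


def nakagawa_r2(fit: FitResult, dataset: pd.DataFrame | None = None) -> tuple[float, float]:
    """Marginal and conditional R^2 for a Gaussian mixed fit.

    marginal = var(fixed predictor) / (var_f + var_random + var_resid);
    conditional adds the random-effect variance to the numerator.  For
    random-slope structures the random variance is averaged over the
    observed slope covariate (pass ``dataset``).
    """
    var_f = fit.fixed_predictor_var
    var_r = _mean_random_variance(fit, dataset)
    denom = var_f + var_r + fit.sigma2_resid
    if denom <= 0:
        raise ValueError("zero total variance")
    return var_f / denom, (var_f + var_r) / denom


def random_effect_diagnostics(fit: FitResult) -> dict:
    """Zone intercept/slope coupling from a temporal fit.

    Returns the model-implied correlation (from the estimated random-
    effect covariance), the empirical Pearson correlation of the per-zone
    conditional modes (BLUPs), and the per-zone table behind the
    intercept-vs-slope scatter.  With fewer than 3 zones the empirical
    correlation is degenerate (+-1 by construction) and flagged.
    """
    if fit.cov_re is None:
        raise ValueError("fit has no random slope: diagnostics need the "
                         "correlated (intercept, slope) structure")
    zones = sorted(fit.random_effects)
    modes = np.array([fit.random_effects[z] for z in zones])
    table = pd.DataFrame({"zone": zones,
                          "intercept_mode": modes[:, 0],
                          "slope_mode": modes[:, 1]})
    if len(zones) >= 3 and modes[:, 0].std() > 0 and modes[:, 1].std() > 0:
        empirical = float(np.corrcoef(modes[:, 0], modes[:, 1])[0, 1])
        reliable = True
    else:
        empirical = float("nan") if len(zones) < 2 else \
            float(np.sign(np.prod(np.diff(modes, axis=0))))
        reliable = False
    return {
        "model_corr": fit.slope_intercept_corr,
        "empirical_corr": empirical,
        "reliable": reliable,
        "table": table,
    }


def fit_per_zone_trends(dataset: pd.DataFrame, response: str,
                        zone_col: str = "zone",
                        decade_col: str = "decade_index") -> pd.DataFrame:
    """Independent OLS slope of size on decade for each zone.

    Exploratory counterpart to the random-slope model: one unpooled
    regression per zone, joined with the zone's mean size for the
    size-vs-trend scatter.  Zones with fewer than 2 distinct decades are
    skipped.
    """
    rows = []
    for zone, grp in dataset.groupby(zone_col):
        x = pd.to_numeric(grp[decade_col], errors="coerce")
        y = pd.to_numeric(grp[response], errors="coerce")
        ok = x.notna() & y.notna()
        x, y = x[ok], y[ok]
        if x.nunique() < 2:
            continue
        slope, intercept = np.polyfit(x.to_numpy(float), y.to_numpy(float), 1)
        rows.append({"zone": zone, "slope": float(slope),
                     "mean_size": float(y.mean()), "n": int(len(y))})
    return pd.DataFrame(rows, columns=["zone", "slope", "mean_size", "n"])
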