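"""Improved residual-trend (RESTREND) attribution of NDVI dynamics.

The residual-trend method assumes NDVI responds linearly to climate; what
the regression cannot explain is attributed to human activity.  Per pixel:

1.  Select the dominant climate variables once for the whole scene by
    combining a random-forest importance ranking with bidirectional stepwise
    regression (variables retained by stepwise, ordered by forest
    importance).
2.  Fit ``NDVI_C = a*T + b*P + c*S + d`` by OLS pixel by pixel; the
    prediction NDVI_C is the climate-driven component.
3.  Residual ``NDVI_H = NDVI_obs - NDVI_C`` is the human-driven component;
    the same subtraction on the windowed CV gives ``CV_H``.
4.  Compare the signs of the observed, climate and human trends to classify
    the driver (climate / human / both) and compute contribution rates; the
    (NDVI driver, CV driver) pair then indexes one of twelve scenarios.

Trend slopes inside the attribution are ordinary least-squares slopes, which
are exactly additive under the decomposition (so climate% + human% = 100 at
every pixel); Sen/M-K remains the trend-mapping method elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .grid import GridStack
from .trends import window_stack

__all__ = [
    "select_climate_variables",
    "SelectionReport",
    "fit_pixel_regressions",
    "PixelRegressions",
    "decompose",
    "ResidualStacks",
    "ols_slope_map",
    "classify_driver",
    "driver_code",
    "classify_scenario",
    "SCENARIO_LABELS",
    "attribute",
    "DriverMap",
    "ScenarioMap",
]


# ---------------------------------------------------------------------------
# Variable selection: random forest + stepwise
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Audit trail of the climate-variable selection."""

    selected: list[str]
    rf_importance: pd.Series           # permutation importance, descending
    stepwise_path: list[tuple[str, str, float]]  # (action, variable, p)
    stepwise_retained: list[str]
    regional_r2: dict[str, float] = field(default_factory=dict)


def _stepwise_ols(y: np.ndarray, X: pd.DataFrame, p_enter: float = 0.05,
                  p_remove: float = 0.10) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Bidirectional p-value stepwise selection on an OLS model."""
    included: list[str] = []
    path: list[tuple[str, str, float]] = []
    while True:
        changed = False
        # forward step: best candidate by entry p-value
        excluded = [c for c in X.columns if c not in included]
        if excluded:
            pvals = {}
            for cand in excluded:
                design = sm.add_constant(X[included + [cand]])
                fit = sm.OLS(y, design).fit()
                pvals[cand] = fit.pvalues[cand]
            best = min(pvals, key=pvals.get)
            if pvals[best] <= p_enter:
                included.append(best)
                path.append(("add", best, float(pvals[best])))
                changed = True
        # backward step: drop the worst included variable
        if included:
            design = sm.add_constant(X[included])
            fit = sm.OLS(y, design).fit()
            worst = fit.pvalues[included].idxmax()
            if fit.pvalues[worst] >= p_remove:
                included.remove(worst)
                path.append(("drop", worst, float(fit.pvalues[worst])))
                changed = True
        if not changed:
            return included, path


def select_climate_variables(
    ndvi: GridStack,
    climate: dict[str, GridStack],
    seed: int = 0,
    n_trees: int = 500,
    max_rows: int = 100_000,
    n_repeats: int = 5,
    min_samples_leaf: int = 15,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> SelectionReport:
    """Choose the dominant climate variables for the scene-wide regression.

    Random forest: fitted on a seeded subsample of valid pixel-years (NDVI
    as response, all candidates as predictors), ranked by permutation
    importance.  Stepwise: bidirectional OLS on the spatially averaged
    regional series.  The returned set is the stepwise-retained variables
    ordered by forest importance.  Constant candidates are excluded with a
    warning.  Deterministic given the seed.
    """
    names = []
    for name, stack in climate.items():
        ndvi.require_same_grid(stack)
        vals = stack.values[~np.isnan(stack.values)]
        if vals.size and np.ptp(vals) == 0:
            warnings.warn(f"climate variable {name!r} is constant; excluded")
            continue
        names.append(name)
    if len(names) < 1:
        raise ValueError("no usable climate candidates")

    rng = np.random.default_rng(seed)

    # -- random-forest importance on pixel-year anomalies -----------------
    # within-pixel temporal anomalies: subtracting each pixel's mean keeps
    # the temporal climate response and removes spatial level differences,
    # which would otherwise let any spatially structured variable act as a
    # location proxy and inflate its importance
    def _anom(stack: GridStack) -> np.ndarray:
        return (stack.values - np.nanmean(stack.values, axis=0, keepdims=True)).ravel()

    y_all = _anom(ndvi)
    X_all = np.column_stack([_anom(climate[n]) for n in names])
    ok = ~np.isnan(y_all) & ~np.isnan(X_all).any(axis=1)
    y_all, X_all = y_all[ok], X_all[ok]
    if len(y_all) > max_rows:
        pick = rng.choice(len(y_all), size=max_rows, replace=False)
        y_all, X_all = y_all[pick], X_all[pick]
    # held-out permutation importance: training-set importance lets deep
    # trees credit memorized noise features, so importance is scored on a
    # split the forest never saw
    order = rng.permutation(len(y_all))
    half = len(y_all) // 2
    tr, te = order[:half], order[half:]
    rf = RandomForestRegressor(
        n_estimators=n_trees, random_state=int(rng.integers(2**31)), n_jobs=1,
        min_samples_leaf=min_samples_leaf,
    )
    rf.fit(X_all[tr], y_all[tr])
    perm = permutation_importance(
        rf, X_all[te], y_all[te], n_repeats=n_repeats,
        random_state=int(rng.integers(2**31)), n_jobs=1,
    )
    importance = pd.Series(perm.importances_mean, index=names).sort_values(ascending=False)

    # -- stepwise on the regional (spatial-mean) series -------------------
    y_reg = np.nanmean(ndvi.values.reshape(ndvi.n_years, -1), axis=1)
    X_reg = pd.DataFrame(
        {n: np.nanmean(climate[n].values.reshape(ndvi.n_years, -1), axis=1) for n in names}
    )
    retained, path = _stepwise_ols(y_reg, X_reg, p_enter, p_remove)

    # a variable must be supported by both methods: retained by stepwise AND
    # carrying held-out forest importance above a loose floor (1% of the top
    # importance — only meant to reject pure-noise features); ordered by
    # importance
    floor = 0.01 * max(float(importance.max()), 0.0)
    selected = [
        n for n in importance.index if n in retained and importance[n] > floor
    ]

    # regional-fit audit: R^2 with the selected set and with 2-var subsets
    r2: dict[str, float] = {}
    def fit_r2(cols: list[str]) -> float:
        if not cols:
            return 0.0
        return float(sm.OLS(y_reg, sm.add_constant(X_reg[cols])).fit().rsquared)
    r2["selected"] = fit_r2(selected)
    if len(selected) > 2:
        r2["first_two"] = fit_r2(selected[:2])
    return SelectionReport(selected=selected, rf_importance=importance,
                           stepwise_path=path, stepwise_retained=retained,
                           regional_r2=r2)


# ---------------------------------------------------------------------------
# Pixel-wise OLS and residual decomposition
# ---------------------------------------------------------------------------

@dataclass
class PixelRegressions:
    """Per-pixel OLS of NDVI on the selected climate variables."""

    variables: list[str]
    coefficients: np.ndarray   # (n_vars, rows, cols)
    intercept: np.ndarray      # (rows, cols)
    std_errors: np.ndarray     # (n_vars + 1, rows, cols), intercept last
    r_squared: np.ndarray
    predicted: GridStack       # NDVI_C


def fit_pixel_regressions(
    ndvi: GridStack, climate: dict[str, GridStack], variables: list[str]
) -> PixelRegressions:
    """OLS fit of NDVI on the selected climate variables at every pixel.

    Pixels with any nodata year or a rank-deficient design become nodata
    (with a warning if rank-deficient).  Batched normal-equation solve.
    """
    for v in variables:
        ndvi.require_same_grid(climate[v])
    ny = ndvi.n_years
    nr, nc = ndvi.shape
    p = len(variables)
    if ny < p + 2:
        raise ValueError(f"need at least {p + 2} years for {p} predictors, have {ny}")

    npx = nr * nc
    X = np.empty((npx, ny, p + 1))
    for k, v in enumerate(variables):
        X[:, :, k] = climate[v].values.reshape(ny, -1).T
    X[:, :, p] = 1.0
    Y = ndvi.values.reshape(ny, -1).T            # (npx, ny)

    valid = ~np.isnan(Y).any(axis=1) & ~np.isnan(X).any(axis=(1, 2))
    beta = np.full((npx, p + 1), np.nan)
    se = np.full((npx, p + 1), np.nan)
    r2 = np.full(npx, np.nan)
    pred = np.full((npx, ny), np.nan)

    idx = np.flatnonzero(valid)
    if idx.size:
        Xv, Yv = X[idx], Y[idx]
        G = np.einsum("pij,pik->pjk", Xv, Xv)            # X'X
        bad = np.abs(np.linalg.det(G)) < 1e-12
        if bad.any():
            warnings.warn(f"{int(bad.sum())} pixels have rank-deficient designs; set nodata")
        good = ~bad
        if good.any():
            Gg = G[good]
            rhs = np.einsum("pij,pi->pj", Xv[good], Yv[good])
            b = np.linalg.solve(Gg, rhs[:, :, None])[:, :, 0]
            beta[idx[good]] = b
            yhat = np.einsum("pij,pj->pi", Xv[good], b)
            pred[idx[good]] = yhat
            resid = Yv[good] - yhat
            dof = max(ny - (p + 1), 1)
            sigma2 = (resid**2).sum(axis=1) / dof
            cov_diag = np.diagonal(np.linalg.inv(Gg), axis1=1, axis2=2)
            se[idx[good]] = np.sqrt(sigma2[:, None] * cov_diag)
            ss_tot = ((Yv[good] - Yv[good].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            ss_res = (resid**2).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                r2v = 1.0 - ss_res / ss_tot
            r2v[ss_tot == 0] = 0.0                        # constant NDVI: defined fit
            r2[idx[good]] = np.clip(r2v, 0.0, 1.0)

    predicted = ndvi.copy(values=pred.T.reshape(ny, nr, nc))
    predicted.variable = "ndvi_c"
    return PixelRegressions(
        variables=list(variables),
        coefficients=beta[:, :p].T.reshape(p, nr, nc),
        intercept=beta[:, p].reshape(nr, nc),
        std_errors=se.T.reshape(p + 1, nr, nc),
        r_squared=r2.reshape(nr, nc),
        predicted=predicted,
    )


@dataclass
class ResidualStacks:
    """Observed / climate-predicted / human-residual stacks for NDVI and CV."""

    ndvi_obs: GridStack
    ndvi_c: GridStack
    ndvi_h: GridStack
    cv_obs: GridStack
    cv_c: GridStack
    cv_h: GridStack


def decompose(ndvi_obs: GridStack, ndvi_c: GridStack, window: int = 3) -> ResidualStacks:
    """Exact residual decomposition of NDVI and its windowed CV.

    ``NDVI_H = NDVI_obs - NDVI_C`` identically; the CV of the predicted
    stack is computed with the same 3x3 spatial window as the observed CV,
    and ``CV_H = CV_obs - CV_C``.
    """
    ndvi_obs.require_same_grid(ndvi_c)
    if not np.array_equal(ndvi_obs.years, ndvi_c.years):
        raise ValueError("observed and predicted stacks must share years")
    ndvi_h = ndvi_obs.copy(values=ndvi_obs.values - ndvi_c.values)
    ndvi_h.variable = "ndvi_h"
    cv_obs = window_stack(ndvi_obs, "cv", window)
    cv_c = window_stack(ndvi_c, "cv", window)
    cv_h = cv_obs.copy(values=cv_obs.values - cv_c.values)
    cv_h.variable = "cv_ndvi_h"
    return ResidualStacks(ndvi_obs=ndvi_obs, ndvi_c=ndvi_c, ndvi_h=ndvi_h,
                          cv_obs=cv_obs, cv_c=cv_c, cv_h=cv_h)


def ols_slope_map(stack: GridStack) -> np.ndarray:
    """Per-pixel OLS slope against year (exactly additive across stacks)."""
    t = stack.years.astype(float)
    tc = t - t.mean()
    denom = (tc**2).sum()
    vals = stack.values.reshape(stack.n_years, -1)
    slope = np.where(
        np.isnan(vals).any(axis=0), np.nan, np.einsum("t,tp->p", tc, np.nan_to_num(vals)) / denom
    )
    return slope.reshape(stack.shape)


# ---------------------------------------------------------------------------
# Driver and scenario classification
# ---------------------------------------------------------------------------

def classify_driver(
    slope_obs: float, slope_c: float, slope_h: float
) -> tuple[str, float, float]:
    """Classify one pixel's driver and contribution rates.

    Sign truth table (same table serves NDVI and CV):

    ========== ========= ========= ======== =========================
    slope_obs  slope_C   slope_H   driver   climate% / human%
    ========== ========= ========= ======== =========================
    > 0        > 0       < 0       climate  100 / 0
    > 0        < 0       > 0       human    0 / 100
    > 0        > 0       > 0       both     100*C/obs / 100*H/obs
    < 0        < 0       > 0       climate  100 / 0
    < 0        > 0       < 0       human    0 / 100
    < 0        < 0       < 0       both     100*C/obs / 100*H/obs
    ========== ========= ========= ======== =========================

    ``slope_obs`` must be nonzero (zero-slope pixels are Stable upstream);
    a sign pattern outside the table (impossible when slopes are additive)
    raises ``ValueError``.
    """
    if np.isnan(slope_obs) or np.isnan(slope_c) or np.isnan(slope_h):
        raise ValueError("driver classification needs finite slopes")
    if slope_obs == 0:
        raise ValueError("slope_obs must be nonzero (handled upstream as Stable)")
    so, sc, sh = np.sign(slope_obs), np.sign(slope_c), np.sign(slope_h)
    if sc == so and sh == -so:
        return "climate", 100.0, 0.0
    if sc == -so and sh == so:
        return "human", 0.0, 100.0
    if sc == so and sh == so:
        return ("both", 100.0 * slope_c / slope_obs, 100.0 * slope_h / slope_obs)
    # a zero component slope: attribute wholly to the nonzero one
    if sh == 0 and sc == so:
        return "climate", 100.0, 0.0
    if sc == 0 and sh == so:
        return "human", 0.0, 100.0
    raise ValueError(
        f"sign pattern (obs={slope_obs}, C={slope_c}, H={slope_h}) not in the driver table"
    )


def driver_code(driver: str, increasing: bool, quantity: str) -> str:
    """Compose the field code, e.g. ('climate', True, 'ndvi') -> 'CDNI'."""
    letter = {"climate": "C", "human": "H", "both": "B"}[driver]
    if quantity == "ndvi":
        suffix = "NI" if increasing else "ND"
    else:
        suffix = "CI" if increasing else "CD"
    return f"{letter}D{suffix}"


#: scenario id -> (label, description)
SCENARIO_LABELS = {
    1: ("CDI", "Climate-driven grassland improvement"),
    2: ("HDI", "Human activities-driven grassland improvement"),
    3: ("BDI", "Both drivers effected grassland improvement"),
    4: ("CDSR", "Climate-driven slight degradation or re-growing"),
    5: ("HDSR", "Human activities-driven slight degradation or re-growing"),
    6: ("BDSR", "Both drivers effected slight degradation or re-growing"),
    7: ("CDMD", "Climate-driven moderate degradation"),
    8: ("HDMD", "Human activities-driven moderate degradation"),
    9: ("BDMD", "Both drivers effected moderate degradation"),
    10: ("CDSD", "Climate-driven severe degradation or desertification"),
    11: ("HDSD", "Human activities-driven severe degradation or desertification"),
    12: ("BDSD", "Both drivers effected severe degradation or desertification"),
}

# combined driver letter from the (NDVI driver, CV driver) pair
_COMBINE = {
    ("C", "C"): "C", ("C", "B"): "C", ("B", "C"): "C",
    ("H", "H"): "H", ("H", "B"): "H", ("B", "H"): "H",
    ("C", "H"): "B", ("H", "C"): "B", ("B", "B"): "B",
}
_GROUP_BASE = {("I", "D"): 1, ("I", "I"): 4, ("D", "I"): 7, ("D", "D"): 10}
_LETTER_OFFSET = {"C": 0, "H": 1, "B": 2}


def classify_scenario(ndvi_driver: str, cv_driver: str) -> tuple[int, str]:
    """Map a (NDVI driver code, CV driver code) pair to a scenario 1-12.

    The scenario group is fixed by the trend-direction pair — NDVI increase
    with CV decrease is improvement (1-3), increase/increase slight
    degradation or regrowth (4-6), decrease/increase moderate degradation
    (7-9), decrease/decrease severe degradation or desertification (10-12)
    — and the position within the group by the combined driver letter:
    climate for {CC, CB, BC}, human for {HH, HB, BH}, both for {CH, HC, BB}.
    """
    for code in (ndvi_driver, cv_driver):
        if len(code) != 4 or code[0] not in "CHB" or code[1] != "D":
            raise ValueError(f"malformed driver code {code!r}")
    if ndvi_driver[2] != "N" or cv_driver[2] != "C":
        raise ValueError(
            f"expected an NDVI code then a CV code, got {ndvi_driver!r}, {cv_driver!r}"
        )
    ndvi_dir = ndvi_driver[3]   # I or D
    cv_dir = cv_driver[3]
    base = _GROUP_BASE[(ndvi_dir, cv_dir)]
    letter = _COMBINE[(ndvi_driver[0], cv_driver[0])]
    sid = base + _LETTER_OFFSET[letter]
    return sid, SCENARIO_LABELS[sid][0]


@dataclass
class DriverMap:
    """Per-pixel driver classes and contribution rates for NDVI and CV."""

    ndvi_driver: np.ndarray          # codes like CDNI ("" = undefined)
    cv_driver: np.ndarray
    ndvi_climate_pct: np.ndarray
    ndvi_human_pct: np.ndarray
    cv_climate_pct: np.ndarray
    cv_human_pct: np.ndarray


@dataclass
class ScenarioMap:
    """Per-pixel scenario 1-12 (0 = undefined) with labels."""

    scenario: np.ndarray
    label: np.ndarray

    def area_summary(self, cell_area: float = 1.0) -> pd.DataFrame:
        analyzed = self.scenario > 0
        total = int(analyzed.sum())
        rows = []
        for sid, (label, desc) in SCENARIO_LABELS.items():
            n = int((self.scenario == sid).sum())
            rows.append({"scenario": sid, "label": label, "description": desc,
                         "pixels": n, "area": n * cell_area,
                         "percent": 100.0 * n / total if total else np.nan})
        return pd.DataFrame(rows)


def _classify_quantity(slope_obs, slope_c, slope_h, quantity):
    nr, nc = slope_obs.shape
    code = np.full((nr, nc), "", dtype=object)
    cpct = np.full((nr, nc), np.nan)
    hpct = np.full((nr, nc), np.nan)
    ok = ~(np.isnan(slope_obs) | np.isnan(slope_c) | np.isnan(slope_h)) & (slope_obs != 0)
    for r, c in np.argwhere(ok):
        try:
            driver, cp, hp = classify_driver(slope_obs[r, c], slope_c[r, c], slope_h[r, c])
        except ValueError:
            continue
        code[r, c] = driver_code(driver, slope_obs[r, c] > 0, quantity)
        cpct[r, c], hpct[r, c] = cp, hp
    return code, cpct, hpct


def attribute(residuals: ResidualStacks, slope_mode: str = "ols") -> tuple[DriverMap, ScenarioMap]:
    """Driver and scenario maps from a residual decomposition.

    ``slope_mode='ols'`` (default) uses least-squares slopes, which are
    additive so contributions sum to 100%; ``'sen'`` uses Sen slopes with
    the component slopes renormalized to the observed slope (sensitivity
    mode; additivity is then imposed, not exact).
    """
    if slope_mode == "ols":
        slopes = {k: ols_slope_map(getattr(residuals, k))
                  for k in ("ndvi_obs", "ndvi_c", "ndvi_h", "cv_obs", "cv_c", "cv_h")}
    elif slope_mode == "sen":
        from .trends import trend_map
        slopes = {k: trend_map(getattr(residuals, k)).slope
                  for k in ("ndvi_obs", "ndvi_c", "ndvi_h", "cv_obs", "cv_c", "cv_h")}
        for q in ("ndvi", "cv"):
            tot = slopes[f"{q}_c"] + slopes[f"{q}_h"]
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = slopes[f"{q}_obs"] / tot
            scale[~np.isfinite(scale)] = 1.0
            slopes[f"{q}_c"] = slopes[f"{q}_c"] * scale
            slopes[f"{q}_h"] = slopes[f"{q}_h"] * scale
    else:
        raise ValueError(f"unknown slope_mode {slope_mode!r}")

    ncode, ncp, nhp = _classify_quantity(
        slopes["ndvi_obs"], slopes["ndvi_c"], slopes["ndvi_h"], "ndvi")
    ccode, ccp, chp = _classify_quantity(
        slopes["cv_obs"], slopes["cv_c"], slopes["cv_h"], "cv")
    drivers = DriverMap(ndvi_driver=ncode, cv_driver=ccode,
                        ndvi_climate_pct=ncp, ndvi_human_pct=nhp,
                        cv_climate_pct=ccp, cv_human_pct=chp)

    nr, nc = ncode.shape
    scen = np.zeros((nr, nc), dtype=int)
    label = np.full((nr, nc), "", dtype=object)
    both = (ncode != "") & (ccode != "")
    for r, c in np.argwhere(both):
        sid, lab = classify_scenario(ncode[r, c], ccode[r, c])
        scen[r, c] = sid
        label[r, c] = lab
    return drivers, ScenarioMap(scenario=scen, label=label)
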