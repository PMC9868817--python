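"""Single-predictor power-law biomass allometry and theory comparison.

The model is the classical allometric equation ``W = a D^c + eps`` where
``W`` is a component dry mass (kg) and ``D`` a stem diameter (cm) — either
DBH or the diameter at some relative height (DRH) predicted by a taper
equation.  Fitting is unweighted nonlinear least squares on the
untransformed scale, started from a log-log ordinary least squares
regression.

Two theoretical reference exponents matter for woody plants:

* metabolic scaling theory (MST) predicts ``c = 8/3`` for woody
  components (stem, branches);
* geometric similarity predicts ``c = 7/3``, relevant for foliage.

``scan_relative_heights`` fits every (component, predictor) pair over a
grid of relative heights and reports, per component, the predictor whose
fitted exponent lies nearest its theoretical value, together with a Wald
95 % confidence interval and a containment flag for the theory value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import least_squares

from .evaluation import FitStatistics, fit_statistics
from .taper import TaperParameterSet, TaperFitResult, diameter_at_relative_height

__all__ = [
    "THEORY_EXPONENTS",
    "AllometricFitResult",
    "TheoryComparison",
    "fit_power_law",
    "compare_to_theory",
    "scan_relative_heights",
    "select_nearest_to_theory",
]

#: Theoretical allometric exponents: metabolic scaling theory (woody
#: components) and geometric similarity (foliage).
THEORY_EXPONENTS: dict[str, float] = {"mst": 8.0 / 3.0, "geometric": 7.0 / 3.0}

#: Which theory each biomass component is compared against by default.
COMPONENT_THEORY: dict[str, str] = {
    "stem": "mst",
    "branch": "mst",
    "foliage": "geometric",
}


@dataclass
class AllometricFitResult:
    component: str
    predictor: str
    a: float
    c: float
    se_a: float
    se_c: float
    ci95_c: tuple[float, float]
    cov: np.ndarray
    stats: FitStatistics
    n_obs: int
    converged: bool


@dataclass(frozen=True)
class TheoryComparison:
    theory: str
    theory_value: float
    contained: bool
    abs_distance: float


def loglog_ols(w, d) -> tuple[float, float]:
    """Closed-form log-log regression start values ``(a, c)``."""
    lw, ld = np.log(np.asarray(w, float)), np.log(np.asarray(d, float))
    c, loga = np.polyfit(ld, lw, 1)
    return float(np.exp(loga)), float(c)


def fit_power_law(
    w,
    d,
    start: tuple[float, float] | None = None,
    component: str = "",
    predictor: str = "",
) -> AllometricFitResult:
    """Fit ``W = a D^c`` by nonlinear least squares on the natural scale.

    ``w`` and ``d`` must be strictly positive.  Start values default to the
    log-log OLS solution.  The 95 % interval for ``c`` is the t-based Wald
    interval ``c ± t(0.975, n-2) se_c``.
    """
    w = np.asarray(w, dtype=float)
    d = np.asarray(d, dtype=float)
    if w.shape != d.shape:
        raise ValueError("w and d must have equal length")
    n = w.size
    if n <= 2:
        raise ValueError("need more than 2 observations to fit a 2-parameter model")
    if np.any(w <= 0):
        raise ValueError("biomass values must be strictly positive")
    if np.any(d <= 0):
        raise ValueError("diameter values must be strictly positive")
    if np.ptp(d) == 0:
        raise ValueError("all diameters identical: power-law fit is rank-deficient")

    if start is None:
        start = loglog_ols(w, d)
    logd = np.log(d)

    def residuals(theta):
        a, c = theta
        return a * d**c - w

    def jac(theta):
        a, c = theta
        dc = d**c
        return np.column_stack([dc, a * dc * logd])

    res = least_squares(
        residuals, np.asarray(start, float), jac=jac,
        bounds=([1e-12, -np.inf], [np.inf, np.inf]),
        ftol=1e-12, xtol=1e-12, gtol=1e-10, max_nfev=10000,
    )
    a, c = res.x
    sse = float(2.0 * res.cost)
    dof = n - 2
    cov = np.linalg.pinv(res.jac.T @ res.jac) * sse / dof
    se_a, se_c = np.sqrt(np.maximum(np.diag(cov), 0.0))
    tcrit = float(sps.t.ppf(0.975, dof))
    ci = (c - tcrit * se_c, c + tcrit * se_c)
    yhat = a * d**c
    stats = fit_statistics(w, yhat, n_params=2)
    return AllometricFitResult(
        component=component, predictor=predictor,
        a=float(a), c=float(c), se_a=float(se_a), se_c=float(se_c),
        ci95_c=ci, cov=cov, stats=stats, n_obs=n,
        converged=bool(res.status > 0),
    )


def compare_to_theory(fit: AllometricFitResult, theory: str | float) -> TheoryComparison:
    """Containment of a theoretical exponent in the fitted 95 % interval.

    ``theory`` is a name from :data:`THEORY_EXPONENTS` or a numeric value.
    Pure arithmetic on the stored interval; nothing is refit.
    """
    if isinstance(theory, str):
        name, value = theory, THEORY_EXPONENTS[theory]
    else:
        name, value = "custom", float(theory)
    lo, hi = fit.ci95_c
    return TheoryComparison(
        theory=name,
        theory_value=value,
        contained=bool(lo <= value <= hi),
        abs_distance=abs(fit.c - value),
    )


DEFAULT_PREDICTOR_GRID: tuple = ("dbh", 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


def _predictor_label(p) -> str:
    return "DBH" if isinstance(p, str) else f"D_{p:g}"


def scan_relative_heights(
    trees: pd.DataFrame,
    taper: TaperParameterSet | TaperFitResult,
    biomass: pd.DataFrame,
    components: tuple[str, ...] = ("stem", "branch", "foliage"),
    grid: tuple = DEFAULT_PREDICTOR_GRID,
) -> pd.DataFrame:
    """Fit every (component, predictor) power law over a DRH grid.

    ``trees`` needs ``tree_id``, ``dbh_cm``, ``height_m``; ``biomass``
    needs ``tree_id`` and ``<component>_kg`` columns.  DRH predictors are
    computed from the taper parameters (noise-free curve).  One output row
    per (component, predictor) with coefficients, Wald interval, theory
    containment flags for both reference exponents, and fit statistics; a
    failed fit is recorded with NaNs rather than raised.
    """
    merged = trees.merge(biomass, on="tree_id", validate="one_to_one")
    dbh = merged["dbh_cm"].to_numpy(float)
    height = merged["height_m"].to_numpy(float)
    rows = []
    for pred in grid:
        if isinstance(pred, str):
            if pred.lower() != "dbh":
                raise ValueError(f"unknown predictor tag {pred!r}")
            dvec = dbh
        else:
            dvec = np.asarray(
                diameter_at_relative_height(taper, dbh, height, float(pred)), float
            )
        label = _predictor_label(pred)
        for comp in components:
            w = merged[f"{comp}_kg"].to_numpy(float)
            row = {"component": comp, "predictor": label,
                   "rel_height": np.nan if isinstance(pred, str) else float(pred)}
            try:
                fit = fit_power_law(w, dvec, component=comp, predictor=label)
            except Exception as exc:  # record, not fatal
                row.update({"a": np.nan, "se_a": np.nan, "c": np.nan,
                            "se_c": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                            "mst_contained": False, "geom_contained": False,
                            "mst_distance": np.nan, "geom_distance": np.nan,
                            "r2": np.nan, "r2_adj": np.nan, "mab": np.nan,
                            "rmse": np.nan, "mpb": np.nan,
                            "converged": False, "error": str(exc)})
                rows.append(row)
                continue
            mst = compare_to_theory(fit, "mst")
            geo = compare_to_theory(fit, "geometric")
            row.update({
                "a": fit.a, "se_a": fit.se_a, "c": fit.c, "se_c": fit.se_c,
                "ci_low": fit.ci95_c[0], "ci_high": fit.ci95_c[1],
                "mst_contained": mst.contained, "geom_contained": geo.contained,
                "mst_distance": mst.abs_distance, "geom_distance": geo.abs_distance,
                "r2": fit.stats.r2, "r2_adj": fit.stats.r2_adj,
                "mab": fit.stats.mab, "rmse": fit.stats.rmse,
                "mpb": fit.stats.mpb, "converged": fit.converged, "error": "",
            })
            rows.append(row)
    return pd.DataFrame(rows)


def select_nearest_to_theory(scan: pd.DataFrame) -> pd.DataFrame:
    """Per component, the predictor whose exponent is closest to its theory.

    Stem and branch are judged against 8/3 (MST), foliage against 7/3
    (geometric).  Ties break toward the lower relative height (DBH treated
    as lowest).
    """
    picks = []
    for comp, sub in scan.groupby("component", sort=False):
        theory = COMPONENT_THEORY.get(comp, "mst")
        col = "mst_distance" if theory == "mst" else "geom_distance"
        sub = sub.dropna(subset=[col]).copy()
        if sub.empty:
            continue
        # stable sort: distance first, then relative height ascending
        # (NaN rel_height = DBH sorts first)
        sub["_rh"] = sub["rel_height"].fillna(-1.0)
        sub = sub.sort_values([col, "_rh"], kind="mergesort")
        best = sub.iloc[0]
        picks.append({
            "component": comp, "predictor": best["predictor"],
            "rel_height": best["rel_height"], "a": best["a"], "c": best["c"],
            "theory": theory, "theory_value": THEORY_EXPONENTS[theory],
            "distance": best[col],
            "contained": bool(best["mst_contained"] if theory == "mst"
                              else best["geom_contained"]),
        })
    return pd.DataFrame(picks)
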