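"""Variable-exponent stem taper equations.

A taper equation predicts the stem diameter ``d`` (cm, over the whole
profile) at any height ``h`` along the stem from tree-level size variables
(DBH, total height H).  Variable-exponent forms write the profile as a base
term raised to an exponent that itself changes along the stem, which makes
them flexible enough to describe butt swell, the mid-stem paraboloid and
the conic tip with one smooth function.

Three Kozak-family models are implemented, named by their customary ids:

``kozak1988``
    ``d = b1 DBH^b2 b3^DBH X^(b4 T^2 + b5 ln(T+0.001) + b6 sqrt(T)
    + b7 e^T + b8 DBH/H)`` with ``X = (1-sqrt(T))/(1-sqrt(0.01))`` and
    ``T = h/H``.

``kozakI2004``
    ``d = b1 DBH^b2 X^(b3 + b4 e^(-DBH/H) + b5 DBH^X + b6 X^(DBH/H))``
    with ``X = (1-T^(1/4))/(1-0.01^(1/4))``.

``kozakII2004``
    ``d = b1 DBH^b2 H^b3 X^(b4 T^4 + b5 e^(-DBH/H) + b6 X^0.1 + b7/DBH
    + b8 H^(1-T^(1/3)) + b9 X)`` with
    ``X = (1-T^(1/3))/(1-(1.3/H)^(1/3))``.

The ``kozakII2004`` base is anchored at breast height: at ``h = 1.3`` the
ratio ``X`` equals 1 and the prediction reduces to ``b1 DBH^b2 H^b3``
regardless of the exponent; at the tip (``T = 1``) the numerator vanishes
and the predicted diameter is 0.

Fitting is ordinary nonlinear least squares over all stem-section
observations, pooled across trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .evaluation import FitStatistics, fit_statistics
from . import reference

__all__ = [
    "MODEL_N_PARAMS",
    "TaperParameterSet",
    "TaperFitResult",
    "predict_diameter",
    "diameter_at_relative_height",
    "join_sections",
    "fit_taper",
]

MODEL_N_PARAMS = {"kozak1988": 8, "kozakI2004": 6, "kozakII2004": 9}


@dataclass(frozen=True)
class TaperParameterSet:
    """A taper model id together with its parameter vector ``b``."""

    model_id: str
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_N_PARAMS:
            raise ValueError(
                f"unknown taper model {self.model_id!r}; "
                f"expected one of {sorted(MODEL_N_PARAMS)}"
            )
        b = tuple(float(v) for v in self.b)
        if len(b) != MODEL_N_PARAMS[self.model_id]:
            raise ValueError(
                f"{self.model_id} takes {MODEL_N_PARAMS[self.model_id]} "
                f"parameters, got {len(b)}"
            )
        if b[0] <= 0:
            raise ValueError("scale parameter b1 must be positive")
        object.__setattr__(self, "b", b)


@dataclass
class TaperFitResult:
    params: TaperParameterSet
    se: np.ndarray
    cov: np.ndarray
    stats: FitStatistics
    n_obs: int
    converged: bool
    sse: float
    n_starts_tried: int = 1
    message: str = ""


def reference_params(model_id: str) -> TaperParameterSet:
    """Published larch-plantation parameter vector for ``model_id``."""
    return TaperParameterSet(model_id, reference.TAPER_PARAMS[model_id])


def _validate_inputs(dbh, height, rel_height) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dbh = np.asarray(dbh, dtype=float)
    height = np.asarray(height, dtype=float)
    t = np.asarray(rel_height, dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("dbh_cm must be positive")
    if np.any(height <= 1.3):
        raise ValueError("height_m must exceed breast height (1.3 m)")
    if np.any((t < 0) | (t > 1)):
        raise ValueError("rel_height must lie in [0, 1]")
    return dbh, height, t


def _eval_kozak1988(b, dbh, height, t):
    b1, b2, b3, b4, b5, b6, b7, b8 = b
    x = (1.0 - np.sqrt(t)) / (1.0 - np.sqrt(0.01))
    expo = (
        b4 * t**2
        + b5 * np.log(t + 0.001)
        + b6 * np.sqrt(t)
        + b7 * np.exp(t)
        + b8 * dbh / height
    )
    base = b1 * dbh**b2 * np.asarray(b3, dtype=float) ** dbh
    with np.errstate(divide="ignore", invalid="ignore"):
        d = base * np.where(x > 0, x, 1.0) ** expo
    return np.where(x > 0, d, 0.0)


def _eval_kozakI2004(b, dbh, height, t):
    b1, b2, b3, b4, b5, b6 = b
    x = (1.0 - t**0.25) / (1.0 - 0.01**0.25)
    expo = (
        b3
        + b4 * np.exp(-dbh / height)
        + b5 * dbh ** x
        + b6 * np.where(x > 0, x, 1.0) ** (dbh / height)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = b1 * dbh**b2 * np.where(x > 0, x, 1.0) ** expo
    return np.where(x > 0, d, 0.0)


def _eval_kozakII2004(b, dbh, height, t):
    b1, b2, b3, b4, b5, b6, b7, b8, b9 = b
    tcr = t ** (1.0 / 3.0)
    x = (1.0 - tcr) / (1.0 - (1.3 / height) ** (1.0 / 3.0))
    xsafe = np.where(x > 0, x, 1.0)
    expo = (
        b4 * t**4
        + b5 * np.exp(-dbh / height)
        + b6 * xsafe**0.1
        + b7 / dbh
        + b8 * height ** (1.0 - tcr)
        + b9 * x
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = b1 * dbh**b2 * height**b3 * xsafe**expo
    return np.where(x > 0, d, 0.0)


_EVALUATORS = {
    "kozak1988": _eval_kozak1988,
    "kozakI2004": _eval_kozakI2004,
    "kozakII2004": _eval_kozakII2004,
}


def predict_diameter(params: TaperParameterSet, dbh_cm, height_m, rel_height):
    """Predicted stem diameter (cm) at relative height ``T = h/H``.

    Broadcasts over any mix of scalar and array arguments; a scalar call
    returns a float.  At the stem tip (``T = 1``) all three models return
    exactly 0.
    """
    dbh, height, t = _validate_inputs(dbh_cm, height_m, rel_height)
    d = _EVALUATORS[params.model_id](np.asarray(params.b), dbh, height, t)
    if np.ndim(d) == 0:
        return float(d)
    return d


def diameter_at_relative_height(fit_or_params, dbh_cm, height_m, i):
    """Diameter at relative height ``i`` — the DRH predictor for allometry.

    ``i`` must lie strictly inside (0, 1): the endpoints are the ground and
    the tip, which are not usable mass predictors.
    """
    if np.any((np.asarray(i, dtype=float) <= 0) | (np.asarray(i, dtype=float) >= 1)):
        raise ValueError("relative height i must lie strictly in (0, 1)")
    params = fit_or_params.params if isinstance(fit_or_params, TaperFitResult) else fit_or_params
    return predict_diameter(params, dbh_cm, height_m, i)


def join_sections(trees: pd.DataFrame, taper: pd.DataFrame) -> pd.DataFrame:
    """Join section measurements to tree-level variables for fitting.

    Resolves the ``height_m`` name clash: in the tree list it is the total
    height, in the section table the height of the section above ground.
    The result carries the *total* height as ``height_m``.
    """
    sections = taper[["tree_id", "rel_height", "diameter_cm"]]
    return sections.merge(trees[["tree_id", "dbh_cm", "height_m"]], on="tree_id")


def _heuristic_start(model_id: str, data: pd.DataFrame) -> np.ndarray:
    """Data-driven fallback start: scale from mean d/DBH, flat exponent."""
    ratio = float(np.mean(data["diameter_cm"] / data["dbh_cm"]))
    n = MODEL_N_PARAMS[model_id]
    b = np.full(n, 0.01)
    b[0] = max(ratio, 0.1)
    b[1] = 1.0
    if model_id == "kozak1988":
        b[2] = 1.0  # b3^DBH term: neutral
    if model_id == "kozakI2004":
        b[2] = 0.5  # exponent intercept
    return b


def fit_taper(
    model_id: str,
    data: pd.DataFrame,
    start: TaperParameterSet | None = None,
    max_nfev: int = 20000,
) -> TaperFitResult:
    """Fit a taper model to pooled stem-section data by nonlinear least squares.

    Parameters
    ----------
    model_id
        One of ``kozak1988``, ``kozakI2004``, ``kozakII2004``.
    data
        One row per section measurement with columns ``dbh_cm``,
        ``height_m``, ``rel_height``, ``diameter_cm`` (tree-level variables
        repeated on each section row).
    start
        Optional start vector.  By default two starts are tried — the
        published larch calibration vector and a data-driven heuristic —
        and the solution with the lowest SSE is kept.

    Standard errors come from the Jacobian-based covariance
    ``(J'J)^-1 SSE/(n - p)`` at the optimum.
    """
    if model_id not in MODEL_N_PARAMS:
        raise ValueError(f"unknown taper model {model_id!r}")
    n_par = MODEL_N_PARAMS[model_id]
    required = {"dbh_cm", "height_m", "rel_height", "diameter_cm"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"taper data missing columns: {sorted(missing)}")
    n_obs = len(data)
    if n_obs < 2 * n_par:
        raise ValueError(
            f"need at least {2 * n_par} observations to fit {model_id}, got {n_obs}"
        )
    dbh = data["dbh_cm"].to_numpy(float)
    height = data["height_m"].to_numpy(float)
    t = data["rel_height"].to_numpy(float)
    y = data["diameter_cm"].to_numpy(float)
    _validate_inputs(dbh, height, t)
    evaluate = _EVALUATORS[model_id]

    def residuals(b):
        return evaluate(b, dbh, height, t) - y

    lower = np.full(n_par, -np.inf)
    upper = np.full(n_par, np.inf)
    lower[0] = 1e-8  # b1 > 0
    if model_id == "kozak1988":
        lower[2] = 1e-8  # b3^DBH requires b3 > 0

    if start is not None:
        starts = [np.asarray(start.b, dtype=float)]
    else:
        starts = [
            np.asarray(reference.TAPER_PARAMS[model_id], dtype=float),
            _heuristic_start(model_id, data),
        ]

    best = None
    for s in starts:
        s = np.clip(s, lower + 1e-10, None)
        res = least_squares(
            residuals, s, bounds=(lower, upper),
            ftol=1e-10, xtol=1e-10, gtol=1e-8, max_nfev=max_nfev,
        )
        if best is None or res.cost < best.cost:
            best = res

    sse = float(2.0 * best.cost)
    jac = best.jac
    dof = max(n_obs - n_par, 1)
    jtj_inv = np.linalg.pinv(jac.T @ jac)
    cov = jtj_inv * sse / dof
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    params = TaperParameterSet(model_id, tuple(best.x))
    yhat = evaluate(best.x, dbh, height, t)
    stats = fit_statistics(y, yhat, n_params=n_par)
    return TaperFitResult(
        params=params,
        se=se,
        cov=cov,
        stats=stats,
        n_obs=n_obs,
        converged=bool(best.status > 0),
        sse=sse,
        n_starts_tried=len(starts),
        message=best.message,
    )
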