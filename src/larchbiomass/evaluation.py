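"""Goodness-of-fit statistics and leave-one-out cross-validation.

The statistic battery is the one customary in taper/biomass modelling:

* ``R2 = 1 - SSres/SStot``
* ``R2_adj = 1 - (1 - R2) (n-1)/(n-lambda)`` with ``lambda`` the number of
  fitted parameters
* ``MAB = mean(|e|)`` — mean absolute bias, units of y
* ``MPB = 100 * sum(|e|) / sum(y)`` — mean percentage bias, percent
* ``RMSE = sqrt(SSres / (n-1))``

Note the RMSE divisor: the forestry convention followed here divides by
``n - 1`` rather than ``n``; the two agree asymptotically and the
conventional variant is available via ``rmse_divisor="n"``.

Cross-validation is leave-one-*tree*-out: all measurements belonging to a
tree leave the training set together, the model is refit, and the held-out
tree is predicted.  Statistics are pooled over all held-out predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = ["FitStatistics", "fit_statistics", "LOOCVResult", "loocv"]


@dataclass(frozen=True)
class FitStatistics:
    r2: float
    r2_adj: float
    mab: float
    mpb: float
    rmse: float
    n: int
    n_params: int

    def as_dict(self) -> dict[str, float]:
        return {
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "mab": self.mab,
            "mpb": self.mpb,
            "rmse": self.rmse,
            "n": self.n,
            "n_params": self.n_params,
        }


def fit_statistics(
    y, yhat, n_params: int, rmse_divisor: str = "n-1"
) -> FitStatistics:
    """Compute the R2 / R2_adj / MAB / MPB / RMSE battery.

    ``rmse_divisor`` selects the RMSE denominator: the default ``"n-1"``
    (forestry convention) or ``"n"``.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted vectors must have equal length")
    n = y.size
    if n <= max(n_params, 1):
        raise ValueError(f"need more than max(n_params, 1) = {max(n_params, 1)} observations")
    if rmse_divisor not in ("n-1", "n"):
        raise ValueError("rmse_divisor must be 'n-1' or 'n'")
    e = y - yhat
    ss_res = float(e @ e)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values have zero variance; R2 undefined")
    ysum = float(y.sum())
    if ysum == 0.0:
        raise ValueError("sum of observed values is zero; MPB undefined")
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params)
    mab = float(np.mean(np.abs(e)))
    mpb = 100.0 * float(np.sum(np.abs(e))) / ysum
    denom = n - 1 if rmse_divisor == "n-1" else n
    rmse = float(np.sqrt(ss_res / denom))
    return FitStatistics(r2=r2, r2_adj=r2_adj, mab=mab, mpb=mpb, rmse=rmse,
                         n=n, n_params=n_params)


@dataclass
class LOOCVResult:
    records: pd.DataFrame      # tree_id, observed, predicted (held-out)
    stats: FitStatistics
    n_folds: int
    failed_folds: list        # tree ids whose refit failed


def loocv(
    data: pd.DataFrame,
    fitter: Callable[[pd.DataFrame], object],
    predict: Callable[[object, pd.DataFrame], np.ndarray],
    y_col: str,
    n_params: int,
    group_col: str = "tree_id",
) -> LOOCVResult:
    """Leave-one-tree-out cross-validation of an arbitrary fitter.

    Parameters
    ----------
    data
        Observation table; all rows sharing ``group_col`` leave together.
    fitter
        ``fitter(train_df) -> model``; must be deterministic given the data.
    predict
        ``predict(model, test_df) -> array`` of predictions for the
        held-out rows.
    y_col
        Column holding the observed response.
    n_params
        Parameter count of the full model, used for the adjusted R2 of the
        pooled held-out statistics.

    Folds whose refit raises are recorded in ``failed_folds`` and excluded
    from the pooled statistics.
    """
    ids = data[group_col].unique()
    rows = []
    failed = []
    for tid in ids:
        test = data[data[group_col] == tid]
        train = data[data[group_col] != tid]
        try:
            model = fitter(train)
            yhat = np.asarray(predict(model, test), dtype=float)
        except Exception:
            failed.append(tid)
            continue
        for obs, pred in zip(test[y_col].to_numpy(float), yhat):
            rows.append((tid, obs, pred))
    records = pd.DataFrame(rows, columns=[group_col, "observed", "predicted"])
    stats = fit_statistics(records["observed"], records["predicted"], n_params=n_params)
    return LOOCVResult(records=records, stats=stats, n_folds=len(ids), failed_folds=failed)
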