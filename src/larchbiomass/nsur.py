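"""Additive biomass systems by nonlinear seemingly unrelated regression.

The system jointly estimates one power law per biomass component,

    W_stem    = a1 * D_{i1}^c1 + e_stem
    W_branch  = a2 * D_{i2}^c2 + e_branch
    W_foliage = a3 * D_{i3}^c3 + e_foliage

with predicted above-ground biomass (AGB) defined *structurally* as the sum
of the three component predictions, so additivity holds to machine
precision.  Because each tree contributes one residual to each equation and
those residuals are correlated (a big tree tends to be heavy in every
compartment), joint feasible generalized least squares (FGLS) with the
cross-equation residual covariance is more efficient than fitting each
equation on its own.

Algorithm (iterated FGLS):

1. stage-1: independent nonlinear least squares per equation;
2. estimate the 3x3 residual covariance ``Sigma = R'R / n``;
3. minimise the stacked criterion ``r(theta)' (Sigma^-1 kron I_n) r(theta)``
   over all six parameters at once (implemented by whitening the per-tree
   residual triple with a Cholesky factor of ``Sigma^-1``);
4. update ``Sigma`` from the new residuals and repeat until the largest
   relative parameter change falls below 1e-6 (cap 50 iterations).

Standard errors come from the GLS information matrix at the optimum.

Observed AGB obtained by summing the observed components makes a fourth AGB
equation's residual the exact sum of the component residuals, so a 4x4
residual covariance is singular by construction; the total equation is
therefore excluded by default and guarded by a singularity check when
explicitly requested (for data where AGB was measured independently).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .allometry import fit_power_law
from .evaluation import FitStatistics, fit_statistics

__all__ = ["NSURSystemSpec", "NSURResult", "fit_nsur", "predict_components"]

COMPONENTS = ("stem", "branch", "foliage")


@dataclass
class NSURSystemSpec:
    """Specification of the three-equation additive system.

    ``predictors`` maps each component to the label of its diameter
    predictor (a column of the predictor table passed to
    :func:`fit_nsur`).  ``start`` optionally maps components to ``(a, c)``
    start values; stage-1 NLS supplies them otherwise.
    """

    predictors: dict[str, str]
    start: dict[str, tuple[float, float]] = field(default_factory=dict)
    include_total_equation: bool = False
    sigma_structure: str = "full"     # full | diagonal | identity
    sigma_divisor: str = "n"          # n | n-lambda
    max_iter: int = 50
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if set(self.predictors) != set(COMPONENTS):
            raise ValueError(f"predictors must be given for exactly {COMPONENTS}")
        if self.sigma_structure not in ("full", "diagonal", "identity"):
            raise ValueError("sigma_structure must be 'full', 'diagonal' or 'identity'")
        if self.sigma_divisor not in ("n", "n-lambda"):
            raise ValueError("sigma_divisor must be 'n' or 'n-lambda'")
        for comp, (a, _) in self.start.items():
            if a <= 0:
                raise ValueError(f"start scale for {comp} must be positive")


@dataclass
class NSURResult:
    estimates: dict[str, tuple[float, float]]   # component -> (a, c)
    se: dict[str, tuple[float, float]]          # component -> (se_a, se_c)
    cov: np.ndarray                             # 6x6, order stem a,c branch a,c foliage a,c
    sigma: pd.DataFrame                         # cross-equation residual covariance
    n_iter: int
    converged: bool
    stats: dict[str, FitStatistics]             # per component + "agb"
    spec: NSURSystemSpec
    stage1: dict[str, tuple[float, float]]      # independent-NLS estimates


def _apply_structure(sigma: np.ndarray, structure: str) -> np.ndarray:
    if structure == "identity":
        return np.eye(sigma.shape[0])
    if structure == "diagonal":
        return np.diag(np.diag(sigma))
    return sigma


def predict_components(result: NSURResult, predictors: pd.DataFrame) -> pd.DataFrame:
    """Per-tree component and AGB predictions from a fitted system.

    ``predictors`` holds one strictly positive diameter column per
    component, named as in the fitted spec.  The AGB column is the exact
    sum of the three component columns.
    """
    out = {}
    for comp in COMPONENTS:
        col = result.spec.predictors[comp]
        d = predictors[col].to_numpy(float)
        if np.any(d <= 0):
            raise ValueError(f"predictor {col!r} must be strictly positive")
        a, c = result.estimates[comp]
        out[comp] = a * d**c
    frame = pd.DataFrame(out, index=predictors.index)
    frame["agb"] = frame[list(COMPONENTS)].sum(axis=1)
    return frame


def fit_nsur(
    biomass: pd.DataFrame,
    predictors: pd.DataFrame,
    spec: NSURSystemSpec,
) -> NSURResult:
    """Estimate the additive system by iterated feasible GLS.

    Parameters
    ----------
    biomass
        One row per tree with columns ``stem_kg``, ``branch_kg``,
        ``foliage_kg`` (and optionally ``agb_kg`` when
        ``spec.include_total_equation``), aligned row-wise with
        ``predictors``.
    predictors
        One diameter column per component, named per ``spec.predictors``.
    """
    n = len(biomass)
    if n < 10:
        raise ValueError("NSUR needs at least 10 trees")
    if len(predictors) != n:
        raise ValueError("biomass and predictor tables must align row-wise")

    y = np.column_stack([biomass[f"{c}_kg"].to_numpy(float) for c in COMPONENTS])
    d = np.column_stack([predictors[spec.predictors[c]].to_numpy(float)
                         for c in COMPONENTS])
    if np.any(y <= 0):
        raise ValueError("component biomass must be strictly positive")
    if np.any(d <= 0):
        raise ValueError("diameter predictors must be strictly positive")
    logd = np.log(d)

    y_agb = None
    if spec.include_total_equation:
        if "agb_kg" not in biomass.columns:
            raise ValueError("include_total_equation requires an agb_kg column")
        y_agb = biomass["agb_kg"].to_numpy(float)
        if np.allclose(y_agb, y.sum(axis=1), rtol=1e-8, atol=1e-10):
            raise ValueError(
                "observed AGB equals the sum of the observed components, so the "
                "total-equation residual covariance is singular by construction; "
                "drop include_total_equation (additivity is already structural)"
            )

    # ---- stage 1: independent NLS per equation -------------------------
    # A complete user-supplied start is taken as the stage-1 point itself,
    # so the FGLS loop can be re-entered at a previous optimum.
    theta = np.empty(6)
    stage1 = {}
    if set(spec.start) == set(COMPONENTS):
        for j, comp in enumerate(COMPONENTS):
            theta[2 * j], theta[2 * j + 1] = spec.start[comp]
            stage1[comp] = tuple(map(float, spec.start[comp]))
    else:
        for j, comp in enumerate(COMPONENTS):
            fit = fit_power_law(y[:, j], d[:, j], start=spec.start.get(comp),
                                component=comp)
            theta[2 * j], theta[2 * j + 1] = fit.a, fit.c
            stage1[comp] = (fit.a, fit.c)

    n_eq = 3 if y_agb is None else 4

    def residual_matrix(th):
        r = np.empty((n, n_eq))
        pred = np.empty((n, 3))
        for j in range(3):
            pred[:, j] = th[2 * j] * d[:, j] ** th[2 * j + 1]
            r[:, j] = pred[:, j] - y[:, j]
        if n_eq == 4:
            r[:, 3] = pred.sum(axis=1) - y_agb
        return r

    def jac_matrix(th):
        """d residual / d theta, shape (n, n_eq, 6)."""
        g = np.zeros((n, n_eq, 6))
        for j in range(3):
            dc = d[:, j] ** th[2 * j + 1]
            g[:, j, 2 * j] = dc
            g[:, j, 2 * j + 1] = th[2 * j] * dc * logd[:, j]
            if n_eq == 4:
                g[:, 3, 2 * j] = dc
                g[:, 3, 2 * j + 1] = th[2 * j] * dc * logd[:, j]
        return g

    def estimate_sigma(th):
        r = residual_matrix(th)
        div = n if spec.sigma_divisor == "n" else max(n - 2, 1)
        return _apply_structure(r.T @ r / div, spec.sigma_structure)

    sigma = estimate_sigma(theta)

    # Numerically perfect stage-1 fit (zero-noise data): Sigma is the zero
    # matrix and GLS is undefined; stage-1 estimates are already exact.
    y_scale = float(np.mean(y**2))
    if float(np.trace(sigma)) <= 1e-18 * y_scale:
        return _finish(theta, np.zeros((6, 6)), sigma, 0, True,
                       y, d, y_agb, spec, stage1, residual_matrix)

    lower = np.array([1e-12, -np.inf] * 3)
    upper = np.full(6, np.inf)

    n_iter = 0
    converged = False
    whitened_jac_at_opt = None
    for n_iter in range(1, spec.max_iter + 1):
        if spec.sigma_structure != "identity":
            cond = np.linalg.cond(sigma)
            if not np.isfinite(cond) or cond > 1e10:
                raise ValueError(
                    f"cross-equation residual covariance is near-singular "
                    f"(condition number {cond:.3g}); check the system structure"
                    + (" — the total equation duplicates the component sum"
                       if n_eq == 4 else "")
                )
        sigma_inv = np.linalg.inv(sigma)
        cfac = np.linalg.cholesky(sigma_inv)  # r' Sinv r = ||r C||^2

        def whitened_residuals(th, _c=cfac):
            return (residual_matrix(th) @ _c).ravel()

        def whitened_jac(th, _c=cfac):
            g = jac_matrix(th)                       # (n, q, 6)
            gw = np.einsum("nqp,qk->nkp", g, _c)     # (n, q, 6)
            return gw.reshape(n * n_eq, 6)

        res = least_squares(
            whitened_residuals, np.clip(theta, lower + 1e-15, None),
            jac=whitened_jac, bounds=(lower, upper),
            ftol=1e-12, xtol=1e-12, gtol=1e-10, max_nfev=5000,
        )
        new_theta = res.x
        rel_change = float(np.max(np.abs(new_theta - theta)
                                  / np.maximum(np.abs(theta), 1e-12)))
        theta = new_theta
        whitened_jac_at_opt = res.jac
        sigma = estimate_sigma(theta)
        if rel_change < spec.tol:
            converged = True
            break
        if float(np.trace(sigma)) <= 1e-18 * y_scale:
            converged = True  # zero residuals: nothing left to weight
            break

    jw = whitened_jac_at_opt
    cov = np.linalg.pinv(jw.T @ jw)
    return _finish(theta, cov, sigma, n_iter, converged,
                   y, d, y_agb, spec, stage1, residual_matrix)


def _finish(theta, cov, sigma, n_iter, converged, y, d, y_agb, spec,
            stage1, residual_matrix) -> NSURResult:
    estimates = {c: (float(theta[2 * j]), float(theta[2 * j + 1]))
                 for j, c in enumerate(COMPONENTS)}
    se_vec = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se = {c: (float(se_vec[2 * j]), float(se_vec[2 * j + 1]))
          for j, c in enumerate(COMPONENTS)}
    pred = np.column_stack([theta[2 * j] * d[:, j] ** theta[2 * j + 1]
                            for j in range(3)])
    stats = {c: fit_statistics(y[:, j], pred[:, j], n_params=2)
             for j, c in enumerate(COMPONENTS)}
    obs_total = y.sum(axis=1) if y_agb is None else y_agb
    stats["agb"] = fit_statistics(obs_total, pred.sum(axis=1), n_params=6)
    labels = list(COMPONENTS) + (["agb"] if sigma.shape[0] == 4 else [])
    sigma_df = pd.DataFrame(sigma, index=labels, columns=labels)
    return NSURResult(
        estimates=estimates, se=se, cov=cov, sigma=sigma_df,
        n_iter=n_iter, converged=converged, stats=stats, spec=spec,
        stage1=stage1,
    )
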