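"""Monte-Carlo parameter-recovery experiments.

Each experiment simulates stands from the larch reference parameter sets
(:mod:`larchbiomass.reference`), refits the corresponding estimator, and
summarises the recovered parameters over seeds.  These are the package's
primary self-validation: with no field data deposited, correctness is
demonstrated by recovering the generating values within Monte-Carlo error.

All randomness flows from a single master seed via
``numpy.random.SeedSequence``; child seeds are reduced below 2**31.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import reference
from .allometry import fit_power_law
from .nsur import NSURSystemSpec, fit_nsur
from .synthetic import SimulationConfig, generate_biomass, generate_trees, generate_taper_profiles
from .taper import diameter_at_relative_height, fit_taper, join_sections

__all__ = [
    "child_seeds",
    "taper_recovery",
    "allometry_recovery",
    "nsur_recovery",
    "summarize_recovery",
]


def child_seeds(master_seed: int, n: int) -> list[int]:
    """``n`` independent integer seeds (< 2**31) derived from one master."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % 2**31 for s in ss.generate_state(n, dtype=np.uint64)]


def taper_recovery(
    n_seeds: int = 20,
    n_trees: int = 114,
    noise_sd: float = 0.6,
    master_seed: int = 20230109,
    model_id: str = "kozakII2004",
) -> pd.DataFrame:
    """Refit the taper model on stands simulated from its reference vector.

    Returns one row per seed with the recovered parameter vector
    (columns ``b1..``), plus ``converged`` and ``sse``.
    """
    rows = []
    for seed in child_seeds(master_seed, n_seeds):
        config = SimulationConfig(
            n_trees=n_trees, taper_model=model_id,
            taper_noise_sd=noise_sd, seed=seed,
        )
        trees = generate_trees(config)
        taper = generate_taper_profiles(trees, config)
        fit = fit_taper(model_id, join_sections(trees, taper))
        row = {f"b{i + 1}": v for i, v in enumerate(fit.params.b)}
        row["converged"] = fit.converged
        row["sse"] = fit.sse
        rows.append(row)
    return pd.DataFrame(rows)


def allometry_recovery(
    component: str,
    n_seeds: int = 20,
    n_trees: int = 1000,
    sigma: float = 0.15,
    master_seed: int = 20230109,
) -> pd.DataFrame:
    """Refit one power law on biomass simulated from its reference values.

    The generating ``(a, c, i)`` are the single-equation (plain nonlinear
    regression) reference values; the DRH predictor is computed from the
    reference taper curve without noise, and the component mass carries
    independent lognormal error with log-scale SD ``sigma``.
    """
    a_true, c_true, i_rel = reference.NLS_ALLOMETRY[component]
    rows = []
    for seed in child_seeds(master_seed, n_seeds):
        config = SimulationConfig(
            n_trees=n_trees,
            allom_params={k: reference.NLS_ALLOMETRY[k] for k in reference.NLS_ALLOMETRY},
            biomass_cv=(sigma, sigma, sigma),
            error_corr=np.eye(3),
            seed=seed,
        )
        trees = generate_trees(config)
        biomass = generate_biomass(trees, config)
        d = diameter_at_relative_height(
            config.taper_parameter_set(),
            trees["dbh_cm"].to_numpy(), trees["height_m"].to_numpy(), i_rel,
        )
        fit = fit_power_law(biomass[f"{component}_kg"].to_numpy(), d,
                            component=component)
        rows.append({"a": fit.a, "c": fit.c, "se_c": fit.se_c,
                     "converged": fit.converged})
    out = pd.DataFrame(rows)
    out.attrs["true"] = {"a": a_true, "c": c_true, "rel_height": i_rel}
    return out


def nsur_recovery(
    n_seeds: int = 20,
    n_trees: int = 114,
    sigma: float = 0.15,
    corr: float = 0.5,
    master_seed: int = 20230109,
) -> pd.DataFrame:
    """Refit the additive NSUR system on stands simulated from its values.

    Generating parameters are the additive-system reference values (stem on
    D_0.2, branch and foliage on D_0.5) with cross-component log-error
    correlation ``corr``.  Returns per-seed recovered ``(a, c)`` for each
    component plus iteration diagnostics.
    """
    error_corr = np.full((3, 3), corr) + (1.0 - corr) * np.eye(3)
    allom = dict(reference.NSUR_ALLOMETRY)
    rows = []
    for seed in child_seeds(master_seed, n_seeds):
        config = SimulationConfig(
            n_trees=n_trees, allom_params=allom,
            biomass_cv=(sigma, sigma, sigma), error_corr=error_corr,
            seed=seed,
        )
        trees = generate_trees(config)
        biomass = generate_biomass(trees, config)
        taper_params = config.taper_parameter_set()
        dbh = trees["dbh_cm"].to_numpy()
        h = trees["height_m"].to_numpy()
        predictors = pd.DataFrame({
            f"D_{i:g}": np.asarray(
                diameter_at_relative_height(taper_params, dbh, h, i), float)
            for i in sorted({allom[c][2] for c in allom})
        })
        spec = NSURSystemSpec(
            predictors={c: f"D_{allom[c][2]:g}" for c in allom},
        )
        res = fit_nsur(biomass, predictors, spec)
        row = {}
        for comp in ("stem", "branch", "foliage"):
            row[f"{comp}_a"], row[f"{comp}_c"] = res.estimates[comp]
        row["n_iter"] = res.n_iter
        row["converged"] = res.converged
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["true"] = {f"{c}_a": allom[c][0] for c in allom} | {
        f"{c}_c": allom[c][1] for c in allom}
    return out


def summarize_recovery(values: pd.Series | np.ndarray) -> dict[str, float]:
    """Mean, Monte-Carlo standard error and n of a recovered parameter."""
    v = np.asarray(values, dtype=float)
    return {
        "mean": float(v.mean()),
        "mc_se": float(v.std(ddof=1) / np.sqrt(v.size)),
        "n_seeds": int(v.size),
    }
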