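"""Synthetic larch-stand generator.

Generates stands of trees with taper profiles and correlated component
biomasses having the statistical structure the downstream estimators
assume, so every stage of the pipeline (taper fitting, DRH allometry,
additive NSUR) can be exercised and validated by parameter recovery
without any field data.

The generative model, stage by stage:

* **Tree list** — DBH from a normal distribution truncated to a
  min/max range; total height from a monotone Chapman-Richards-type
  height-diameter curve ``H = 1.3 + a (1 - exp(-b DBH))^c`` plus Gaussian
  noise, clipped above breast height.  Defaults reproduce the summary
  statistics of the 114-tree larch calibration stand (DBH mean 17.4 cm,
  SD 5.6, range [5.1, 26.8]; H mean ~13.6 m).
* **Taper profiles** — diameters on a fixed relative-height section grid
  (default: the 15-point grid 0.00, 0.02, 0.04, 0.06, 0.08, 0.10, 0.15,
  0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90) from a Kozak taper
  curve plus additive Gaussian measurement error, truncated at zero.
* **Component biomass** — ``W_k = a_k D_{i_k}^{c_k} exp(eps_k)`` where
  ``D_{i_k}`` comes from the *noise-free* taper curve and the log-scale
  errors ``(eps_stem, eps_branch, eps_foliage)`` are multivariate normal
  with per-component SD ``biomass_cv`` and a common correlation matrix
  (default 0.5 off-diagonal — the cross-equation correlation that makes
  seemingly-unrelated estimation worthwhile).  Observed AGB is defined as
  the exact sum of the three components.

Reproducibility: one master seed; independent child streams for the
tree/taper/biomass stages are derived with ``numpy.random.SeedSequence``
so the stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import reference
from .taper import TaperParameterSet, predict_diameter

__all__ = [
    "DEFAULT_SECTION_GRID",
    "SimulationConfig",
    "generate_trees",
    "generate_taper_profiles",
    "generate_biomass",
    "simulate_stand",
]

#: Relative heights at which stem sections are measured.
DEFAULT_SECTION_GRID: tuple[float, ...] = (
    0.00, 0.02, 0.04, 0.06, 0.08, 0.10, 0.15, 0.20,
    0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90,
)


def _default_error_corr() -> np.ndarray:
    return np.full((3, 3), 0.5) + 0.5 * np.eye(3)


@dataclass
class SimulationConfig:
    """All knobs of the generative model; defaults emulate the larch stand."""

    n_trees: int = 114
    dbh_mean: float = 17.4
    dbh_sd: float = 5.6
    dbh_min: float = 5.1
    dbh_max: float = 26.8
    # Chapman-Richards-type height-diameter curve H = 1.3 + a(1-e^(-b D))^c
    hd_a: float = 26.0
    hd_b: float = 0.04
    hd_c: float = 1.1
    height_noise_sd: float = 1.2
    taper_model: str = "kozakII2004"
    taper_params: tuple[float, ...] | None = None   # None -> larch reference
    taper_noise_sd: float = 0.6
    section_grid: tuple[float, ...] = DEFAULT_SECTION_GRID
    # component -> (a, c, relative height of the predictor diameter)
    allom_params: dict[str, tuple[float, float, float]] | None = None
    biomass_cv: tuple[float, float, float] = (0.15, 0.15, 0.15)
    error_corr: np.ndarray = field(default_factory=_default_error_corr)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees <= 0:
            raise ValueError("n_trees must be positive")
        if self.dbh_min >= self.dbh_max:
            raise ValueError("dbh_min must be strictly below dbh_max")
        if self.dbh_sd <= 0:
            raise ValueError("dbh_sd must be positive")
        if any(cv < 0 for cv in self.biomass_cv):
            raise ValueError("biomass_cv entries must be non-negative")
        corr = np.asarray(self.error_corr, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ValueError("error_corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("error_corr must have a unit diagonal")
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError("error_corr must be positive-definite") from exc
        self.error_corr = corr

    # -- derived pieces ---------------------------------------------------
    def taper_parameter_set(self) -> TaperParameterSet:
        b = self.taper_params
        if b is None:
            b = reference.TAPER_PARAMS[self.taper_model]
        return TaperParameterSet(self.taper_model, tuple(b))

    def allometry(self) -> dict[str, tuple[float, float, float]]:
        if self.allom_params is not None:
            return self.allom_params
        return dict(reference.NSUR_ALLOMETRY)

    def rngs(self) -> dict[str, np.random.Generator]:
        """Independent child streams per stage, all derived from ``seed``."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "trees": np.random.default_rng(children[0]),
            "taper": np.random.default_rng(children[1]),
            "biomass": np.random.default_rng(children[2]),
        }


def generate_trees(config: SimulationConfig) -> pd.DataFrame:
    """Tree list: ``tree_id``, ``dbh_cm``, ``height_m``.

    DBH is truncated-normal on ``[dbh_min, dbh_max]``; height follows the
    height-diameter curve plus noise and is clipped above breast height.
    """
    rng = config.rngs()["trees"]
    lo = (config.dbh_min - config.dbh_mean) / config.dbh_sd
    hi = (config.dbh_max - config.dbh_mean) / config.dbh_sd
    dbh = sps.truncnorm.rvs(
        lo, hi, loc=config.dbh_mean, scale=config.dbh_sd,
        size=config.n_trees, random_state=rng,
    )
    mean_h = 1.3 + config.hd_a * (1.0 - np.exp(-config.hd_b * dbh)) ** config.hd_c
    height = mean_h + rng.normal(0.0, config.height_noise_sd, size=config.n_trees)
    height = np.maximum(height, 1.31)
    return pd.DataFrame({
        "tree_id": np.arange(1, config.n_trees + 1),
        "dbh_cm": dbh,
        "height_m": height,
    })


def generate_taper_profiles(trees: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Section diameters on the configured grid, with measurement error.

    Diameter = taper-curve prediction + N(0, ``taper_noise_sd``), truncated
    at zero.  Output columns: ``tree_id``, ``rel_height``, ``height_m``
    (section height above ground), ``diameter_cm``.
    """
    params = config.taper_parameter_set()
    rng = config.rngs()["taper"]
    grid = np.asarray(config.section_grid, dtype=float)
    dbh = trees["dbh_cm"].to_numpy(float)[:, None]
    h_tot = trees["height_m"].to_numpy(float)[:, None]
    d = predict_diameter(params, dbh, h_tot, grid[None, :])
    if config.taper_noise_sd > 0:
        d = d + rng.normal(0.0, config.taper_noise_sd, size=d.shape)
    d = np.maximum(d, 0.0)
    n, m = d.shape
    return pd.DataFrame({
        "tree_id": np.repeat(trees["tree_id"].to_numpy(), m),
        "rel_height": np.tile(grid, n),
        "height_m": (h_tot * grid[None, :]).ravel(),
        "diameter_cm": d.ravel(),
    })


def generate_biomass(trees: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Correlated lognormal component biomasses driven by noise-free DRH.

    ``W_k = a_k D_{i_k}^{c_k} exp(eps_k)`` with ``(eps)`` multivariate
    normal (log-scale SDs ``biomass_cv``, correlation ``error_corr``);
    ``agb_kg`` is the exact sum of the three components.
    """
    params = config.taper_parameter_set()
    allom = config.allometry()
    rng = config.rngs()["biomass"]
    dbh = trees["dbh_cm"].to_numpy(float)
    h_tot = trees["height_m"].to_numpy(float)
    n = len(trees)

    sd = np.asarray(config.biomass_cv, dtype=float)
    # Cholesky of the correlation keeps zero-noise components exactly zero.
    z = rng.standard_normal((n, 3))
    eps = z @ np.linalg.cholesky(config.error_corr).T * sd

    out = {"tree_id": trees["tree_id"].to_numpy()}
    for j, comp in enumerate(("stem", "branch", "foliage")):
        a, c, i = allom[comp]
        d_i = np.asarray(predict_diameter(params, dbh, h_tot, i), dtype=float)
        out[f"{comp}_kg"] = a * d_i**c * np.exp(eps[:, j])
    frame = pd.DataFrame(out)
    frame["agb_kg"] = frame[["stem_kg", "branch_kg", "foliage_kg"]].sum(axis=1)
    return frame


def simulate_stand(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (trees, taper, biomass) in one call."""
    trees = generate_trees(config)
    return trees, generate_taper_profiles(trees, config), generate_biomass(trees, config)
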