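"""Synthetic stand generator: determinism, truncation, grid, error structure."""

import numpy as np
import pandas as pd
import pytest

from larchbiomass import (DEFAULT_SECTION_GRID, SimulationConfig,
                          generate_biomass, generate_taper_profiles,
                          generate_trees, predict_diameter, simulate_stand)
from larchbiomass.reference import BIOMASS_RANGES


def test_seed_determinism_across_all_generators():
    config = SimulationConfig(n_trees=25, seed=5)
    a = simulate_stand(config)
    b = simulate_stand(SimulationConfig(n_trees=25, seed=5))
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x, y)
    c = simulate_stand(SimulationConfig(n_trees=25, seed=6))
    assert not np.allclose(a[0]["dbh_cm"], c[0]["dbh_cm"])


def test_dbh_truncation_and_calibrated_mean():
    config = SimulationConfig(seed=0)
    means = []
    for seed in range(8):
        trees = generate_trees(SimulationConfig(seed=seed))
        assert trees["dbh_cm"].between(config.dbh_min, config.dbh_max).all()
        means.append(trees["dbh_cm"].mean())
    assert abs(np.mean(means) - 17.4) < 1.5


def test_heights_exceed_breast_height():
    trees = generate_trees(SimulationConfig(n_trees=500, height_noise_sd=5.0, seed=3))
    assert (trees["height_m"] > 1.3).all()


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimulationConfig(n_trees=0)
    with pytest.raises(ValueError):
        SimulationConfig(dbh_min=20.0, dbh_max=10.0)
    bad_corr = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
    with pytest.raises(ValueError, match="positive-definite"):
        SimulationConfig(error_corr=bad_corr)


def test_section_grid_conformity(default_stand):
    _, trees, taper, _ = default_stand
    counts = taper.groupby("tree_id")["rel_height"].agg(["count", tuple])
    assert (counts["count"] == len(DEFAULT_SECTION_GRID)).all()
    assert all(t == DEFAULT_SECTION_GRID for t in counts["tuple"])
    assert (taper["diameter_cm"] >= 0).all()


def test_zero_noise_taper_equals_curve(noiseless_stand):
    config, trees, taper, _ = noiseless_stand
    params = config.taper_parameter_set()
    merged = taper.merge(trees, on="tree_id", suffixes=("_section", ""))
    expected = predict_diameter(
        params,
        merged["dbh_cm"].to_numpy(),
        merged["height_m"].to_numpy(),
        merged["rel_height"].to_numpy(),
    )
    np.testing.assert_allclose(merged["diameter_cm"].to_numpy(), expected, rtol=1e-12)


def test_tip_diameter_zero_when_grid_includes_one():
    config = SimulationConfig(n_trees=5, seed=2, taper_noise_sd=0.0,
                              section_grid=(0.5, 1.0))
    trees = generate_trees(config)
    taper = generate_taper_profiles(trees, config)
    tips = taper[taper["rel_height"] == 1.0]
    assert np.allclose(tips["diameter_cm"], 0.0)


def test_zero_cv_biomass_is_exact_power_law(noiseless_stand):
    config, trees, _, biomass = noiseless_stand
    params = config.taper_parameter_set()
    allom = config.allometry()
    for comp in ("stem", "branch", "foliage"):
        a, c, i = allom[comp]
        d = predict_diameter(params, trees["dbh_cm"].to_numpy(),
                             trees["height_m"].to_numpy(), i)
        np.testing.assert_allclose(biomass[f"{comp}_kg"], a * d**c, rtol=1e-12)
    np.testing.assert_allclose(
        biomass["agb_kg"],
        biomass[["stem_kg", "branch_kg", "foliage_kg"]].sum(axis=1),
        rtol=0, atol=0,
    )


def test_biomass_positive_and_means_within_calibration_ranges(default_stand):
    _, _, _, biomass = default_stand
    for comp in ("stem", "branch", "foliage"):
        col = biomass[f"{comp}_kg"]
        assert (col > 0).all()
        lo, hi = BIOMASS_RANGES[comp]
        assert lo < col.mean() < hi


def test_identity_correlation_gives_uncorrelated_log_residuals():
    """With an identity copula the cross-component log-residual sample
    correlations vanish within Monte-Carlo error at large n (oracle: the
    correlation of the generated eps draws themselves)."""
    config = SimulationConfig(n_trees=4000, seed=11, error_corr=np.eye(3))
    trees = generate_trees(config)
    biomass = generate_biomass(trees, config)
    params = config.taper_parameter_set()
    allom = config.allometry()
    eps = {}
    for comp in ("stem", "branch", "foliage"):
        a, c, i = allom[comp]
        d = predict_diameter(params, trees["dbh_cm"].to_numpy(),
                             trees["height_m"].to_numpy(), i)
        eps[comp] = np.log(biomass[f"{comp}_kg"].to_numpy()) - np.log(a * d**c)
    corr = np.corrcoef(np.column_stack(list(eps.values())), rowvar=False)
    off = corr[~np.eye(3, dtype=bool)]
    assert np.all(np.abs(off) < 3.0 / np.sqrt(config.n_trees))


def test_correlated_copula_recovers_target_correlation():
    config = SimulationConfig(n_trees=4000, seed=12, biomass_cv=(0.3, 0.3, 0.3))
    trees = generate_trees(config)
    biomass = generate_biomass(trees, config)
    params = config.taper_parameter_set()
    allom = config.allometry()
    logs = []
    for comp in ("stem", "branch", "foliage"):
        a, c, i = allom[comp]
        d = predict_diameter(params, trees["dbh_cm"].to_numpy(),
                             trees["height_m"].to_numpy(), i)
        logs.append(np.log(biomass[f"{comp}_kg"].to_numpy()) - np.log(a * d**c))
    corr = np.corrcoef(np.column_stack(logs), rowvar=False)
    assert np.all(np.abs(corr[~np.eye(3, dtype=bool)] - 0.5) < 0.06)
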