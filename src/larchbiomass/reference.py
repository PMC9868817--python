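"""Reference parameter sets for a North-China larch plantation.

These are published calibration values for *Larix principis-rupprechtii*
plantation stands in northern China: fitted coefficients of three Kozak
variable-exponent taper equations, single-equation power-law biomass
coefficients on the best diameter-at-relative-height (DRH) predictors, and
the corresponding additive-system (NSUR) coefficients.  They serve two
purposes in this package:

* defaults for the synthetic stand generator, so simulated stands resemble
  the real plantation the models were calibrated on, and
* generating values for the parameter-recovery experiments in
  :mod:`larchbiomass.experiments`.

Summary statistics of the calibration stand (114 destructively sampled
trees) used by the generator defaults: DBH mean 17.4 cm, SD 5.6, range
[5.1, 26.8]; total height mean 13.6 m, range [3.5, 21.9].
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Taper equations: fitted parameter vectors b1.. per model id.
# ---------------------------------------------------------------------------
TAPER_PARAMS: dict[str, tuple[float, ...]] = {
    "kozak1988": (1.281, 0.977, 0.998, -1.002, 0.235, -2.923, 1.671, 0.133),
    "kozakI2004": (1.392, 0.936, 0.485, -0.137, 0.003, -0.335),
    "kozakII2004": (0.973, 0.991, 0.022, 0.549, -1.035, 0.668, 1.265, 0.010, -0.158),
}

# Approximate standard errors, same order as TAPER_PARAMS.
TAPER_SE: dict[str, tuple[float, ...]] = {
    "kozak1988": (0.050, 0.022, 0.001, 0.094, 0.005, 0.083, 0.032, 0.012),
    "kozakI2004": (0.025, 0.005, 0.001, 0.044, 0.001, 0.015),
    "kozakII2004": (0.015, 0.008, 0.009, 0.015, 0.041, 0.015, 0.184, 0.001, 0.013),
}

# ---------------------------------------------------------------------------
# Single-equation power-law biomass models W = a * D_i^c fitted by plain
# nonlinear regression, on the DRH predictor whose exponent came closest to
# its theoretical value (stem/branch: 8/3 metabolic scaling; foliage: 7/3
# geometric scaling).  Keyed by component; values (a, c, relative height).
# ---------------------------------------------------------------------------
NLS_ALLOMETRY: dict[str, tuple[float, float, float]] = {
    "stem": (0.0501, 2.6779, 0.2),
    "branch": (0.0236, 2.6754, 0.5),
    "foliage": (0.0116, 2.3253, 0.5),
}

# Same structure estimated jointly as an additive system by NSUR.
NSUR_ALLOMETRY: dict[str, tuple[float, float, float]] = {
    "stem": (0.0318, 2.6657, 0.2),
    "branch": (0.0087, 2.6568, 0.5),
    "foliage": (0.0127, 2.3151, 0.5),
}

# Calibration-stand tree size summary (cm / m).
STAND_SUMMARY = {
    "n_trees": 114,
    "dbh_mean": 17.4,
    "dbh_sd": 5.6,
    "dbh_min": 5.1,
    "dbh_max": 26.8,
    "height_mean": 13.6,
    "height_min": 3.5,
    "height_max": 21.9,
}

# Observed dry-mass ranges (kg) of the calibration stand, per component.
BIOMASS_RANGES = {
    "stem": (2.37, 256.2),
    "branch": (1.14, 58.2),
    "foliage": (0.64, 17.32),
    "agb": (4.96, 318.4),
}
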