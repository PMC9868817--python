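"""End-to-end pipeline: simulate/load -> taper -> allometry scan -> NSUR -> CV.

Input is either three CSV tables (tree list, stem-section taper
measurements, component biomass) or a :class:`SimulationConfig`; output is
a directory of result tables mirroring the standard reporting layout of
taper/biomass studies (taper coefficients with SEs, per-model
goodness-of-fit, the DRH allometry scan, the additive-system coefficients
and residual covariance, cross-validation records) plus a machine-readable
run report.

File schemas (UTF-8 CSV, headers mandatory, decimal point):

* ``trees.csv``   — tree_id, dbh_cm, height_m
* ``taper.csv``   — tree_id, rel_height, height_m, diameter_cm
* ``biomass.csv`` — tree_id, stem_kg, branch_kg, foliage_kg, agb_kg
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .allometry import (DEFAULT_PREDICTOR_GRID, scan_relative_heights,
                        select_nearest_to_theory)
from .evaluation import loocv
from .nsur import NSURSystemSpec, fit_nsur, predict_components
from .synthetic import SimulationConfig, simulate_stand
from .taper import (MODEL_N_PARAMS, TaperParameterSet, diameter_at_relative_height,
                    fit_taper, join_sections, predict_diameter)

__all__ = [
    "PipelineConfig", "RunReport", "run_pipeline",
    "read_trees", "read_taper", "read_biomass", "write_table",
]

_FLOAT_FMT = "%.10g"

_SCHEMAS = {
    "trees": {"tree_id": None, "dbh_cm": "positive", "height_m": "above_bh"},
    "taper": {"tree_id": None, "rel_height": "unit_interval",
              "height_m": "nonnegative", "diameter_cm": "nonnegative"},
    "biomass": {"tree_id": None, "stem_kg": "positive", "branch_kg": "positive",
                "foliage_kg": "positive", "agb_kg": "positive"},
}

_CHECKS = {
    "positive": (lambda s: s > 0, "must be strictly positive"),
    "nonnegative": (lambda s: s >= 0, "must be non-negative"),
    "above_bh": (lambda s: s > 1.3, "must exceed breast height (1.3 m)"),
    "unit_interval": (lambda s: (s >= 0) & (s <= 1), "must lie in [0, 1]"),
}


def _read_validated(path, kind: str) -> pd.DataFrame:
    schema = _SCHEMAS[kind]
    frame = pd.read_csv(path)
    missing = set(schema) - set(frame.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {sorted(missing)} "
            f"(header row mandatory)"
        )
    for col, rule in schema.items():
        if rule is None:
            continue
        ok_fn, msg = _CHECKS[rule]
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = ~ok_fn(values) | values.isna()
        if bad.any():
            rows = (frame.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise ValueError(f"{path}: column {col!r} {msg}; offending file row(s) {rows}")
        frame[col] = values
    return frame


def read_trees(path) -> pd.DataFrame:
    frame = _read_validated(path, "trees")
    if frame["tree_id"].duplicated().any():
        dup = frame.loc[frame["tree_id"].duplicated(), "tree_id"].iloc[0]
        raise ValueError(f"{path}: duplicate tree_id {dup!r}")
    return frame


def read_taper(path) -> pd.DataFrame:
    return _read_validated(path, "taper")


def read_biomass(path) -> pd.DataFrame:
    frame = _read_validated(path, "biomass")
    mismatch = ~np.isclose(
        frame["agb_kg"],
        frame[["stem_kg", "branch_kg", "foliage_kg"]].sum(axis=1),
        rtol=1e-6,
    )
    if mismatch.any():
        rows = (frame.index[mismatch] + 2).tolist()[:5]
        raise ValueError(
            f"{path}: agb_kg must equal stem+branch+foliage; file row(s) {rows}"
        )
    return frame


def write_table(frame: pd.DataFrame, path) -> Path:
    """Write a result CSV with a fixed float format (deterministic bytes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


@dataclass
class PipelineConfig:
    """Inputs, stages and knobs of one pipeline run.

    Exactly one of (``trees_csv``+``taper_csv``+``biomass_csv``) or
    ``simulation`` must be supplied.
    """

    out_dir: str | Path
    trees_csv: str | Path | None = None
    taper_csv: str | Path | None = None
    biomass_csv: str | Path | None = None
    simulation: SimulationConfig | None = None
    taper_models: tuple[str, ...] = ("kozak1988", "kozakI2004", "kozakII2004")
    selected_taper_model: str = "kozakII2004"
    allometry_grid: tuple = DEFAULT_PREDICTOR_GRID
    nsur_predictors: dict[str, float] | None = None  # component -> rel height; None = scan pick
    run_crossval: bool = True
    crossval_taper: bool = False   # n taper refits; opt-in
    seed: int = 0

    def validate(self) -> None:
        paths = (self.trees_csv, self.taper_csv, self.biomass_csv)
        have_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if self.simulation is None and not have_paths:
            raise ValueError(
                "supply either all three input CSVs or a simulation config"
                + ("; input file list is incomplete" if some_paths else "")
            )
        if self.simulation is not None and some_paths:
            raise ValueError("supply input CSVs or a simulation config, not both")
        if self.selected_taper_model not in MODEL_N_PARAMS:
            raise ValueError(f"unknown taper model {self.selected_taper_model!r}")
        for p in paths:
            if p is not None and not Path(p).is_file():
                raise ValueError(f"input file not found: {p}")


@dataclass
class RunReport:
    stages: dict[str, dict] = field(default_factory=dict)
    manifest: list[str] = field(default_factory=list)
    key_results: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"stages": self.stages, "manifest": self.manifest,
                "key_results": self.key_results}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute simulate/load -> fit-taper -> scan-allometry -> fit-NSUR -> CV.

    Each stage writes its tables into ``config.out_dir`` before the next
    starts, so partial output survives a failing stage.  Fully
    deterministic given the inputs and ``config.seed``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    def record(path: Path) -> None:
        report.manifest.append(path.name)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                report.stages[name] = {"status": "failed", "error": str(exc)}
                _write_report(report, out)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            report.stages[name] = {
                "status": "ok", "elapsed_s": round(time.perf_counter() - t0, 3)}
            return result
        return wrap

    # ---- stage: data ----------------------------------------------------
    def _data():
        if config.simulation is not None:
            sim = config.simulation
            if sim.seed != config.seed:
                from dataclasses import replace
                sim = replace(sim, seed=config.seed)
            trees, taper, biomass = simulate_stand(sim)
        else:
            trees = read_trees(config.trees_csv)
            taper = read_taper(config.taper_csv)
            biomass = read_biomass(config.biomass_csv)
        for name, frame in (("trees", trees), ("taper", taper), ("biomass", biomass)):
            record(write_table(frame, out / f"{name}.csv"))
        return trees, taper, biomass

    trees, taper_obs, biomass = stage("data")(_data)

    # ---- stage: taper fitting ------------------------------------------
    def _taper():
        joined = join_sections(trees, taper_obs)
        fits, coef_rows, gof_rows = {}, [], []
        for model_id in config.taper_models:
            fit = fit_taper(model_id, joined)
            fits[model_id] = fit
            for i, (est, se) in enumerate(zip(fit.params.b, fit.se)):
                coef_rows.append({"model_id": model_id, "parameter": f"b{i + 1}",
                                  "estimate": est, "se": se})
            gof_rows.append({"model_id": model_id, **fit.stats.as_dict(),
                             "converged": fit.converged})
        record(write_table(pd.DataFrame(coef_rows),
                                               out / "taper_fit.csv"))
        record(write_table(pd.DataFrame(gof_rows),
                                               out / "taper_gof.csv"))
        return fits

    taper_fits = stage("fit_taper")(_taper)
    selected_fit = taper_fits[config.selected_taper_model]

    # ---- stage: allometry scan -----------------------------------------
    def _scan():
        scan = scan_relative_heights(trees, selected_fit.params, biomass,
                                     grid=config.allometry_grid)
        record(write_table(scan, out / "allometry_scan.csv"))
        picks = select_nearest_to_theory(scan)
        record(write_table(picks, out / "allometry_selection.csv"))
        return scan, picks

    scan, picks = stage("scan_allometry")(_scan)

    # ---- stage: NSUR ----------------------------------------------------
    def _nsur():
        if config.nsur_predictors is not None:
            pred_rel = dict(config.nsur_predictors)
        else:
            pred_rel = {}
            for _, row in picks.iterrows():
                rh = row["rel_height"]
                pred_rel[row["component"]] = 0.5 if pd.isna(rh) else float(rh)
        dbh = trees["dbh_cm"].to_numpy(float)
        h = trees["height_m"].to_numpy(float)
        predictors = pd.DataFrame({
            f"D_{i:g}": np.asarray(diameter_at_relative_height(
                selected_fit.params, dbh, h, i), float)
            for i in sorted(set(pred_rel.values()))
        })
        spec = NSURSystemSpec(
            predictors={c: f"D_{i:g}" for c, i in pred_rel.items()})
        res = fit_nsur(biomass, predictors, spec)
        rows = []
        for comp in ("stem", "branch", "foliage"):
            (a, c), (se_a, se_c) = res.estimates[comp], res.se[comp]
            rows.append({"component": comp, "predictor": spec.predictors[comp],
                         "a": a, "se_a": se_a, "c": c, "se_c": se_c,
                         **res.stats[comp].as_dict()})
        rows.append({"component": "agb", "predictor": "sum", "a": np.nan,
                     "se_a": np.nan, "c": np.nan, "se_c": np.nan,
                     **res.stats["agb"].as_dict()})
        record(write_table(pd.DataFrame(rows),
                                               out / "nsur_fit.csv"))
        record(write_table(
            res.sigma.reset_index(names="component"), out / "nsur_sigma.csv"))
        obs_pred = predict_components(res, predictors)
        obs_pred.insert(0, "tree_id", trees["tree_id"].to_numpy())
        cal_rows = []
        for comp in ("stem", "branch", "foliage", "agb"):
            obs_pred[f"{comp}_obs"] = biomass[f"{comp}_kg"].to_numpy()
            # linear calibration of predicted on observed, per scatter panel
            x = obs_pred[f"{comp}_obs"].to_numpy()
            yv = obs_pred[comp].to_numpy()
            slope, intercept = np.polyfit(x, yv, 1)
            r = np.corrcoef(x, yv)[0, 1]
            cal_rows.append({"component": comp, "slope": slope,
                             "intercept": intercept, "r2": r * r})
        record(write_table(obs_pred, out / "nsur_predictions.csv"))
        record(write_table(pd.DataFrame(cal_rows), out / "calibration.csv"))
        return res, predictors, pred_rel

    nsur_res, nsur_predictors, pred_rel = stage("fit_nsur")(_nsur)

    # ---- stage: cross-validation ---------------------------------------
    if config.run_crossval:
        def _cv():
            from .allometry import fit_power_law
            records, stat_rows = [], []
            data = trees.merge(biomass, on="tree_id")
            dbh = data["dbh_cm"].to_numpy(float)
            h = data["height_m"].to_numpy(float)
            for comp, i_rel in pred_rel.items():
                data[f"_d_{comp}"] = np.asarray(diameter_at_relative_height(
                    selected_fit.params, dbh, h, i_rel), float)

                def fitter(train, _c=comp):
                    return fit_power_law(train[f"{_c}_kg"].to_numpy(),
                                         train[f"_d_{_c}"].to_numpy())

                def predict(model, test, _c=comp):
                    return model.a * test[f"_d_{_c}"].to_numpy() ** model.c

                cv = loocv(data, fitter, predict, y_col=f"{comp}_kg", n_params=2)
                rec = cv.records.copy()
                rec.insert(1, "tag", comp)
                records.append(rec)
                stat_rows.append({"tag": comp, **cv.stats.as_dict(),
                                  "failed_folds": len(cv.failed_folds)})
            if config.crossval_taper:
                joined = join_sections(trees, taper_obs)

                def t_fitter(train):
                    return fit_taper(config.selected_taper_model, train)

                def t_predict(model, test):
                    return predict_diameter(model.params,
                                            test["dbh_cm"].to_numpy(),
                                            test["height_m"].to_numpy(),
                                            test["rel_height"].to_numpy())

                cv = loocv(joined, t_fitter, t_predict, y_col="diameter_cm",
                           n_params=MODEL_N_PARAMS[config.selected_taper_model])
                rec = cv.records.copy()
                rec.insert(1, "tag", config.selected_taper_model)
                records.append(rec)
                stat_rows.append({"tag": config.selected_taper_model,
                                  **cv.stats.as_dict(),
                                  "failed_folds": len(cv.failed_folds)})
            record(write_table(pd.concat(records),
                                                   out / "cv_records.csv"))
            record(write_table(pd.DataFrame(stat_rows),
                                                   out / "cv_stats.csv"))
        stage("crossval")(_cv)

    # ---- key results + report ------------------------------------------
    key = {"selected_taper_model": config.selected_taper_model,
           "taper_r2_adj": selected_fit.stats.r2_adj,
           "components": {}}
    for _, row in picks.iterrows():
        comp = row["component"]
        key["components"][comp] = {
            "selected_predictor": row["predictor"],
            "nls_exponent": row["c"],
            "theory": row["theory"],
            "theory_value": row["theory_value"],
            "theory_contained": bool(row["contained"]),
            "nsur_exponent": nsur_res.estimates[comp][1],
        }
    report.key_results = key
    _write_report(report, out)
    return report


def _write_report(report: RunReport, out: Path) -> None:
    path = out / "report.json"
    path.write_text(json.dumps(report.as_dict(), indent=2, sort_keys=True))
    if path.name not in report.manifest:
        report.manifest.append(path.name)
    lines = ["pipeline run summary", "===================="]
    for name, info in report.stages.items():
        lines.append(f"{name}: {info.get('status')}")
    for comp, info in report.key_results.get("components", {}).items():
        lines.append(
            f"{comp}: predictor {info['selected_predictor']}, "
            f"NLS c = {info['nls_exponent']:.4f}, NSUR c = {info['nsur_exponent']:.4f}, "
            f"theory {info['theory']} ({info['theory_value']:.4f}) "
            f"{'inside' if info['theory_contained'] else 'outside'} the 95% CI"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
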