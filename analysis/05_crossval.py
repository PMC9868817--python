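#!/usr/bin/env python
"""Leave-one-tree-out cross-validation of the biomass and taper models.

Each fold drops one tree entirely (all of its section and biomass
records), refits, and predicts the held-out tree.  Held-out statistics
are compared with in-sample ones to quantify optimism.  The taper CV
refits the 9-parameter Kozak II model once per tree and is run on a
40-tree subsample to keep the driver quick.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from larchbiomass import fit_power_law, fit_statistics, loocv
from larchbiomass.pipeline import read_biomass, read_taper, read_trees, write_table
from larchbiomass.taper import (TaperParameterSet, diameter_at_relative_height,
                                fit_taper, join_sections, predict_diameter)

BASE = Path(__file__).resolve().parent.parent / "results"
trees = read_trees(BASE / "stand" / "trees.csv")
taper = read_taper(BASE / "stand" / "taper.csv")
biomass = read_biomass(BASE / "stand" / "biomass.csv")

coef = pd.read_csv(BASE / "taper_fit.csv").query("model_id == 'kozakII2004'")
coef = coef.assign(idx=coef.parameter.str.lstrip("b").astype(int)).sort_values("idx")
taper_params = TaperParameterSet("kozakII2004", tuple(coef["estimate"]))

stat_rows, all_records = [], []

# --- biomass components: full 114-tree LOOCV -----------------------------
data = trees.merge(biomass, on="tree_id")
dbh, h = data["dbh_cm"].to_numpy(), data["height_m"].to_numpy()
for comp, i_rel in (("stem", 0.2), ("branch", 0.5), ("foliage", 0.5)):
    data[f"_d_{comp}"] = np.asarray(
        diameter_at_relative_height(taper_params, dbh, h, i_rel), float)

    def fitter(train, _c=comp):
        return fit_power_law(train[f"{_c}_kg"].to_numpy(),
                             train[f"_d_{_c}"].to_numpy())

    def predict(model, test, _c=comp):
        return model.a * test[f"_d_{_c}"].to_numpy() ** model.c

    cv = loocv(data, fitter, predict, y_col=f"{comp}_kg", n_params=2)
    model = fitter(data)
    ins = fit_statistics(data[f"{comp}_kg"], predict(model, data), 2)
    rec = cv.records.copy(); rec.insert(1, "tag", comp); all_records.append(rec)
    stat_rows.append({"tag": comp, "phase": "heldout", **cv.stats.as_dict()})
    stat_rows.append({"tag": comp, "phase": "in_sample", **ins.as_dict()})
    print(f"{comp:8s} held-out MAB={cv.stats.mab:.3f} RMSE={cv.stats.rmse:.3f} "
          f"MPB={cv.stats.mpb:.2f}% | in-sample RMSE={ins.rmse:.3f}")

# --- taper: LOOCV on a 40-tree subsample ---------------------------------
sub_ids = trees["tree_id"].iloc[:40]
joined = join_sections(trees[trees.tree_id.isin(sub_ids)],
                       taper[taper.tree_id.isin(sub_ids)])

cv = loocv(
    joined,
    lambda train: fit_taper("kozakII2004", train),
    lambda model, test: predict_diameter(model.params,
                                         test["dbh_cm"].to_numpy(),
                                         test["height_m"].to_numpy(),
                                         test["rel_height"].to_numpy()),
    y_col="diameter_cm", n_params=9)
rec = cv.records.copy(); rec.insert(1, "tag", "kozakII2004"); all_records.append(rec)
stat_rows.append({"tag": "kozakII2004", "phase": "heldout", **cv.stats.as_dict()})
print(f"taper    held-out (40 trees) MAB={cv.stats.mab:.3f} cm "
      f"RMSE={cv.stats.rmse:.3f} cm MPB={cv.stats.mpb:.2f}% "
      f"({len(cv.failed_folds)} failed folds)")

write_table(pd.concat(all_records), BASE / "cv_records.csv")
write_table(pd.DataFrame(stat_rows), BASE / "cv_stats.csv")
print(f"tables -> {BASE / 'cv_records.csv'}, {BASE / 'cv_stats.csv'}")
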