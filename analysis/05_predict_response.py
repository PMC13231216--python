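"""Response-prediction modelling on the synthetic cohort.

Runs the full statistical chain on the cohort from 01_simulate_inputs.py:
stratified 7:3 split, univariable screen (p < .05), VIF collinearity
exclusion, single-predictor and combined logistic models, ROC with
bootstrap CIs, DeLong comparisons, Youden cutoffs, Hosmer-Lemeshow
calibration, decision curves, fivefold cross-validation, subgroup AUCs,
histology correlations and the design-stage AUC sample size.
Writes results/prediction/ tables.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from tddmri.prediction import (
    auc_mann_whitney,
    build_design,
    collinearity_screen,
    decision_curve,
    delong_test,
    hosmer_lemeshow,
    kfold_cv,
    multivariable_logistic,
    pearson_correlation,
    precision_recall_curve,
    roc_auc,
    sample_size_auc,
    stratified_split,
    subgroup_eval,
    univariable_logistic,
    youden_cutoff,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "prediction"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20240901

cohort = pd.read_csv(ROOT / "inputs" / "cohort.csv")
split = stratified_split(cohort, 0.7, seed=SEED)
train = cohort[split == "training"].reset_index(drop=True)
test = cohort[split == "test"].reset_index(drop=True)
print(f"split: {len(train)} training ({int(train.response.sum())} responders) / "
      f"{len(test)} test")

# -- univariable screen ------------------------------------------------------
CANDIDATES = ["age", "sex", "t_stage", "n_stage", "ajcc_stage", "ebv_dna",
              "tumor_volume_cm3", "ki67", "tsr", "chemo_cycles",
              "adc_pgse", "adc_20hz", "adc_40hz", "radc",
              "f_in", "d", "cellularity", "D_ex"]
uni_rows, screened = [], []
for var in CANDIDATES:
    rep = univariable_logistic(train, var)
    for term, row in rep.terms.iterrows():
        uni_rows.append({"predictor": var, "term": term, **row.to_dict()})
    if (rep.terms["p"] < 0.05).any():
        screened.append(var)
pd.DataFrame(uni_rows).to_csv(OUT / "univariable.csv", index=False)
print(f"univariable screen (p<.05): {screened}")

if len(screened) >= 2:
    retained, excl = collinearity_screen(train, screened)
    for e in excl:
        print(f"collinearity exclusion: {e['excluded']} ({e['reason']})")
else:
    retained = screened

# -- the three study models --------------------------------------------------
models = {"tsr": ["tsr"], "cellularity": ["cellularity"],
          "combined": ["tsr", "cellularity"]}
scores_train, scores_test, rows = {}, {}, []
for name, preds in models.items():
    rep = multivariable_logistic(train, preds)
    scores_train[name] = rep.probabilities
    Xte, _ = build_design(test, preds)
    Xte = Xte.reindex(columns=rep.design_columns, fill_value=0.0)
    eta = rep.intercept + Xte.to_numpy() @ rep.terms["beta"].to_numpy()
    scores_test[name] = 1 / (1 + np.exp(-eta))
    auc_tr, ci_tr = roc_auc(scores_train[name], train.response,
                            n_boot=1000, seed=SEED + 1)
    yj = youden_cutoff(scores_train[name], train.response)
    rows.append({"model": name, "set": "training", "auc": auc_tr,
                 "auc_lo": ci_tr[0], "auc_hi": ci_tr[1],
                 "sens": yj["sensitivity"]["value"],
                 "spec": yj["specificity"]["value"],
                 "ppv": yj["ppv"]["value"], "npv": yj["npv"]["value"]})
auc_te, ci_te = roc_auc(scores_test["combined"], test.response,
                        n_boot=1000, seed=SEED + 2)
yj_te = youden_cutoff(scores_test["combined"], test.response)
rows.append({"model": "combined", "set": "test", "auc": auc_te,
             "auc_lo": ci_te[0], "auc_hi": ci_te[1],
             "sens": yj_te["sensitivity"]["value"],
             "spec": yj_te["specificity"]["value"],
             "ppv": yj_te["ppv"]["value"], "npv": yj_te["npv"]["value"]})
perf = pd.DataFrame(rows)
perf.to_csv(OUT / "model_performance.csv", index=False)
print("\n" + perf.round(3).to_string(index=False))

for single in ("tsr", "cellularity"):
    z, p = delong_test(scores_train["combined"], scores_train[single],
                       train.response)
    print(f"DeLong combined vs {single}: z={z:+.2f}, p={p:.3f}")

stat, p_hl, _ = hosmer_lemeshow(scores_train["combined"], train.response)
print(f"Hosmer-Lemeshow (training, combined): chi2={stat:.2f}, p={p_hl:.2f}")

decision_curve(scores_train["combined"], train.response).to_csv(
    OUT / "decision_curve.csv", index=False)
precision_recall_curve(scores_train["combined"], train.response).to_csv(
    OUT / "pr_curve.csv", index=False)

cv = kfold_cv(cohort, ["tsr", "cellularity"], k=5, seed=SEED + 3)
print(f"fivefold CV (combined): mean AUC {cv['mean_auc']:.3f} "
      f"± {cv['sd_auc']:.3f}")

sub = subgroup_eval(train, scores_train["combined"], "response",
                    ["sex", "ajcc_stage", "ebv_dna"])
sub.to_csv(OUT / "subgroup_auc.csv", index=False)
print("subgroup AUC range:",
      f"{sub.auc.min():.2f}-{sub.auc.max():.2f}")

# -- histology correlations and design aid -----------------------------------
pairs = pd.read_csv(ROOT / "inputs" / "histology_pairs.csv")
corr = {m: pearson_correlation(pairs[f"imaging_{m}"], pairs[f"histology_{m}"])
        for m in ("d", "cellularity", "f_in")}
print("imaging-histology Pearson r:",
      {m: round(v[0], 2) for m, v in corr.items()})

n_req = sample_size_auc(0.50, 0.75, 0.70, alpha=0.05, power=0.90)
print(f"design-stage minimum sample size (AUC 0.50 vs 0.75, 70/30, "
      f"power 90%): n={n_req}")

summary = {
    "screened": screened, "retained": retained,
    "train_auc": {m: float(auc_mann_whitney(s, train.response))
                  for m, s in scores_train.items()},
    "test_auc_combined": float(auc_te),
    "cv_mean_auc": cv["mean_auc"],
    "hosmer_lemeshow_p": float(p_hl),
    "histology_r": {m: float(v[0]) for m, v in corr.items()},
    "sample_size": n_req,
}
(OUT / "summary.json").write_text(json.dumps(summary, indent=2))
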