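"""End-to-end orchestration: simulate → fit → repeatability → prediction.

``run_pipeline`` executes the stages named in a :class:`~tddmri.io.RunConfig`
and writes a manifest (inputs, seeds, package version, SHA-256 of every
artifact) so identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import agreement_report, dice, icc
from .fitting import FitConfig, fit_maps
from .io import RunConfig, sha256_file, write_volume
from .prediction import (
    collinearity_screen,
    decision_curve,
    hosmer_lemeshow,
    kfold_cv,
    multivariable_logistic,
    roc_auc,
    stratified_split,
    subgroup_eval,
    univariable_logistic,
    youden_cutoff,
)
from .scheme import AcquisitionScheme, default_scheme
from .simulate import (
    PhantomSpec,
    generate_cohort,
    generate_histology_pairs,
    generate_phantom,
    generate_reader_masks,
    generate_test_retest,
)

logger = logging.getLogger(__name__)

IMAGING_PREDICTORS = [
    "adc_pgse", "adc_20hz", "adc_40hz", "radc", "f_in", "d", "cellularity", "D_ex",
]
CLINICAL_PREDICTORS = [
    "age", "sex", "t_stage", "n_stage", "ajcc_stage", "ebv_dna",
    "tumor_volume_cm3", "ki67", "tsr", "chemo_cycles",
]


def _stage_simulate(cfg: RunConfig, out: Path, scheme) -> dict:
    files = {}
    if "phantom" in cfg:
        p = cfg["phantom"]
        spec = PhantomSpec(
            shape=tuple(p.get("shape", (16, 16, 16))),
            snr=p.get("snr", 50.0),
            semiaxes_mm=tuple(p.get("semiaxes_mm", (10.0, 8.0, 7.0))),
            regions={
                int(k): v
                for k, v in p.get(
                    "regions", {1: {"d": 14.0, "f_in": 0.35, "D_ex": 2.0}}
                ).items()
            },
            seed=p["seed"],
        )
        vols, truth, mask = generate_phantom(spec, scheme)
        write_volume(out / "phantom_signals.nii", vols)
        write_volume(out / "phantom_mask.nii", mask)
        for k, v in truth.items():
            write_volume(out / f"phantom_truth_{k}.nii", v)
        files["phantom"] = ["phantom_signals.nii", "phantom_mask.nii"] + [
            f"phantom_truth_{k}.nii" for k in truth
        ]
        if "reader_masks" in cfg:
            r = cfg["reader_masks"]
            m2 = generate_reader_masks(mask, r.get("target_dice", 0.82), seed=r["seed"])
            write_volume(out / "phantom_mask_reader2.nii", m2)
            files["reader_masks"] = ["phantom_mask_reader2.nii"]
    if "cohort" in cfg:
        c = cfg["cohort"]
        coh = generate_cohort(
            n=c.get("n", 220),
            responder_fraction=c.get("responder_fraction", 151.0 / 220.0),
            effect_scale=c.get("effect_scale", 1.0),
            seed=c["seed"],
        )
        coh.to_csv(out / "cohort.csv", index=False)
        files["cohort"] = ["cohort.csv"]
        hist = generate_histology_pairs(coh, seed=c["seed"] + 1)
        hist.to_csv(out / "histology_pairs.csv", index=False)
        files["histology"] = ["histology_pairs.csv"]
    if "test_retest" in cfg:
        t = cfg["test_retest"]
        df = generate_test_retest(
            n_subjects=t.get("n_subjects", 54),
            mean=t.get("mean", 2.4),
            between_cv=t.get("between_cv", 0.20),
            within_cv=t.get("within_cv", 0.09),
            seed=t["seed"],
        )
        df.to_csv(out / "test_retest.csv", index=False)
        files["test_retest"] = ["test_retest.csv"]
    return files


def _stage_fit(cfg: RunConfig, out: Path, scheme) -> dict:
    from .io import read_mask, read_volume

    vols, aff = read_volume(out / "phantom_signals.nii")
    mask, aff_m = read_mask(out / "phantom_mask.nii")
    from .io import check_same_grid

    check_same_grid(vols.shape[:-1], aff, mask.shape, aff_m)
    fit_cfg = FitConfig(**cfg.get("fit", {}).get("config", {}))
    maps, voi = fit_maps(vols, mask, scheme, fit_cfg)
    for k, v in maps.items():
        write_volume(out / f"map_{k}.nii", v, aff)
    pd.DataFrame([{"n_voxels": voi.n_voxels, **voi.means}]).to_csv(
        out / "voi_summary.csv", index=False
    )
    return {"fit": [f"map_{k}.nii" for k in maps] + ["voi_summary.csv"]}


def _stage_repro(cfg: RunConfig, out: Path) -> dict:
    df = pd.read_csv(out / "test_retest.csv")
    rep = agreement_report(df["value1"], df["value2"], metric=str(df["metric"].iloc[0]))
    icc_val, icc_ci, degenerate = icc(df[["value1", "value2"]].to_numpy())
    report = {**asdict(rep), "icc": icc_val, "icc_ci": icc_ci,
              "icc_degenerate": degenerate}
    if (out / "phantom_mask_reader2.nii").exists():
        from .io import read_mask

        m1, _ = read_mask(out / "phantom_mask.nii")
        m2, _ = read_mask(out / "phantom_mask_reader2.nii")
        report["reader_dice"] = dice(m1, m2)
    (out / "repro_report.json").write_text(json.dumps(report, indent=2))
    return {"repro": ["repro_report.json"]}


def _stage_predict(cfg: RunConfig, out: Path) -> dict:
    coh = pd.read_csv(out / "cohort.csv")
    p = cfg.get("predict", {})
    split = stratified_split(
        coh, ratio=p.get("ratio", 0.7), seed=cfg["split"]["seed"]
    )
    train = coh[split == "training"].reset_index(drop=True)
    test = coh[split == "test"].reset_index(drop=True)

    candidates = [c for c in CLINICAL_PREDICTORS + IMAGING_PREDICTORS if c in coh]
    uni_rows, screened = [], []
    for var in candidates:
        rep = univariable_logistic(train, var)
        for term, row in rep.terms.iterrows():
            uni_rows.append({"predictor": var, "term": term, **row.to_dict()})
        if (rep.terms["p"] < 0.05).any():
            screened.append(var)
    pd.DataFrame(uni_rows).to_csv(out / "univariable.csv", index=False)
    if len(screened) >= 2:
        retained, excl = collinearity_screen(train, screened)
    else:
        retained, excl = screened, []

    results = {"screened": screened, "collinearity_excluded": excl,
               "retained": retained}
    if retained:
        multi = multivariable_logistic(train, retained)
        multi.terms.to_csv(out / "multivariable.csv")
        n_boot = p.get("n_boot", 1000)
        auc_tr, ci_tr = roc_auc(
            multi.probabilities, train["response"], n_boot=n_boot,
            seed=cfg["split"]["seed"] + 1,
        )
        from .prediction import build_design

        Xte, _ = build_design(test, retained)
        Xte = Xte.reindex(columns=multi.design_columns, fill_value=0.0)
        eta_te = multi.intercept + Xte.to_numpy() @ multi.terms["beta"].to_numpy()
        p_te = 1.0 / (1.0 + np.exp(-eta_te))
        auc_te, ci_te = roc_auc(
            p_te, test["response"], n_boot=n_boot, seed=cfg["split"]["seed"] + 2
        )
        yj = youden_cutoff(multi.probabilities, train["response"])
        hl_tr = hosmer_lemeshow(multi.probabilities, train["response"])
        decision_curve(multi.probabilities, train["response"]).to_csv(
            out / "decision_curve_training.csv", index=False
        )
        cv = kfold_cv(coh, retained, k=p.get("k", 5), seed=cfg["split"]["seed"] + 3)
        sub = subgroup_eval(
            train, multi.probabilities, "response",
            [v for v in ("sex", "ajcc_stage", "ebv_dna") if v in train],
        )
        sub.to_csv(out / "subgroup_auc.csv", index=False)
        results.update(
            {
                "train_auc": auc_tr, "train_auc_ci": ci_tr,
                "test_auc": auc_te, "test_auc_ci": ci_te,
                "youden": yj,
                "hosmer_lemeshow_training": hl_tr,
                "cv_mean_auc": cv["mean_auc"], "cv_sd_auc": cv["sd_auc"],
            }
        )
    (out / "prediction_report.json").write_text(json.dumps(results, indent=2, default=float))
    files = ["univariable.csv", "prediction_report.json"]
    for f in ("multivariable.csv", "decision_curve_training.csv", "subgroup_auc.csv"):
        if (out / f).exists():
            files.append(f)
    return {"predict": files}


def run_pipeline(config: RunConfig | dict, out_dir) -> Path:
    """Run the configured stages and write a reproducibility manifest."""
    cfg = config if isinstance(config, RunConfig) else RunConfig(config)
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = (
        AcquisitionScheme.from_json(Path(cfg["scheme"]))
        if "scheme" in cfg
        else default_scheme()
    )
    scheme.to_json(out / "scheme.json")
    artifacts: dict = {"scheme": ["scheme.json"]}
    stages = [("simulate", lambda: _stage_simulate(cfg, out, scheme))]
    if "phantom" in cfg:
        stages.append(("fit", lambda: _stage_fit(cfg, out, scheme)))
    if "test_retest" in cfg:
        stages.append(("repro", lambda: _stage_repro(cfg, out)))
    if "cohort" in cfg and "split" in cfg:
        stages.append(("predict", lambda: _stage_predict(cfg, out)))
    for name, fn in stages:
        try:
            artifacts.update(fn())
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    manifest = {
        "version": __version__,
        "config": dict(cfg),
        "stages": {
            stage: {f: sha256_file(out / f) for f in files}
            for stage, files in artifacts.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
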