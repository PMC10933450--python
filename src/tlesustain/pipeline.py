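"""End-to-end pipeline: simulate/load -> z-score -> fit -> assign ->
characterize -> predict, driven by a declarative YAML/dict config.

Every stage logs its wall time; a failure aborts the run with the stage
name and cause.  All randomness derives from the single config seed, so a
fixed (config, seed) pair yields identical outputs across runs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_io, rois
from .fitting import (FitConfig, assign_individuals, fit_subtypes,
                      positional_variance, select_model_order)
from .prognosis import (ClassifierConfig, build_features, evaluate_pooled,
                        evaluate_stratified, permutation_test)
from .progression import build_event_set
from .subtype_stats import (clinical_compare, roiwise_group_comparison,
                            seizure_freedom_table, stage_atrophy_correlation)
from .synthcohort import (CohortConfig, make_ground_truth, simulate_cohort,
                          simulate_outcomes)
from .zscoring import compute_zscores, fit_normative, select_modeling_rois

__all__ = ["run_pipeline", "load_config", "DEFAULT_CONFIG", "PipelineError"]

log = logging.getLogger("tlesustain")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "tlesustain_out",
    "simulate": {"n_patients": 296, "n_controls": 81},
    "inputs": None,  # {"morphometry": path, "clinical": path} disables simulate
    "zscore": {"center_age": True},
    "modeling_rois": None,  # default: rois.MODELING_ROIS
    "thresholds": [1.0, 2.0, 3.0],
    "z_max": 5.0,
    "fit": {
        "k_range": [2, 3, 4],
        "n_folds": 3,
        "n_starts": 25,
        "n_iter_mcmc": 100_000,
        "k": None,  # fixed k skips CVIC selection
    },
    "predict": {
        "features": "clinical",  # or "clinical+mri"
        "n_folds": 10,
        "n_perm": None,  # e.g. 1000 enables the permutation test
        "fixed_kernel": None,
    },
}


class PipelineError(RuntimeError):
    pass


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _stage(name):
    def deco(fn):
        def wrapped(state, cfg):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                fn(state, cfg)
            except Exception as e:  # noqa: BLE001 - report stage and cause
                raise PipelineError(f"stage {name!r} failed: {e}") from e
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
        wrapped.stage_name = name
        return wrapped
    return deco


@_stage("data")
def _stage_data(st, cfg):
    outdir = st["outdir"]
    if cfg.get("inputs"):
        st["morph"] = cohort_io.read_morphometry(cfg["inputs"]["morphometry"])
        st["clin"] = cohort_io.read_clinical(cfg["inputs"]["clinical"])
    else:
        sim = cfg["simulate"]
        gt = make_ground_truth(CohortConfig(), seed=cfg["seed"])
        morph, clin = simulate_cohort(gt, sim["n_patients"], sim["n_controls"],
                                      seed=cfg["seed"] + 1)
        clin = simulate_outcomes(gt, clin, seed=cfg["seed"] + 2)
        st["morph"], st["clin"], st["gt"] = morph, clin, gt
        cohort_io.write_table(morph, outdir / "morphometry.csv")
        cohort_io.write_table(clin, outdir / "clinical.csv")
        gt.subject_truth.to_csv(outdir / "ground_truth.csv", index=False)


@_stage("zscore")
def _stage_zscore(st, cfg):
    morph = st["morph"]
    controls = morph[morph["group"] == "control"]
    patients = morph[morph["group"] == "patient"]
    st["normative"] = fit_normative(controls,
                                    center_age=cfg["zscore"]["center_age"])
    st["Z_full"] = compute_zscores(st["normative"], patients)
    roi_list = cfg["modeling_rois"] or [r for r in rois.MODELING_ROIS
                                        if r in st["Z_full"].rois]
    st["Z_model"] = select_modeling_rois(st["Z_full"], roi_list)
    cohort_io.write_zscores(st["Z_full"], st["outdir"] / "zscores.csv")


@_stage("fit")
def _stage_fit(st, cfg):
    f = cfg["fit"]
    es = build_event_set(st["Z_model"].rois, tuple(cfg["thresholds"]),
                         cfg["z_max"])
    fit_cfg = FitConfig(n_starts=f["n_starts"], n_iter_mcmc=f["n_iter_mcmc"])
    Z = st["Z_model"].values
    if f.get("k"):
        k = int(f["k"])
    elif len(f["k_range"]) == 1:
        k = int(f["k_range"][0])
    else:
        report = select_model_order(Z, es, f["k_range"], f["n_folds"],
                                    seed=cfg["seed"] + 3, config=fit_cfg)
        k = report.selected_k
        pd.DataFrame({"k": report.k_values, "cvic": report.cvic,
                      "mean_oos_loglik": report.mean_oos_loglik}).to_csv(
            st["outdir"] / "cvic.csv", index=False)
        log.info("CVIC selected k=%d", k)
    st["model"] = fit_subtypes(Z, es, k, fit_cfg, seed=cfg["seed"] + 4)
    cohort_io.save_artifact(
        st["outdir"] / "model.json",
        subtype_model=st["model"], normative_model=st["normative"],
        metadata={"seed": cfg["seed"], "k": k,
                  "n_starts": f["n_starts"], "n_iter_mcmc": f["n_iter_mcmc"],
                  "features": list(st["Z_model"].rois)})
    for c in range(st["model"].n_subtypes):
        pvd = positional_variance(st["model"].mcmc, c)
        np.savetxt(st["outdir"] / f"positional_variance_subtype{c + 1}.csv",
                   pvd, delimiter=",")


@_stage("assign")
def _stage_assign(st, cfg):
    st["assign"] = assign_individuals(st["model"], st["Z_model"].values,
                                      subject_ids=st["Z_model"].subject_ids)
    st["assign"].table.to_csv(st["outdir"] / "assignments.csv")


@_stage("characterize")
def _stage_characterize(st, cfg):
    assign, clin = st["assign"], st["clin"]
    labels = assign.table.loc[clin["subject_id"], "label"]
    labels.index = clin.index
    rho = stage_atrophy_correlation(assign, st["Z_model"])
    rho.to_csv(st["outdir"] / "stage_atrophy_correlation.csv", index=False)
    drop = [c for c in ("subject_id", "outcome", "treatment_arm")
            if c in clin.columns]
    comp = clinical_compare(clin.drop(columns=drop), labels)
    comp.to_csv(st["outdir"] / "clinical_comparisons.csv", index=False)
    if "outcome" in clin.columns:
        tabs = [seizure_freedom_table(clin, labels, arm)
                for arm in sorted(clin["treatment_arm"].dropna().unique())]
        pd.concat(tabs).to_csv(st["outdir"] / "seizure_freedom.csv",
                               index=False)


@_stage("predict")
def _stage_predict(st, cfg):
    p = cfg["predict"]
    clin, assign = st["clin"], st["assign"]
    m = (clin["treatment_arm"] == "OG") & \
        clin["outcome"].isin(["effective", "ineffective"])
    sub = clin[m]
    Z = st["Z_full"].subset(sub["subject_id"]) \
        if p["features"] == "clinical+mri" else None
    X = build_features(sub, Z)
    y = (sub["outcome"] == "effective").astype(int).to_numpy()
    subtypes = assign.table.loc[sub["subject_id"], "label"].to_numpy()
    ccfg = ClassifierConfig(n_folds=p["n_folds"],
                            fixed_kernel=p["fixed_kernel"])
    strat = evaluate_stratified(X, y, subtypes, ccfg, seed=cfg["seed"] + 5)
    pooled = evaluate_pooled(X, y, ccfg, seed=cfg["seed"] + 5)
    report = {}
    for name, rep in (("stratified", strat), ("pooled", pooled)):
        report[name] = {
            "sensitivity": rep.sensitivity, "specificity": rep.specificity,
            "accuracy": rep.accuracy, "youden_j": rep.youden_j,
            "confusion": rep.confusion.tolist(),
            "per_subtype": rep.per_subtype,
        }
    if p["n_perm"]:
        pval, _, _ = permutation_test(X, y, subtypes, ccfg,
                                      n_perm=p["n_perm"],
                                      seed=cfg["seed"] + 6)
        report["stratified"]["permutation_p"] = pval
    (st["outdir"] / "prognosis.json").write_text(json.dumps(report, indent=2))
    st["prognosis"] = report


_STAGES = [_stage_data, _stage_zscore, _stage_fit, _stage_assign,
           _stage_characterize, _stage_predict]


def run_pipeline(config, outdir=None) -> dict:
    """Run all stages; returns the in-memory state (tables, models,
    assignments, reports) and writes the artifact directory."""
    cfg = load_config(config)
    if outdir is not None:
        cfg["outdir"] = str(outdir)
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    state = {"outdir": out}
    for stage in _STAGES:
        stage(state, cfg)
    return state
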