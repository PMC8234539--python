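"""End-to-end orchestration: simulate -> extract -> screen -> train ->
evaluate -> compare, as reproducible, manifest-logged runs.

A run trains on a synthetic primary cohort and evaluates on independently
seeded validation cohorts, mirroring a three-cohort design.  Every stage
is also callable on its own.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical_scores, dsnn, screening, survstats, synthdata
from .radiomics import extract_all

__all__ = [
    "default_config",
    "extract_features",
    "drc_combine",
    "evaluate_score",
    "run_all",
]

DEFAULT_HORIZON = 36.0  # months


def default_config(**overrides) -> dict:
    cfg = {
        "seed": 0,
        "n_primary": 200,
        "n_validation": (60, 60),
        "grid_shape": (16, 16, 16),
        "lesion_radius_range": (3.0, 6.0),
        "horizon": DEFAULT_HORIZON,
        "bins": 32,
        "dsnn": {},
    }
    cfg.update(overrides)
    return cfg


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def extract_features(cohort: synthdata.Cohort, n_bins: int = 32) -> pd.DataFrame:
    """Feature table (patients x named features) for a generated cohort."""
    rows = {}
    for p in cohort.patients:
        if p.image is None:
            raise ValueError(f"patient {p.id} has no image")
        rows[p.id] = extract_all(p.image, n_bins=n_bins)
    return pd.DataFrame.from_dict(rows, orient="index")


def _cohort_config(cfg: dict, n: int, seed: int) -> synthdata.CohortConfig:
    return synthdata.CohortConfig(
        n_patients=n,
        grid_shape=tuple(cfg["grid_shape"]),
        lesion_radius_range=tuple(cfg["lesion_radius_range"]),
        seed=seed,
    )


def evaluate_score(score, time, event, horizon: float = DEFAULT_HORIZON,
                   n_boot: int = 500, seed: int = 0,
                   km_cutoff: float | None = None) -> dict:
    """Evaluation battery for one risk score on one cohort."""
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)

    c, lo, hi = survstats.cindex_ci(score, time, event, n_boot=n_boot,
                                    seed=seed)
    roc = survstats.time_roc(score, time, event, horizon)
    cutoff = km_cutoff if km_cutoff is not None else roc.youden_cutoff
    group = (score > cutoff).astype(int)
    if len(np.unique(group)) == 2:
        chi2, df, logrank_p = survstats.log_rank(time, event, group)
    else:
        chi2, df, logrank_p = float("nan"), 1, float("nan")

    prob = survstats.risk_to_prob(score, time, event, horizon)
    try:
        _, hl_chi2, hl_p = survstats.calibration_3yr(prob, time, event,
                                                     horizon=horizon)
    except ValueError:
        hl_chi2, hl_p = float("nan"), float("nan")
    dca = survstats.decision_curve(prob, time, event, horizon,
                                   np.arange(0.05, 0.70, 0.05))
    fit = survstats.fit_cox(score[:, None], time, event, names=["score"])
    return {
        "c_index": c, "c_ci": [lo, hi],
        "auc_t": roc.auc, "youden_cutoff": roc.youden_cutoff,
        "logrank_chi2": chi2, "logrank_p": logrank_p,
        "hl_chi2": hl_chi2, "hl_p": hl_p,
        "hr": float(fit.hr[0]), "hr_p": float(fit.p[0]),
        "net_benefit": dca["net_benefit"].tolist(),
        "km_cutoff": float(cutoff),
    }


def drc_combine(drs_scores, clinical_records: pd.DataFrame, time, event):
    """Cox combination of the deep score with prognostic clinical factors.

    Clinical covariates (point-coded signature matrix) are kept when their
    univariate Cox p < 0.05; the deep score always enters.  Returns
    ``(CoxFit, combined_scores)``.
    """
    drs = np.asarray(drs_scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = clinical_scores._signature_matrix(clinical_records, "combine")

    keep = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = survstats.fit_cox(v[:, None], time, event)
        if fit.p[0] < 0.05:
            keep.append(col)

    if np.ptp(drs) == 0:
        cols = X[keep].to_numpy(dtype=float)
        names = keep
    else:
        cols = np.column_stack([drs] + [X[c].to_numpy(dtype=float)
                                        for c in keep])
        names = ["drs"] + keep
    fit = survstats.fit_cox(cols, time, event, names=names)
    return fit, fit.linear_predictor(cols)


def run_all(cfg: dict | None = None, out_dir=None) -> dict:
    """Execute the full pipeline on synthetic cohorts.

    Returns the evaluation report; when ``out_dir`` is given, writes the
    report JSON, the feature/screen tables and a run manifest.
    """
    cfg = default_config() if cfg is None else {**default_config(), **cfg}
    seed = int(cfg["seed"])
    horizon = float(cfg["horizon"])
    t0 = _time.time()
    stages_done = []
    try:
        # --- simulate ---------------------------------------------------
        cohorts = {"PC": synthdata.generate_cohort(
            _cohort_config(cfg, cfg["n_primary"], seed))}
        for k, n in enumerate(cfg["n_validation"]):
            cohorts[f"VC{k + 1}"] = synthdata.generate_cohort(
                _cohort_config(cfg, n, seed + 1000 * (k + 1)))
        stages_done.append("simulate")

        # --- extract ----------------------------------------------------
        features = {name: extract_features(c, n_bins=cfg["bins"])
                    for name, c in cohorts.items()}
        stages_done.append("extract")

        # --- screen (on the primary cohort only) ------------------------
        pc = cohorts["PC"]
        results = screening.screen(features["PC"], pc.time, pc.event)
        selected = [r.feature_name for r in results if r.selected]
        if len(selected) < 2:  # degenerate screen on tiny runs
            ranked = sorted(results, key=lambda r: -r.c_index)
            selected = [r.feature_name for r in ranked[:10]]
        stages_done.append("screen")

        # --- train ------------------------------------------------------
        ds_cfg = dsnn.DSNNConfig(seed=seed, **cfg["dsnn"])
        model, log = dsnn.train(features["PC"][selected], pc.time, pc.event,
                                ds_cfg)
        stages_done.append("train")

        # --- evaluate ---------------------------------------------------
        report = {"config_hash": _config_hash(cfg), "seed": seed,
                  "selected_features": len(selected), "cohorts": {}}
        scores = {}
        for name, cohort in cohorts.items():
            s = dsnn.predict_risk(model, features[name][selected])
            scores[name] = s
            report["cohorts"][name] = {
                "n": len(cohort.patients),
                "events": int(cohort.event.sum()),
                "drs": evaluate_score(s, cohort.time, cohort.event,
                                      horizon=horizon, seed=seed),
            }
        stages_done.append("evaluate")

        # --- compare ----------------------------------------------------
        for name, cohort in cohorts.items():
            clin = pd.DataFrame([p.clinical for p in cohort.patients])
            comp = {}
            sf = clinical_scores.score_frame(clin)
            for sys_name, col in [("CAPRA", "capra"), ("CAPRA-S", "capra_s"),
                                  ("NCCN", "nccn"),
                                  ("GG-RP", "gg_rp_group")]:
                try:
                    comp[sys_name] = _system_summary(
                        sf[col].to_numpy(float), scores[name],
                        cohort.time, cohort.event)
                except ValueError as exc:
                    comp[sys_name] = {"error": str(exc)}
            for which in ("pre", "post", "combine"):
                try:
                    _, cs = clinical_scores.clinical_signature(
                        clin, cohort.time, cohort.event, which)
                    comp[f"CS-{which}"] = _system_summary(
                        cs, scores[name], cohort.time, cohort.event)
                except ValueError as exc:
                    comp[f"CS-{which}"] = {"error": str(exc)}
            try:
                drc_fit, drc = drc_combine(scores[name], clin,
                                           cohort.time, cohort.event)
                comp["DRC-BCR"] = _system_summary(
                    drc, scores[name], cohort.time, cohort.event)
            except ValueError as exc:
                comp["DRC-BCR"] = {"error": str(exc)}
            report["cohorts"][name]["comparators"] = comp
        stages_done.append("compare")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed after stages {stages_done}: {exc}"
        ) from exc

    report["runtime_s"] = round(_time.time() - t0, 2)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1))
        screening.results_frame(results).to_csv(out / "screen.csv",
                                                index=False)
        manifest = {
            "config": cfg, "config_hash": report["config_hash"],
            "seed": seed, "stages": stages_done,
            "outputs": ["report.json", "screen.csv"],
            "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str))
    return report


def _system_summary(system_score, drs_score, time, event) -> dict:
    """C-index of a comparator plus its paired test against the deep score."""
    c = screening.harrell_cindex(system_score, time, event)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = survstats.fit_cox(np.asarray(system_score, float)[:, None],
                                time, event)
    p_vs_drs = survstats.compare_cindex(np.asarray(drs_score, float),
                                        np.asarray(system_score, float),
                                        time, event)
    return {"c_index": float(c), "hr": float(fit.hr[0]),
            "hr_p": float(fit.p[0]), "p_vs_drs": float(p_vs_drs)}
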