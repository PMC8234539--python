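"""Comparator clinical risk systems and Cox-based clinical signatures.

CAPRA / CAPRA-S / NCCN point tables are published external knowledge and
ship as an editable JSON data file (``data/risk_tables.json``); the logic
here only performs lookups.  Gleason grading is accepted as grade groups
1-5 (GG2 = secondary pattern 4 -> 1 point; GG3+ = primary pattern 4/5 ->
3 points in both CAPRA systems).

Clinical signatures (CS-pre / CS-post / CS-combine) are Cox fits on the
point-coded covariate groups; the signature value is the linear
predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .survstats import CoxFit, fit_cox

__all__ = [
    "RiskAssignment",
    "load_tables",
    "capra",
    "capra_s",
    "nccn",
    "gg_rp_group",
    "capra_components",
    "capra_s_components",
    "clinical_signature",
    "PRE_COVARIATES",
    "POST_COVARIATES",
]

PRE_COVARIATES = ("psa", "ct", "gg_nb", "ppb")
POST_COVARIATES = ("gg_rp", "sm", "epe", "svi")


@dataclass
class RiskAssignment:
    system: str
    score: int
    category: str


def load_tables() -> dict:
    with resources.files("radsurv.data").joinpath(
            "risk_tables.json").open() as fh:
        return json.load(fh)


_TABLES = None


def _tables() -> dict:
    global _TABLES
    if _TABLES is None:
        _TABLES = load_tables()
    return _TABLES


def _bin_points(value: float, bins: list) -> int:
    for row in bins:
        if row["max"] is None or value <= row["max"]:
            return int(row["points"])
    raise ValueError(f"value {value} not covered by point table")


def _require(record: dict, system: str, fields) -> None:
    for f in fields:
        if f not in record or record[f] is None:
            raise ValueError(f"{system}: missing required field '{f}'")


def _category(score: int, bins: dict) -> str:
    if score <= bins["low_max"]:
        return "low"
    if score <= bins["intermediate_max"]:
        return "intermediate"
    return "high"


def capra_components(record: dict) -> dict:
    """Per-variable CAPRA points (preoperative)."""
    t = _tables()["capra"]
    _require(record, "CAPRA", ("psa", "gg_nb", "ct", "ppb", "age"))
    if record["psa"] <= 0:
        raise ValueError("CAPRA: psa must be positive")
    return {
        "psa": _bin_points(float(record["psa"]), t["psa_points"]),
        "gg_nb": t["gleason_group_points"][str(int(record["gg_nb"]))],
        "ct": t["ct_points"][str(int(record["ct"]))],
        "ppb": _bin_points(float(record["ppb"]), t["ppb_points"]),
        "age": _bin_points(float(record["age"]), t["age_points"]),
    }


def capra(record: dict) -> RiskAssignment:
    t = _tables()["capra"]
    score = sum(capra_components(record).values())
    return RiskAssignment("CAPRA", score, _category(score, t["risk_bins"]))


def capra_s_components(record: dict) -> dict:
    """Per-variable CAPRA-S points (postoperative)."""
    t = _tables()["capra_s"]
    _require(record, "CAPRA-S", ("psa", "gg_rp", "sm", "epe", "svi"))
    comps = {
        "psa": _bin_points(float(record["psa"]), t["psa_points"]),
        "gg_rp": t["gleason_group_points"][str(int(record["gg_rp"]))],
        "sm": t["sm_points"] * int(bool(record["sm"])),
        "epe": t["epe_points"] * int(bool(record["epe"])),
        "svi": t["svi_points"] * int(bool(record["svi"])),
    }
    # lymph-node status is optional in our cohorts; 0 when absent
    comps["ln"] = t["ln_points"] * int(bool(record.get("ln", 0)))
    return comps


def capra_s(record: dict) -> RiskAssignment:
    t = _tables()["capra_s"]
    score = sum(capra_s_components(record).values())
    return RiskAssignment("CAPRA-S", score, _category(score, t["risk_bins"]))


def nccn(record: dict) -> str:
    """Three-tier NCCN risk category (low / intermediate / high)."""
    t = _tables()["nccn"]
    _require(record, "NCCN", ("psa", "gg_nb", "ct"))
    psa, gg, ct = float(record["psa"]), int(record["gg_nb"]), int(record["ct"])
    h = t["high_any"]
    if ct >= h["ct_min"] or gg >= h["gg_min"] or psa > h["psa_min"]:
        return "high"
    lo = t["low"]
    if ct <= lo["ct_max"] and gg <= lo["gg_max"] and psa < lo["psa_max"]:
        return "low"
    return "intermediate"


def gg_rp_group(record: dict) -> int:
    _require(record, "GG-RP", ("gg_rp",))
    gg = int(record["gg_rp"])
    if not 1 <= gg <= 5:
        raise ValueError(f"GG-RP: grade group {gg} outside 1-5")
    return gg


_CATEGORY_ORDINAL = {"low": 0, "intermediate": 1, "high": 2}


def risk_ordinal(category: str) -> int:
    """Numeric coding of a risk category for concordance computations."""
    return _CATEGORY_ORDINAL[category]


# ---------------------------------------------------------------------------
# clinical signatures
# ---------------------------------------------------------------------------


def _signature_matrix(records: pd.DataFrame, which: str):
    """Point-coded covariate matrix for a signature group.

    Preoperative variables use CAPRA points except PSA which uses the
    CAPRA-S PSA bins; postoperative variables use CAPRA-S points.
    """
    caps = _tables()["capra_s"]
    cap = _tables()["capra"]
    cols = {}
    if which in ("pre", "combine"):
        cols["psa"] = [
            _bin_points(v, caps["psa_points"]) for v in records["psa"]]
        cols["ct"] = [cap["ct_points"][str(int(v))] for v in records["ct"]]
        cols["gg_nb"] = [cap["gleason_group_points"][str(int(v))]
                         for v in records["gg_nb"]]
        cols["ppb"] = [_bin_points(v, cap["ppb_points"])
                       for v in records["ppb"]]
    if which in ("post", "combine"):
        cols["gg_rp"] = [caps["gleason_group_points"][str(int(v))]
                         for v in records["gg_rp"]]
        cols["sm"] = [caps["sm_points"] * int(bool(v))
                      for v in records["sm"]]
        cols["epe"] = [caps["epe_points"] * int(bool(v))
                       for v in records["epe"]]
        cols["svi"] = [caps["svi_points"] * int(bool(v))
                       for v in records["svi"]]
    if not cols:
        raise ValueError(f"unknown signature group '{which}'")
    return pd.DataFrame(cols, index=records.index)


def clinical_signature(records: pd.DataFrame, time, event,
                       which: str = "combine"):
    """Fit CS-pre / CS-post / CS-combine; returns ``(CoxFit, cs_scores)``.

    Requires at least 10 events (documented stability floor).  Constant or
    aliased design columns raise with the offending names.
    """
    event = np.asarray(event, dtype=int)
    if event.sum() < 10:
        raise ValueError("clinical signature needs >= 10 events")
    X = _signature_matrix(records, which)

    bad = [c for c in X.columns if X[c].nunique() <= 1]
    if not bad:
        M = X.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(M - M.mean(axis=0))
        if rank < M.shape[1]:
            bad = list(X.columns)
    if bad:
        raise ValueError(f"singular design; aliased columns: {bad}")

    fit = fit_cox(X.to_numpy(dtype=float), np.asarray(time, dtype=float),
                  event, names=list(X.columns))
    cs = fit.linear_predictor(X.to_numpy(dtype=float))
    return fit, cs


def score_frame(records: pd.DataFrame) -> pd.DataFrame:
    """All comparator scores for a cohort table (one row per patient)."""
    rows = []
    for _, rec in records.iterrows():
        r = rec.to_dict()
        cap = capra(r)
        cps = capra_s(r)
        rows.append({
            "capra": cap.score,
            "capra_category": cap.category,
            "capra_s": cps.score,
            "capra_s_category": cps.category,
            "nccn": risk_ordinal(nccn(r)),
            "gg_rp_group": gg_rp_group(r),
        })
    return pd.DataFrame(rows, index=records.index)
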