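"""Univariate concordance screening of features against censored survival.

Each feature is scored by Harrell's C-index and a two-sided Wald p-value
from a one-covariate Cox fit on the z-standardized feature.  A feature is
retained when C > 0.5 and p < 0.05 (no sign-flipping, no multiplicity
correction — deliberately liberal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._concordance import concordance_index
from .survstats import fit_cox

__all__ = [
    "ScreenResult",
    "harrell_cindex",
    "univariate_p",
    "screen",
    "family_of",
    "family_report",
]

#: default selection rule
C_THRESHOLD = 0.5
ALPHA = 0.05


@dataclass
class ScreenResult:
    feature_name: str
    c_index: float
    p_value: float
    selected: bool


def harrell_cindex(score, time, event) -> float:
    """Harrell's concordance index (larger score = higher hazard)."""
    return concordance_index(score, time, event)


def univariate_p(score, time, event) -> float:
    """Two-sided Wald p from a one-covariate Cox fit on the standardized score.

    Degenerate (constant) features and non-converging fits return p = 1.
    """
    x = np.asarray(score, dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        return 1.0
    z = (x - x.mean()) / sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = fit_cox(z[:, None], time, event)
        except (ValueError, np.linalg.LinAlgError):
            return 1.0
    if not np.isfinite(fit.p[0]):
        return 1.0
    return float(fit.p[0])


def screen(feature_table: pd.DataFrame, time, event,
           c_threshold: float = C_THRESHOLD,
           alpha: float = ALPHA) -> list[ScreenResult]:
    """Apply the univariate rule to every column of ``feature_table``."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(feature_table) != len(time):
        raise ValueError("feature table and survival rows are misaligned")

    results = []
    for name in feature_table.columns:
        x = feature_table[name].to_numpy(dtype=float)
        finite = np.isfinite(x)
        if not finite.all() or np.ptp(x) == 0:
            results.append(ScreenResult(name, 0.5, 1.0, False))
            continue
        try:
            c = concordance_index(x, time, event)
        except ValueError:
            results.append(ScreenResult(name, 0.5, 1.0, False))
            continue
        p = univariate_p(x, time, event)
        results.append(ScreenResult(name, float(c), p,
                                    bool(c > c_threshold and p < alpha)))
    return results


def family_of(feature_name: str) -> str:
    """Feature family from the ``filter_class_feature`` naming convention.

    Texture-matrix classes (glcm and extensions) collapse into 'texture'.
    """
    parts = feature_name.split("_")
    cls = parts[1] if len(parts) >= 3 else parts[0]
    cls = cls.lower()
    if cls in {"glcm", "glrlm", "glszm", "ngtdm", "gldm"}:
        return "texture"
    if cls == "firstorder":
        return "first-order"
    return cls


def family_report(results: list[ScreenResult]) -> pd.DataFrame:
    """Counts and percentages of selected features per family.

    Percentages are of the selected pool (unrounded; callers format).
    """
    selected = [r for r in results if r.selected]
    n_sel = len(selected)
    fams: dict[str, int] = {}
    for r in selected:
        fam = family_of(r.feature_name)
        fams[fam] = fams.get(fam, 0) + 1
    rows = [
        {"family": fam, "selected": cnt,
         "pct_of_selected": 100.0 * cnt / n_sel if n_sel else 0.0}
        for fam, cnt in sorted(fams.items())
    ]
    return pd.DataFrame(rows, columns=["family", "selected", "pct_of_selected"])


def results_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"feature_name": r.feature_name, "c_index": r.c_index,
          "p_value": r.p_value, "selected": r.selected} for r in results]
    )
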