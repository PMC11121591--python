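"""Screening of texture features for variability across the grade groups.

Each feature is tested across the three Gleason grade groups with one-way
ANOVA when every group looks normal, and with the (tie-corrected)
Kruskal-Wallis test otherwise.  Normality is operationalised per group with
Shapiro-Wilk at alpha = 0.05; a group too small for Shapiro-Wilk (< 3
observations) routes the feature to Kruskal-Wallis.  Features with
p <= 0.05 are selected.  No multiplicity correction is applied by default;
an optional Benjamini-Hochberg switch is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ScreeningResult", "route_test", "screen_features", "SELECTION_ALPHA"]

SELECTION_ALPHA = 0.05
NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class ScreeningResult:
    feature_name: str
    test_used: str  # "ANOVA" | "KruskalWallis"
    statistic: float
    p_value: float
    selected: bool


def route_test(groups: list[np.ndarray], normality_alpha: float = NORMALITY_ALPHA) -> str:
    """Choose ANOVA iff every group passes Shapiro-Wilk at ``normality_alpha``."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 2:
            raise ValueError("every group needs at least 2 observations")
        if g.size < 3 or np.ptp(g) == 0:
            return "KruskalWallis"
        if stats.shapiro(g).pvalue < normality_alpha:
            return "KruskalWallis"
    return "ANOVA"


def _test_one(groups: list[np.ndarray], normality_alpha: float) -> tuple[str, float, float]:
    test = route_test(groups, normality_alpha)
    if test == "ANOVA":
        res = stats.f_oneway(*groups)
    else:
        res = stats.kruskal(*groups)
    return test, float(res.statistic), float(res.pvalue)


def screen_features(
    features: pd.DataFrame,
    grade_groups: pd.Series,
    alpha: float = SELECTION_ALPHA,
    normality_alpha: float = NORMALITY_ALPHA,
    fdr: bool = False,
) -> pd.DataFrame:
    """Screen every feature column for variability across the grade groups.

    ``features`` is a patients x features table and ``grade_groups`` a
    same-indexed series of labels 1/2/3.  Returns one row per feature with
    the test used, its statistic, the p-value and the selection flag
    (p <= alpha).  Constant features get p = 1 and are excluded with a
    warning.  ``fdr=True`` applies Benjamini-Hochberg before selection.
    """
    grade_groups = grade_groups.loc[features.index]
    labels = sorted(grade_groups.unique())
    if len(labels) < 3:
        raise ValueError(f"expected 3 grade groups, found {labels}")
    rows = []
    for col in features.columns:
        values = features[col].to_numpy(dtype=float)
        if np.ptp(values) == 0:
            warnings.warn(f"feature {col!r} is constant; excluded from selection")
            rows.append((col, "none", np.nan, 1.0))
            continue
        groups = [values[(grade_groups == lab).to_numpy()] for lab in labels]
        test, statistic, p = _test_one(groups, normality_alpha)
        rows.append((col, test, statistic, p))
    out = pd.DataFrame(rows, columns=["feature", "test_used", "statistic", "p_value"])
    p_eff = out["p_value"].to_numpy()
    if fdr:
        p_eff = multipletests(p_eff, method="fdr_bh")[1]
        out["p_adjusted"] = p_eff
    out["selected"] = (p_eff <= alpha) & (out["test_used"] != "none")
    return out
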