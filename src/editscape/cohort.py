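"""Drug-sensitivity grouping and cohort-level descriptive statistics.

Cell lines are stratified per drug by IC50 quartile: strictly below Q1 is
HIGH_SENSITIVITY (the drug inhibits at low concentration), strictly above
Q3 is LOW_SENSITIVITY, everything else INTERMEDIATE (retained in the table
but excluded from group comparisons).  Quartiles use linear-interpolation
("type 7") quantiles by default; a nearest-rank alternative is available.

Two-group comparisons gate on Shapiro–Wilk normality in both groups at
0.05: both normal => Welch-free pooled t-test, otherwise the two-sample
Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffedit import HIGH_SENSITIVITY, LOW_SENSITIVITY, bh_fdr

logger = logging.getLogger(__name__)

INTERMEDIATE = "INTERMEDIATE"

_QUANTILE_METHODS = {"linear": "linear", "nearest-rank": "inverted_cdf"}


def assign_sensitivity(
    ic50: pd.DataFrame, drug: str, quantile_method: str = "linear"
) -> pd.DataFrame:
    """Label samples HIGH/LOW/INTERMEDIATE sensitivity by IC50 quartile.

    Expects a long table with columns ``sample_id, drug, ic50``; returns the
    rows for ``drug`` with a ``label`` column added.  Strict inequalities:
    a value exactly at Q1 or Q3 stays INTERMEDIATE.
    """
    if quantile_method not in _QUANTILE_METHODS:
        raise ValueError(f"quantile_method must be one of {sorted(_QUANTILE_METHODS)}")
    sub = ic50[ic50["drug"] == drug].copy()
    if len(sub) < 8:
        raise ValueError(f"drug {drug!r}: need >= 8 samples, got {len(sub)}")
    values = sub["ic50"].to_numpy(dtype=float)
    if np.all(values == values[0]):
        raise ValueError(f"drug {drug!r}: all IC50 values equal; quartiles degenerate")
    method = _QUANTILE_METHODS[quantile_method]
    q1, q3 = np.quantile(values, [0.25, 0.75], method=method)
    sub["label"] = INTERMEDIATE
    sub.loc[sub["ic50"] < q1, "label"] = HIGH_SENSITIVITY
    sub.loc[sub["ic50"] > q3, "label"] = LOW_SENSITIVITY
    logger.info(
        "%s: Q1=%.4g Q3=%.4g -> %d high / %d low / %d intermediate",
        drug, q1, q3,
        int((sub["label"] == HIGH_SENSITIVITY).sum()),
        int((sub["label"] == LOW_SENSITIVITY).sum()),
        int((sub["label"] == INTERMEDIATE).sum()),
    )
    return sub.reset_index(drop=True)


@dataclass(frozen=True)
class GroupCompareResult:
    variable: str
    normality_p_g1: float
    normality_p_g2: float
    test_used: str  # "t_test" or "wilcoxon"
    statistic: float
    pvalue: float
    adjusted_p: float | None = None


def _shapiro_p(values: np.ndarray) -> float:
    if np.all(values == values[0]):
        return float("nan")  # undefined on a constant sample
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(values).pvalue)


def group_compare(values_g1, values_g2, variable: str = "") -> GroupCompareResult:
    """Shapiro–Wilk-gated two-sided comparison of two independent groups.

    Uses a t-test when both groups look normal (Shapiro–Wilk p >= 0.05 in
    each), the Wilcoxon rank-sum test otherwise; a constant group makes the
    normality test undefined and forces the rank test with a warning.
    """
    g1 = np.asarray(values_g1, dtype=float)
    g2 = np.asarray(values_g2, dtype=float)
    if g1.size < 3 or g2.size < 3:
        raise ValueError("need at least 3 values per group")
    p1, p2 = _shapiro_p(g1), _shapiro_p(g2)
    if np.isnan(p1) or np.isnan(p2):
        logger.warning("constant group for %r: normality undefined, using rank test", variable)
        normal = False
    else:
        normal = p1 >= 0.05 and p2 >= 0.05
    if normal:
        res = stats.ttest_ind(g1, g2)
        test = "t_test"
    else:
        res = stats.mannwhitneyu(g1, g2, alternative="two-sided")
        test = "wilcoxon"
    return GroupCompareResult(
        variable=variable,
        normality_p_g1=p1,
        normality_p_g2=p2,
        test_used=test,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
    )


def group_compare_batch(variables: dict[str, tuple], adjust: bool = True) -> pd.DataFrame:
    """Compare a batch of variables, optionally BH-adjusting across them."""
    results = [group_compare(g1, g2, variable=name) for name, (g1, g2) in variables.items()]
    df = pd.DataFrame(
        [
            (r.variable, r.normality_p_g1, r.normality_p_g2, r.test_used, r.statistic, r.pvalue)
            for r in results
        ],
        columns=["variable", "normality_p_g1", "normality_p_g2", "test_used", "statistic", "pvalue"],
    )
    if adjust and len(df):
        df["adjusted_p"] = bh_fdr(df["pvalue"].to_numpy())
    return df


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in an input vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
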