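"""Patient-cohort validation: hyper/hypo editing classification, the
Kaplan–Meier product-limit estimator, the two-sample log-rank test, and the
per-site survival scan over differentially edited sites.

A patient is HYPER-edited at a site when their editing level is strictly
above the cohort mean at that site, HYPO otherwise ("over the mean" is
strict); the mean is taken over patients with the site observed, so each
site's scan uses its own cohort subset.  Event/censoring ties at the same
time follow the standard convention: events first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .diffedit import bh_fdr
from .repeats import annotate_repeat_class  # noqa: F401  (re-export: site annotation)

logger = logging.getLogger(__name__)

HYPER = "HYPER"
HYPO = "HYPO"


def classify_hyper_hypo(levels: pd.Series) -> pd.Series:
    """HYPER/HYPO labels for one site's per-patient editing levels.

    HYPER iff level > mean over the non-missing levels; missing stays
    missing.  All-identical levels give an all-HYPO degenerate split (warned).
    """
    obs = levels.dropna()
    if len(obs) < 2:
        raise ValueError("need at least 2 non-missing levels to classify")
    mean = float(obs.mean())
    if obs.nunique() == 1:
        logger.warning("all editing levels identical (%.4g): degenerate all-HYPO split", mean)
    labels = pd.Series(index=levels.index, dtype=object)
    labels[obs.index] = np.where(obs > mean, HYPER, HYPO)
    return labels


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan–Meier product-limit step table.

    Returns one row per distinct observed time with columns ``time, at_risk,
    events, censored, survival``; survival changes only at event times and
    starts from 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    # keep only rows where subjects leave risk (drops the t=0 anchor row)
    table = kmf.event_table[kmf.event_table["removed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "censored": table["censored"].to_numpy(dtype=int),
        }
    )
    out["survival"] = surv.reindex(out["time"].to_numpy()).to_numpy(dtype=float)
    return out.reset_index(drop=True)


def logrank_test(labels, times, events) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi2, pvalue), df = 1.

    ``labels`` partitions subjects into exactly two groups; missing-label
    subjects must be removed by the caller.
    """
    labels = pd.Series(list(labels))
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = labels.dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    m = labels == groups[0]
    res = _ll_logrank(times[m], times[~m], events[m], events[~m])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SiteSurvivalResult:
    site_id: str
    n_hyper: int
    n_hypo: int
    chi2: float
    pvalue: float
    significant: bool
    km_hyper: pd.DataFrame = field(repr=False, default=None)
    km_hypo: pd.DataFrame = field(repr=False, default=None)


def site_survival_scan(
    levels: pd.DataFrame,
    survival: pd.DataFrame,
    site_ids: list[str] | None = None,
    p_max: float = 0.05,
    min_patients: int = 4,
) -> tuple[pd.DataFrame, dict[str, SiteSurvivalResult]]:
    """Scan DES sites for association between editing class and PFS.

    Parameters
    ----------
    levels : patients x sites frame of editing levels in [0, 1] (NaN missing),
        indexed by patient_id.
    survival : frame with ``patient_id, pfs_months, event`` columns.
    site_ids : sites to scan (default: every column of `levels`).
    p_max : raw log-rank significance threshold (BH-adjusted p also reported).

    Per site: patients missing the site are excluded, the remainder is split
    HYPER/HYPO about the site mean, and the two arms are compared by
    log-rank with Kaplan–Meier tables attached.  Sites with fewer than
    ``min_patients`` observed patients, or a degenerate one-arm split, are
    skipped with a reason.
    """
    surv = survival.set_index("patient_id")
    if site_ids is None:
        site_ids = list(levels.columns)

    summary_rows, details = [], {}
    for sid in site_ids:
        lev = levels[sid].dropna()
        lev = lev[lev.index.isin(surv.index)]
        if len(lev) < min_patients:
            logger.info("site %s skipped: %d patients with the site observed", sid, len(lev))
            continue
        labels = classify_hyper_hypo(lev)
        n_hyper = int((labels == HYPER).sum())
        n_hypo = int((labels == HYPO).sum())
        if n_hyper == 0 or n_hypo == 0:
            logger.info("site %s skipped: one-arm split (%d hyper / %d hypo)", sid, n_hyper, n_hypo)
            continue
        t = surv.loc[lev.index, "pfs_months"].to_numpy(dtype=float)
        e = surv.loc[lev.index, "event"].to_numpy(dtype=int)
        chi2, p = logrank_test(labels.to_numpy(), t, e)
        hyper_mask = (labels == HYPER).to_numpy()
        details[sid] = SiteSurvivalResult(
            site_id=sid,
            n_hyper=n_hyper,
            n_hypo=n_hypo,
            chi2=chi2,
            pvalue=p,
            significant=p < p_max,
            km_hyper=km_estimate(t[hyper_mask], e[hyper_mask]),
            km_hypo=km_estimate(t[~hyper_mask], e[~hyper_mask]),
        )
        summary_rows.append((sid, n_hyper, n_hypo, chi2, p))

    summary = pd.DataFrame(
        summary_rows, columns=["site_id", "n_hyper", "n_hypo", "logrank_chi2", "pvalue"]
    )
    if len(summary):
        summary["pvalue_bh"] = bh_fdr(summary["pvalue"].to_numpy())
        summary["significant"] = summary["pvalue"] < p_max
    return summary, details


def pfs_quartile_filter(
    survival: pd.DataFrame, quantile_method: str = "linear"
) -> pd.DataFrame:
    """Optional pre-filter keeping only patients in the first and fourth
    quartiles of PFS months (the extremes of progression behaviour)."""
    method = {"linear": "linear", "nearest-rank": "inverted_cdf"}[quantile_method]
    q1, q3 = np.quantile(survival["pfs_months"].to_numpy(dtype=float), [0.25, 0.75], method=method)
    keep = (survival["pfs_months"] < q1) | (survival["pfs_months"] > q3)
    return survival[keep].reset_index(drop=True)
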