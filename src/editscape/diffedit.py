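"""Differential-editing analysis: per-site beta-binomial likelihood-ratio
tests across two sample groups, BH FDR control, fold change / delta on MLE
means, DES selection, and the Alu Editing Index.

Conventions: group 1 is the LOW-sensitivity group and group 2 the
HIGH-sensitivity group (a sensitive cell line has a low IC50).  ``delta`` is
``mean_g1 - mean_g2`` of the fitted beta means alpha/(alpha+beta); a site's
``direction`` names the group in which editing is higher.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .betabin import redit_llr_test
from .core import EditingMatrix
from .repeats import ALU, RepeatIndex

logger = logging.getLogger(__name__)

LOW_SENSITIVITY = "LOW_SENSITIVITY"
HIGH_SENSITIVITY = "HIGH_SENSITIVITY"

RESULT_COLUMNS = [
    "llr", "pvalue", "fdr", "mean_g1", "mean_g2", "log2fc", "delta",
    "n_obs_g1", "n_obs_g2",
]


def editing_level(alt: float, ref: float) -> float:
    """Editing level alt/(alt+ref); undefined (raises) on an empty cell."""
    total = alt + ref
    if total <= 0:
        raise ValueError("editing level undefined at zero total (missing cell)")
    return alt / total


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    return multipletests(p, method="fdr_bh")[1]


def fold_change(mean_g1: float, mean_g2: float, pseudo: float = 1e-4, base: float = 2.0) -> float:
    """log-base fold change of two editing means with a pseudocount guard.

    ``log2((mean_g1 + pseudo) / (mean_g2 + pseudo))`` by default; exactly 0
    when both means are 0.
    """
    if mean_g1 == 0 and mean_g2 == 0:
        return 0.0
    return float(np.log((mean_g1 + pseudo) / (mean_g2 + pseudo)) / np.log(base))


@dataclass
class SkippedSite:
    site_id: str
    reason: str


def differential_editing(
    matrix: EditingMatrix,
    group1_samples: list[str],
    group2_samples: list[str],
    min_cells: int = 2,
    df: int = 2,
) -> tuple[pd.DataFrame, list[SkippedSite]]:
    """Run the beta-binomial LLR test at every site of a matrix.

    NO_COVERAGE cells are dropped per site per group (groups may end up with
    unequal effective sizes); sites with fewer than ``min_cells`` covered
    cells in either group are skipped with a reason.  BH FDR is computed over
    the tested sites only.

    Returns a result frame indexed by site_id with columns ``llr, pvalue,
    fdr, mean_g1, mean_g2, log2fc, delta, n_obs_g1, n_obs_g2``, plus the
    skipped-site list.
    """
    overlap = set(group1_samples) & set(group2_samples)
    if overlap:
        raise ValueError(f"samples in both groups: {sorted(overlap)[:5]}")
    a1, t1 = matrix.alt[group1_samples].to_numpy(), matrix.total[group1_samples].to_numpy()
    a2, t2 = matrix.alt[group2_samples].to_numpy(), matrix.total[group2_samples].to_numpy()

    rows, index, skipped = [], [], []
    for i, site_id in enumerate(matrix.site_ids):
        m1 = ~np.isnan(t1[i]) & (t1[i] > 0)
        m2 = ~np.isnan(t2[i]) & (t2[i] > 0)
        if m1.sum() < min_cells or m2.sum() < min_cells:
            skipped.append(SkippedSite(site_id, f"covered cells g1={int(m1.sum())} g2={int(m2.sum())} < {min_cells}"))
            continue
        cells1 = np.column_stack([a1[i, m1], t1[i, m1]])
        cells2 = np.column_stack([a2[i, m2], t2[i, m2]])
        res = redit_llr_test(cells1, cells2, df=df)
        mg1, mg2 = res.fit_g1.mean, res.fit_g2.mean
        rows.append(
            (
                res.llr, res.pvalue, np.nan, mg1, mg2,
                fold_change(mg1, mg2), mg1 - mg2, int(m1.sum()), int(m2.sum()),
            )
        )
        index.append(site_id)

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS, index=pd.Index(index, name="site_id"))
    if len(results):
        results["fdr"] = bh_fdr(results["pvalue"].to_numpy())
    logger.info("differential test: %d sites tested, %d skipped", len(results), len(skipped))
    return results, skipped


def select_des(
    results: pd.DataFrame,
    p_max: float = 0.05,
    fdr_max: float = 0.1,
    fc_min: float = 2.5,
    fc_scale: str = "ratio",
) -> pd.DataFrame:
    """Flag differentially edited sites (DESs) and assign a direction.

    A site is a DES iff ``pvalue < p_max`` and ``fdr < fdr_max`` and the
    fold-change magnitude clears ``fc_min``.  ``fc_scale`` chooses how
    ``fc_min`` is read: ``"ratio"`` (default) requires the editing-level
    ratio ``2**|log2fc| >= fc_min``; ``"log2"`` requires
    ``|log2fc| >= fc_min``.  The ratio reading is the default because a
    selection gate on the same scale as a planted or expected effect passes
    an unbiased estimate of a threshold-sized effect only about half the
    time; with the ratio reading the gate sits far inside a log2-sized
    effect and selection is driven by the test, not the gate.  Sites with
    both group means zero are never DESs.  Direction is LOW_SENSITIVITY when
    the fitted mean is higher in group 1 (the low-sensitivity group), else
    HIGH_SENSITIVITY.
    """
    out = results.copy()
    magnitude = out["log2fc"].abs()
    if fc_scale == "ratio":
        fc_ok = np.power(2.0, magnitude) >= fc_min
    elif fc_scale == "log2":
        fc_ok = magnitude >= fc_min
    else:
        raise ValueError(f"fc_scale must be 'log2' or 'ratio', got {fc_scale!r}")
    nonzero = ~((out["mean_g1"] == 0) & (out["mean_g2"] == 0))
    out["is_des"] = (out["pvalue"] < p_max) & (out["fdr"] < fdr_max) & fc_ok & nonzero
    out["direction"] = np.where(out["delta"] > 0, LOW_SENSITIVITY, HIGH_SENSITIVITY)
    return out


@dataclass(frozen=True)
class AEIResult:
    """Alu Editing Index of one sample: pooled edited/total read ratio over
    sites inside Alu elements (a ratio of sums, not a mean of ratios)."""

    sample_id: str
    aei: float
    n_sites_used: int
    total_reads_used: int

    @property
    def defined(self) -> bool:
        return self.total_reads_used > 0


def compute_aei(matrix: EditingMatrix, repeats, sample_id: str) -> AEIResult:
    """Alu Editing Index for one sample: sum(alt)/sum(alt+ref) over that
    sample's observed cells at sites overlapping ALU intervals.

    With zero Alu-site reads the index is undefined: returned as NaN with
    ``total_reads_used == 0``.
    """
    index = RepeatIndex(repeats)
    in_alu = [
        index.classify(c, p) == ALU
        for c, p in zip(matrix.sites["chrom"], matrix.sites["pos"])
    ]
    alt = matrix.alt.loc[in_alu, sample_id]
    total = matrix.total.loc[in_alu, sample_id]
    mask = total.notna() & (total > 0)
    sum_alt, sum_total = float(alt[mask].sum()), float(total[mask].sum())
    if sum_total == 0:
        logger.warning("AEI undefined for %s: no covered Alu-site reads", sample_id)
        return AEIResult(sample_id, float("nan"), int(mask.sum()), 0)
    return AEIResult(sample_id, sum_alt / sum_total, int(mask.sum()), int(sum_total))


def compute_aei_all(matrix: EditingMatrix, repeats) -> pd.DataFrame:
    """AEI for every sample of a matrix, as a table."""
    rows = [compute_aei(matrix, repeats, s) for s in matrix.sample_ids]
    return pd.DataFrame(
        [(r.sample_id, r.aei, r.n_sites_used, r.total_reads_used) for r in rows],
        columns=["sample_id", "aei", "n_sites_used", "total_reads_used"],
    )
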