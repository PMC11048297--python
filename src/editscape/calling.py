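"""Edited-site calling and the filter cascade.

Stages, in order:

1. **candidate call** — per sample, a site is called iff it has at least
   ``min_edited_reads`` edited reads AND an allele frequency
   ``alt/(alt+ref) >= min_af``; the candidate list is the union of per-sample
   calls.
2. **missing-value resolution** — for every candidate site, every sample's
   cell is backfilled from the raw counts: OBSERVED (possibly with zero or
   sub-threshold edited reads) when the sample has coverage there,
   NO_COVERAGE otherwise.
3. **prevalence** — keep sites present in strictly more than ``min_prevalence``
   of samples; "present" defaults to covered (OBSERVED), with a "called"
   alternative since per-sample counts are needed downstream either way.
4. **DNA-variant subtraction** — drop sites whose (chrom, pos, ref, alt)
   exactly matches a genomic variant (A>G on +, T>C on − per the strand
   rule), so germline/somatic DNA changes are not mistaken for editing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EditingMatrix, FilterReport, GenomicSite, site_frame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CascadeParams:
    min_edited_reads: int = 5
    min_af: float = 0.05
    min_prevalence: float = 0.5
    presence: str = "observed"  # or "called"

    def __post_init__(self) -> None:
        if self.min_edited_reads < 0:
            raise ValueError("min_edited_reads must be >= 0")
        if not 0 <= self.min_af <= 1:
            raise ValueError("min_af must be in [0, 1]")
        if not 0 <= self.min_prevalence < 1:
            raise ValueError("min_prevalence must be in [0, 1)")
        if self.presence not in ("observed", "called"):
            raise ValueError("presence must be 'observed' or 'called'")


def _clean_obs(obs: pd.DataFrame) -> pd.DataFrame:
    total = obs["ref_reads"] + obs["alt_reads"]
    zero = total == 0
    if zero.any():
        logger.warning("%d zero-total observed cells treated as NO_COVERAGE", int(zero.sum()))
    return obs[~zero]


def call_candidate_sites(
    obs: pd.DataFrame, min_edited_reads: int = 5, min_af: float = 0.05
) -> pd.DataFrame:
    """Per-sample candidate calls from an observation frame.

    Returns the observation rows satisfying both thresholds:
    ``alt_reads >= min_edited_reads`` and ``alt/(alt+ref) >= min_af``.
    """
    obs = _clean_obs(obs)
    total = obs["ref_reads"] + obs["alt_reads"]
    af = obs["alt_reads"] / total
    called = obs[(obs["alt_reads"] >= min_edited_reads) & (af >= min_af)]
    return called


def _site_ids(frame: pd.DataFrame) -> pd.Series:
    return (
        frame["chrom"].astype(str)
        + ":" + frame["pos"].astype(str)
        + ":" + frame["strand"].astype(str)
    )


def resolve_missing(
    candidate_sites: list[GenomicSite], obs: pd.DataFrame, sample_ids: list[str]
) -> EditingMatrix:
    """Build the candidate-site matrix, disambiguating missing cells.

    For each candidate site and sample: OBSERVED(alt, total) from the raw
    counts when the sample covers the site (even if the site was never
    "called" there — zero-edited and sub-threshold cells are kept as data),
    NO_COVERAGE when it does not.
    """
    sites = site_frame(sorted(candidate_sites))
    obs = _clean_obs(obs).copy()
    obs["site_id"] = _site_ids(obs)
    obs["total"] = obs["ref_reads"] + obs["alt_reads"]

    alt = (
        obs.pivot(index="site_id", columns="sample_id", values="alt_reads")
        .reindex(index=sites.index, columns=sample_ids)
    )
    total = (
        obs.pivot(index="site_id", columns="sample_id", values="total")
        .reindex(index=sites.index, columns=sample_ids)
    )
    alt.columns.name = total.columns.name = None
    return EditingMatrix(sites, alt.astype(float), total.astype(float))


def prevalence_filter(
    matrix: EditingMatrix,
    min_frac: float = 0.5,
    presence: str = "observed",
    min_edited_reads: int = 5,
    min_af: float = 0.05,
) -> tuple[EditingMatrix, list[str]]:
    """Keep sites present in strictly more than ``min_frac`` of samples.

    ``presence='observed'`` counts covered cells; ``presence='called'``
    counts cells that pass the candidate-call thresholds.
    Returns (filtered matrix, removed site ids).
    """
    if presence == "observed":
        present = matrix.observed()
    elif presence == "called":
        with np.errstate(invalid="ignore", divide="ignore"):
            af = matrix.alt / matrix.total
        present = matrix.observed() & (matrix.alt >= min_edited_reads) & (af >= min_af)
    else:
        raise ValueError(f"presence must be 'observed' or 'called', got {presence!r}")
    frac = present.sum(axis=1) / matrix.n_samples
    keep = frac > min_frac
    removed = list(matrix.sites.index[~keep])
    logger.info("prevalence filter (%s > %g): kept %d of %d sites",
                presence, min_frac, int(keep.sum()), matrix.n_sites)
    return matrix.subset_sites(matrix.sites.index[keep]), removed


def subtract_dna_variants(
    matrix: EditingMatrix, variants: set[tuple[str, int, str, str]]
) -> tuple[EditingMatrix, list[str]]:
    """Drop sites exactly matching a DNA variant by (chrom, pos, ref, alt).

    Matching is strand-aware through the site's own alleles: a minus-strand
    site matches a T>C variant record, a plus-strand site an A>G record.
    Returns (filtered matrix, removed site ids).
    """
    keys = list(
        zip(
            matrix.sites["chrom"],
            matrix.sites["pos"].astype(int),
            matrix.sites["ref_base"],
            matrix.sites["alt_base"],
        )
    )
    hit = np.array([k in variants for k in keys])
    removed = list(matrix.sites.index[hit])
    logger.info("variant subtraction: removed %d of %d sites", len(removed), matrix.n_sites)
    return matrix.subset_sites(matrix.sites.index[~hit]), removed


def run_cascade(
    obs: pd.DataFrame,
    variants: set[tuple[str, int, str, str]],
    params: CascadeParams = CascadeParams(),
    sample_ids: list[str] | None = None,
) -> tuple[EditingMatrix, FilterReport]:
    """Run the full filter cascade and account for every removal.

    ``obs`` is the concatenated observation frame of all samples (columns
    ``sample_id, chrom, pos, strand, ref_base, ref_reads, alt_reads``).
    Returns the final EditingMatrix and a FilterReport whose stages satisfy
    input − removed = output.
    """
    if sample_ids is None:
        sample_ids = sorted(obs["sample_id"].unique())
    report = FilterReport()
    clean = _clean_obs(obs)

    all_sites = set(_site_ids(clean))
    called = call_candidate_sites(clean, params.min_edited_reads, params.min_af)
    candidate_ids = set(_site_ids(called))
    report.add("candidate_call", len(all_sites), len(all_sites) - len(candidate_ids))

    candidates = [GenomicSite.from_id(sid) for sid in candidate_ids]
    matrix = resolve_missing(candidates, clean, sample_ids)
    report.add("resolve_missing", matrix.n_sites, 0)

    matrix, removed_prev = prevalence_filter(
        matrix, params.min_prevalence, params.presence,
        params.min_edited_reads, params.min_af,
    )
    report.add("prevalence", matrix.n_sites + len(removed_prev), len(removed_prev))

    matrix, removed_var = subtract_dna_variants(matrix, variants)
    report.add("variant_subtraction", matrix.n_sites + len(removed_var), len(removed_var))
    return matrix, report
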