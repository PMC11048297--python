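"""Synthetic-data generation with known ground truth.

Emulates the statistical structure the downstream analysis assumes: per-site
edited-read counts that are beta-binomial across samples (overdispersed
relative to binomial), negative-binomial coverage, a planted fraction of
differentially edited sites at a fixed |log2 fold change| split evenly
between the two group directions, heterozygous DNA-variant contaminant
sites, random per-cell dropout, quartile-separable drug IC50 values, and
exponential progression times whose hazard depends on the editing level at
designated sites.

Default group sizes (10 vs 8) mirror a typical drug-family comparison in a
small cell-line panel; the differential fold change defaults to the 2.5
log2-units selection threshold so planted effects sit at the decision
boundary's magnitude.

Beta-binomial parameterization: mean/overdispersion (mu, rho) with
``alpha = mu (1-rho)/rho`` and ``beta = (1-mu)(1-rho)/rho``, so the beta
mean alpha/(alpha+beta) equals mu and rho -> 0 recovers the binomial.
All randomness flows from the single seed in each config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import STRAND_ALLELES, EditingMatrix, GenomicSite, site_frame
from .repeats import ALU, NON_ALU_REPEAT, RepeatInterval
from . import io as eio

_CHROMS = ["chr1", "chr2", "chr3", "chr5", "chr8", "chr17", "chr19", "chr22"]
_POS_STEP = 1000


@dataclass(frozen=True)
class SimConfig:
    """Conditions of the simulated two-group editing experiment."""

    n_sites: int = 1000
    frac_des: float = 0.1
    n_group1: int = 10
    n_group2: int = 8
    coverage_mean: float = 50.0
    coverage_dispersion: float = 5.0
    null_mean: float = 0.1
    null_overdispersion: float = 0.05
    des_log2fc: float = 2.5
    frac_dna_variant: float = 0.05
    dropout_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_des", "frac_dna_variant", "dropout_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if not 0 < self.null_mean < 1:
            raise ValueError("null_mean must be in (0, 1)")
        if not 0 <= self.null_overdispersion < 1:
            raise ValueError("null_overdispersion must be in [0, 1)")
        if self.des_log2fc < 0:
            raise ValueError("des_log2fc must be >= 0")

    @property
    def group1_samples(self) -> list[str]:
        return [f"g1_s{i:02d}" for i in range(1, self.n_group1 + 1)]

    @property
    def group2_samples(self) -> list[str]:
        return [f"g2_s{i:02d}" for i in range(1, self.n_group2 + 1)]


@dataclass(frozen=True)
class SurvSimConfig:
    """Conditions of the simulated progression-free-survival cohort."""

    n_patients: int = 86
    baseline_hazard: float = 0.03  # events per month; median PFS ~ 23 months
    effect_beta: float = 3.0  # log-hazard per unit editing level
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


def _bb_shapes(mu: float, rho: float) -> tuple[float, float]:
    if rho == 0:
        return np.inf, np.inf  # caller special-cases pure binomial
    return mu * (1 - rho) / rho, (1 - mu) * (1 - rho) / rho


def _draw_bb(rng: np.random.Generator, mu: float, rho: float, n: np.ndarray) -> np.ndarray:
    """Beta-binomial draws with mean mu, overdispersion rho, totals n."""
    if rho == 0:
        return rng.binomial(n, mu)
    a, b = _bb_shapes(mu, rho)
    p = rng.beta(a, b, size=n.shape)
    return rng.binomial(n, p)


def gen_editing_counts(cfg: SimConfig) -> tuple[EditingMatrix, pd.DataFrame]:
    """Simulate the editing-count matrix and its ground-truth table.

    Differential (DES) sites carry ``null_mean * 2**des_log2fc`` in the
    raised group — split 50/50 between group 1 and group 2 — and a config
    whose raised mean leaves (0, 1) is rejected outright rather than
    silently clipped.  DNA-variant contaminant sites express at 0.5 allele
    fraction in both groups (a heterozygous genomic variant leaking into the
    RNA counts) and are never differential.

    Returns (matrix, truth) with truth columns ``site_id, chrom, pos,
    strand, is_des, is_dna_variant, true_mean_g1, true_mean_g2, true_log2fc``.
    """
    raised = cfg.null_mean * 2.0 ** cfg.des_log2fc
    n_des = round(cfg.frac_des * cfg.n_sites)
    if n_des > 0 and not 0 < raised < 1:
        raise ValueError(
            f"raised DES mean {raised:.4g} = null_mean * 2^des_log2fc leaves (0, 1); "
            "infeasible config"
        )

    rng = np.random.default_rng(cfg.seed)
    strands = np.asarray(list(STRAND_ALLELES), dtype=object)
    sites = [
        GenomicSite(
            _CHROMS[i % len(_CHROMS)],
            _POS_STEP * (i // len(_CHROMS) + 1),
            str(rng.choice(strands)),
        )
        for i in range(cfg.n_sites)
    ]
    meta = site_frame(sites)

    n_var = round(cfg.frac_dna_variant * cfg.n_sites)
    order = rng.permutation(cfg.n_sites)
    des_idx = set(order[:n_des].tolist())
    var_idx = set(order[n_des : n_des + n_var].tolist())  # disjoint from DES
    des_list = sorted(des_idx)
    up_in_g1 = {s for j, s in enumerate(des_list) if j % 2 == 0}

    samples = cfg.group1_samples + cfg.group2_samples
    n_g1 = cfg.n_group1
    n_total = len(samples)

    # negative-binomial coverage: mean m, dispersion r => p = r/(r+m)
    r = cfg.coverage_dispersion
    p_nb = r / (r + cfg.coverage_mean)
    coverage = rng.negative_binomial(r, p_nb, size=(cfg.n_sites, n_total)).astype(float)
    dropout = rng.random((cfg.n_sites, n_total)) < cfg.dropout_rate
    coverage[dropout] = 0.0

    alt = np.zeros_like(coverage)
    truth_rows = []
    for i in range(cfg.n_sites):
        if i in var_idx:
            mu1 = mu2 = 0.5
            rho1 = rho2 = 0.0  # genomic het: binomial sampling noise only
            is_des = False
        elif i in des_idx:
            is_des = True
            rho1 = rho2 = cfg.null_overdispersion
            if i in up_in_g1:
                mu1, mu2 = raised, cfg.null_mean
            else:
                mu1, mu2 = cfg.null_mean, raised
        else:
            is_des = False
            mu1 = mu2 = cfg.null_mean
            rho1 = rho2 = cfg.null_overdispersion
        n_row = coverage[i].astype(int)
        alt[i, :n_g1] = _draw_bb(rng, mu1, rho1, n_row[:n_g1])
        alt[i, n_g1:] = _draw_bb(rng, mu2, rho2, n_row[n_g1:])
        truth_rows.append(
            (
                meta.index[i], meta.iloc[i]["chrom"], int(meta.iloc[i]["pos"]),
                meta.iloc[i]["strand"], is_des, i in var_idx, mu1, mu2,
                float(np.log2(mu1 / mu2)) if mu1 != mu2 else 0.0,
            )
        )

    missing = coverage == 0
    alt[missing] = np.nan
    coverage[missing] = np.nan

    matrix = EditingMatrix(
        meta,
        pd.DataFrame(alt, index=meta.index, columns=samples),
        pd.DataFrame(coverage, index=meta.index, columns=samples),
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "site_id", "chrom", "pos", "strand", "is_des", "is_dna_variant",
            "true_mean_g1", "true_mean_g2", "true_log2fc",
        ],
    ).set_index("site_id")
    return matrix, truth


def gen_dna_variants(truth: pd.DataFrame) -> list[tuple[str, int, str, str]]:
    """Emit the planted genomic variants as (chrom, pos, ref, alt) records,
    alleles following the strand rule (A>G on +, T>C on −)."""
    records = []
    for row in truth[truth["is_dna_variant"]].itertuples():
        ref, alt = STRAND_ALLELES[row.strand]
        records.append((row.chrom, int(row.pos), ref, alt))
    return records


def gen_ic50(
    n_samples: int,
    n_drugs: int = 3,
    separation: float = 2.0,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    drugs: list[str] | None = None,
    n_shifted: int | None = None,
) -> pd.DataFrame:
    """Simulate a normalized IC50 table with quartile-separable values.

    The first ``n_shifted`` samples (default ``ceil(n/2)``) receive a
    ``+separation`` shift on every drug (high IC50 = low sensitivity), so
    quartile extremes recover the planted split when separation is large;
    noise is standard normal.
    """
    if n_samples < 8:
        raise ValueError("need at least 8 samples for quartile grouping")
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"s{i:02d}" for i in range(1, n_samples + 1)]
    if drugs is None:
        drugs = [f"drug{j + 1}" for j in range(n_drugs)]
    n_shift = -(-n_samples // 2) if n_shifted is None else n_shifted
    rows = []
    for drug in drugs:
        vals = rng.normal(0.0, 1.0, n_samples)
        vals[:n_shift] += separation
        rows.extend((s, drug, float(v)) for s, v in zip(sample_ids, vals))
    return pd.DataFrame(rows, columns=["sample_id", "drug", "ic50"])


def gen_survival(levels, cfg: SurvSimConfig) -> pd.DataFrame:
    """Simulate progression-free survival driven by an editing level.

    Event times are exponential with hazard
    ``baseline_hazard * exp(effect_beta * level)``; censoring is independent:
    each patient is censored with probability ``censor_rate`` at a uniform
    fraction of their event time.

    ``levels`` is a sequence (or Series, whose index becomes patient_id) of
    per-patient editing levels in [0, 1]; its length must equal
    ``cfg.n_patients``.
    """
    if isinstance(levels, pd.Series):
        patient_ids = list(levels.index.astype(str))
        lev = levels.to_numpy(dtype=float)
    else:
        lev = np.asarray(levels, dtype=float)
        patient_ids = [f"p{i:03d}" for i in range(1, lev.size + 1)]
    if lev.size != cfg.n_patients:
        raise ValueError(f"got {lev.size} levels for n_patients={cfg.n_patients}")
    if np.any((lev < 0) | (lev > 1)):
        raise ValueError("editing levels must be in [0, 1]")

    rng = np.random.default_rng(cfg.seed)
    hazard = cfg.baseline_hazard * np.exp(cfg.effect_beta * lev)
    times = rng.exponential(1.0 / hazard)
    censored = rng.random(lev.size) < cfg.censor_rate
    obs_times = np.where(censored, times * rng.random(lev.size), times)
    return pd.DataFrame(
        {
            "patient_id": patient_ids,
            "pfs_months": obs_times,
            "event": (~censored).astype(int),
            "editing_level": lev,
        }
    )


def gen_repeat_annotation(
    sites: pd.DataFrame,
    frac_alu: float = 0.6,
    frac_non_alu: float = 0.2,
    seed: int = 0,
    halfwidth: int = 150,
) -> list[RepeatInterval]:
    """Random repeat annotation over simulated sites: ``frac_alu`` of sites
    covered by an ALU interval, ``frac_non_alu`` by a non-Alu repeat, the
    rest left non-repetitive.  Intervals are 0-based half-open windows of
    ``2*halfwidth`` around each covered site."""
    rng = np.random.default_rng(seed)
    n = len(sites)
    order = rng.permutation(n)
    n_alu = round(frac_alu * n)
    n_rep = round(frac_non_alu * n)
    classes = {}
    classes.update({i: ALU for i in order[:n_alu]})
    classes.update({i: NON_ALU_REPEAT for i in order[n_alu : n_alu + n_rep]})
    out = []
    for i, (chrom, pos) in enumerate(zip(sites["chrom"], sites["pos"])):
        cls = classes.get(i)
        if cls is None:
            continue
        start = max(0, int(pos) - 1 - halfwidth)
        out.append(RepeatInterval(chrom, start, int(pos) - 1 + halfwidth + 1, cls))
    return out


@dataclass
class FixturePaths:
    counts: dict[str, Path] = field(default_factory=dict)
    vcf: Path | None = None
    bed: Path | None = None
    ic50: Path | None = None
    survival: Path | None = None
    truth: Path | None = None


def matrix_to_observations(matrix: EditingMatrix) -> pd.DataFrame:
    """Flatten a matrix into the raw observation frame (covered cells only)."""
    frames = []
    for s in matrix.sample_ids:
        total = matrix.total[s]
        mask = total.notna() & (total > 0)
        sub = matrix.sites[mask]
        alt = matrix.alt.loc[mask, s]
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s,
                    "chrom": sub["chrom"],
                    "pos": sub["pos"].astype(int),
                    "strand": sub["strand"],
                    "ref_base": sub["ref_base"],
                    "ref_reads": (total[mask] - alt).astype(int),
                    "alt_reads": alt.astype(int),
                }
            ).reset_index(drop=True)
        )
    return pd.concat(frames, ignore_index=True)


def write_fixtures(
    outdir,
    matrix: EditingMatrix,
    truth: pd.DataFrame,
    ic50: pd.DataFrame | None = None,
    survival: pd.DataFrame | None = None,
    repeats: list[RepeatInterval] | None = None,
) -> FixturePaths:
    """Write every pipeline input to disk in its external dialect.

    Per-sample site-count TSVs, the VCF variant list, the BED repeat
    annotation, and plain TSVs for IC50/survival/truth; all round-trip
    losslessly through the readers in :mod:`editscape.io`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = FixturePaths()

    obs = matrix_to_observations(matrix)
    counts_dir = outdir / "counts"
    counts_dir.mkdir(exist_ok=True)
    for s in matrix.sample_ids:
        p = counts_dir / f"{s}.tsv"
        eio.write_site_counts(obs[obs["sample_id"] == s], p)
        paths.counts[s] = p

    paths.vcf = outdir / "dna_variants.vcf"
    eio.write_vcf_variants(gen_dna_variants(truth), paths.vcf)

    if repeats is not None:
        paths.bed = outdir / "repeats.bed"
        eio.write_bed_repeats(repeats, paths.bed)
    if ic50 is not None:
        paths.ic50 = outdir / "ic50.tsv"
        eio.write_table(ic50, paths.ic50)
    if survival is not None:
        paths.survival = outdir / "survival.tsv"
        eio.write_table(survival, paths.survival)
    paths.truth = outdir / "truth.tsv"
    eio.write_table(truth.reset_index(), paths.truth)
    return paths
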