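"""End-to-end orchestration: simulate -> call -> group -> diff -> aei -> survive.

A single YAML config drives the whole run; one top-level seed governs every
stochastic stage through deterministically derived sub-seeds, so two runs
with the same config produce byte-identical output tables.  A JSON run
manifest records the tool version, a config hash, the sub-seeds, and every
stage's row counts (the filter cascade's audit embedded verbatim).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as eio
from .calling import CascadeParams, run_cascade
from .cohort import assign_sensitivity
from .core import EditingMatrix
from .diffedit import (
    HIGH_SENSITIVITY,
    LOW_SENSITIVITY,
    compute_aei_all,
    differential_editing,
    select_des,
)
from .simulate import (
    SimConfig,
    SurvSimConfig,
    gen_editing_counts,
    gen_ic50,
    gen_repeat_annotation,
    gen_survival,
    write_fixtures,
)
from .survival import site_survival_scan

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A user-facing configuration problem (unknown key, bad range)."""


@dataclass(frozen=True)
class DiffParams:
    p_max: float = 0.05
    fdr_max: float = 0.1
    fc_min: float = 2.5
    fc_scale: str = "ratio"
    df: int = 2

    def __post_init__(self) -> None:
        for name in ("p_max", "fdr_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name}={v} must be in (0, 1]")
        if self.fc_min < 0:
            raise ConfigError(f"fc_min={self.fc_min} must be >= 0")
        if self.fc_scale not in ("log2", "ratio"):
            raise ConfigError(f"fc_scale={self.fc_scale!r} must be 'log2' or 'ratio'")


@dataclass(frozen=True)
class Ic50Params:
    n_drugs: int = 3
    separation: float = 3.0
    drug: str = "drug1"

    def __post_init__(self) -> None:
        if self.n_drugs < 1:
            raise ConfigError("n_drugs must be >= 1")


@dataclass(frozen=True)
class StageToggles:
    aei: bool = True
    survival: bool = True


@dataclass(frozen=True)
class RunConfig:
    outdir: str = "editscape_run"
    seed: int = 0
    simulate: SimConfig = field(default_factory=SimConfig)
    ic50: Ic50Params = field(default_factory=Ic50Params)
    calling: CascadeParams = field(default_factory=CascadeParams)
    diff: DiffParams = field(default_factory=DiffParams)
    survival: SurvSimConfig = field(default_factory=SurvSimConfig)
    n_sites_scan: int = 5
    stages: StageToggles = field(default_factory=StageToggles)


def _build(cls, data: dict, path: str):
    """Construct a (nested) dataclass from a dict, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config key(s) at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if isinstance(value, dict):
            sub_cls = _NESTED.get(name)
            if sub_cls is None:
                raise ConfigError(f"{path}{name}: unexpected mapping")
            kwargs[name] = _build(sub_cls, value, f"{path}{name}.")
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"{path or 'config'}: {err}") from None


_NESTED = {
    "simulate": SimConfig,
    "ic50": Ic50Params,
    "calling": CascadeParams,
    "diff": DiffParams,
    "survival": SurvSimConfig,
    "stages": StageToggles,
}


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config; defaults are filled and logged."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    cfg = _build(RunConfig, raw, "")
    logger.info("config validated: %s", config_to_dict(cfg))
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage sub-seeds (< 2^31) from the master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s % 2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the run manifest.

    Outputs under ``cfg.outdir``: the simulated fixtures (counts/, VCF, BED,
    ic50.tsv, survival tables), matrix.tsv + filter_report.tsv, groups.tsv,
    des.tsv, aei.tsv, site_survival.tsv, and manifest.json.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    seeds = _sub_seeds(cfg.seed, 4)
    manifest: dict = {
        "tool": "editscape",
        "version": __version__,
        "config": config_to_dict(cfg),
        "config_hash": hashlib.sha256(
            json.dumps(config_to_dict(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "sub_seeds": seeds,
        "started": started,
        "stages": {},
    }

    # --- simulate ------------------------------------------------------
    sim_cfg = dataclasses.replace(cfg.simulate, seed=seeds[0])
    matrix, truth = gen_editing_counts(sim_cfg)
    samples = sim_cfg.group1_samples + sim_cfg.group2_samples
    ic50 = gen_ic50(
        len(samples),
        n_drugs=cfg.ic50.n_drugs,
        separation=cfg.ic50.separation,
        seed=seeds[1],
        sample_ids=samples,
        n_shifted=sim_cfg.n_group1,
    )
    repeats = gen_repeat_annotation(matrix.sites, seed=seeds[1])
    fixtures = write_fixtures(outdir / "inputs", matrix, truth, ic50=ic50, repeats=repeats)
    manifest["stages"]["simulate"] = {
        "n_sites": matrix.n_sites,
        "n_samples": matrix.n_samples,
        "n_des_planted": int(truth["is_des"].sum()),
        "n_dna_variants_planted": int(truth["is_dna_variant"].sum()),
    }

    # --- ingest the fixtures back through the readers ------------------
    obs = pd.concat(
        [eio.read_site_counts(p, s) for s, p in fixtures.counts.items()], ignore_index=True
    )
    variants = eio.read_vcf_variants(fixtures.vcf)
    bed = eio.read_bed_repeats(fixtures.bed)
    ic50_in = eio.read_table(fixtures.ic50)

    # --- call ----------------------------------------------------------
    called, report = run_cascade(obs, variants, cfg.calling, sample_ids=samples)
    eio.write_matrix(called, outdir / "matrix.tsv")
    eio.write_table(report.to_frame(), outdir / "filter_report.tsv")
    manifest["stages"]["call"] = report.to_frame().to_dict("records")

    # --- group ---------------------------------------------------------
    groups = assign_sensitivity(ic50_in, cfg.ic50.drug)
    eio.write_table(groups, outdir / "groups.tsv")
    low = groups.loc[groups["label"] == LOW_SENSITIVITY, "sample_id"].tolist()
    high = groups.loc[groups["label"] == HIGH_SENSITIVITY, "sample_id"].tolist()
    manifest["stages"]["groups"] = {"n_low": len(low), "n_high": len(high)}

    # --- diff ----------------------------------------------------------
    results, skipped = differential_editing(called, low, high, df=cfg.diff.df)
    des = select_des(
        results, p_max=cfg.diff.p_max, fdr_max=cfg.diff.fdr_max,
        fc_min=cfg.diff.fc_min, fc_scale=cfg.diff.fc_scale,
    )
    des_out = des.join(matrix.sites.loc[des.index, ["chrom", "pos", "strand"]])
    eio.write_table(des_out.reset_index(), outdir / "des.tsv")
    manifest["stages"]["diff"] = {
        "n_tested": len(results),
        "n_skipped": len(skipped),
        "n_des": int(des["is_des"].sum()),
    }

    # --- aei -----------------------------------------------------------
    if cfg.stages.aei:
        aei = compute_aei_all(called, bed)
        eio.write_table(aei, outdir / "aei.tsv")
        manifest["stages"]["aei"] = {"n_samples": len(aei)}

    # --- survive -------------------------------------------------------
    if cfg.stages.survival:
        surv_cfg = dataclasses.replace(cfg.survival, seed=seeds[2])
        des_sites = des.index[des["is_des"]].tolist()[: cfg.n_sites_scan]
        if des_sites:
            rng = np.random.default_rng(seeds[3])
            patients = [f"p{i:03d}" for i in range(1, surv_cfg.n_patients + 1)]
            levels = pd.DataFrame(
                rng.beta(0.5, 0.5, size=(surv_cfg.n_patients, len(des_sites))),
                index=pd.Index(patients, name="patient_id"),
                columns=des_sites,
            )
            # the first DES site drives progression hazard; the rest are null
            surv = gen_survival(levels[des_sites[0]], surv_cfg)
            eio.write_table(surv, outdir / "patients.tsv")
            eio.write_table(levels.reset_index(), outdir / "patient_levels.tsv")
            summary, _ = site_survival_scan(levels, surv, p_max=cfg.diff.p_max)
            eio.write_table(summary, outdir / "site_survival.tsv")
            manifest["stages"]["survive"] = {
                "n_sites_scanned": len(summary),
                "n_significant": int(summary["significant"].sum()) if len(summary) else 0,
                "driver_site": des_sites[0],
            }
        else:
            manifest["stages"]["survive"] = {"n_sites_scanned": 0, "n_significant": 0}

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("run complete: %s", outdir)
    return manifest
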