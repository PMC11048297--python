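"""Readers and writers for every external file the pipeline touches.

File dialects
-------------
* **Site-count TSV** (one per sample, REDITools/bam-readcount style):
  headered, tab-delimited, columns ``chrom, pos, strand, ref_base, A, C, G, T``
  with ``pos`` 1-based.  The edited (alt) read count is resolved by the
  strand rule: the G count on ``+`` strand sites, the C count on ``-``.
* **VCF 4.2** for DNA variant lists (read via cyvcf2; written as plain text).
* **BED3+class** for repeat annotation: 0-based half-open intervals with a
  fourth column in {ALU, NON_ALU_REPEAT}.
* **Plain headered TSVs** for IC50, survival, matrices and result tables.
* **Coordinate map TSV** for assembly liftover results, consumed — never
  computed: ``chrom_old, pos_old, chrom_new, pos_new`` with the literal token
  ``FAILED`` in ``chrom_new`` for unconvertible rows.

All text is UTF-8.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import STRAND_ALLELES, EditingMatrix, GenomicSite, site_frame
from .repeats import RepeatInterval

logger = logging.getLogger(__name__)

OBS_COLUMNS = ["sample_id", "chrom", "pos", "strand", "ref_base", "ref_reads", "alt_reads"]

_BASES = ["A", "C", "G", "T"]


# ---------------------------------------------------------------------------
# site-count tables
# ---------------------------------------------------------------------------

def read_site_counts(path, sample_id: str) -> pd.DataFrame:
    """Read one sample's per-site base counts into an observation frame.

    Returns a frame with columns ``sample_id, chrom, pos, strand, ref_base,
    ref_reads, alt_reads`` — one OBSERVED row per input row.  Reads carrying
    neither the reference nor the strand-rule alternative base are ignored:
    the working total is ``ref_reads + alt_reads`` only.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("chrom", "pos", "strand", "ref_base", *_BASES) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    bad_strand = ~df["strand"].isin(STRAND_ALLELES)
    if bad_strand.any():
        line = int(df.index[bad_strand][0]) + 2  # 1-based, counting the header
        raise ValueError(f"{path}:{line}: unknown strand {df.loc[bad_strand, 'strand'].iloc[0]!r}")

    for col in _BASES + ["pos"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.allclose(vals.dropna() % 1, 0):
            line = int(df.index[vals.isna() | (vals % 1 != 0)][0]) + 2
            raise ValueError(f"{path}:{line}: non-integer value in column {col!r}")
        df[col] = vals.astype(int)

    dup = df.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValueError(f"{path}:{line}: duplicate (chrom, pos, strand)")

    expected_ref = df["strand"].map({s: a[0] for s, a in STRAND_ALLELES.items()})
    mismatch = df["ref_base"] != expected_ref
    if mismatch.any():
        line = int(df.index[mismatch][0]) + 2
        raise ValueError(
            f"{path}:{line}: ref_base {df.loc[mismatch, 'ref_base'].iloc[0]!r} "
            f"violates the strand rule (expected {expected_ref[mismatch].iloc[0]!r})"
        )

    plus = df["strand"] == "+"
    ref_reads = np.where(plus, df["A"], df["T"])
    alt_reads = np.where(plus, df["G"], df["C"])
    other = df[_BASES].sum(axis=1) - ref_reads - alt_reads
    if (n_other := int((other > 0).sum())):
        logger.info("%s: %d rows carry other-mismatch reads (ignored)", path, n_other)

    out = pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": df["chrom"],
            "pos": df["pos"],
            "strand": df["strand"],
            "ref_base": df["ref_base"],
            "ref_reads": ref_reads.astype(int),
            "alt_reads": alt_reads.astype(int),
        }
    )
    return out


def write_site_counts(obs: pd.DataFrame, path) -> None:
    """Write one sample's observation frame back to the site-count dialect."""
    plus = obs["strand"] == "+"
    table = pd.DataFrame(
        {
            "chrom": obs["chrom"],
            "pos": obs["pos"],
            "strand": obs["strand"],
            "ref_base": obs["ref_base"],
            "A": np.where(plus, obs["ref_reads"], 0),
            "C": np.where(plus, 0, obs["alt_reads"]),
            "G": np.where(plus, obs["alt_reads"], 0),
            "T": np.where(plus, 0, obs["ref_reads"]),
        }
    )
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF variants
# ---------------------------------------------------------------------------

def read_vcf_variants(path) -> set[tuple[str, int, str, str]]:
    """Read a VCF into a set of (chrom, pos, ref, alt); multi-allelic records
    are expanded to one tuple per alternative allele."""
    from cyvcf2 import VCF

    out: set[tuple[str, int, str, str]] = set()
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            out.add((rec.CHROM, rec.POS, rec.REF, alt))
    return out


def write_vcf_variants(variants: Iterable[tuple[str, int, str, str]], path) -> None:
    """Write (chrom, pos, ref, alt) tuples as a minimal VCF 4.2 file."""
    rows = sorted(variants)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({r[0] for r in rows}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# BED repeat annotation
# ---------------------------------------------------------------------------

def read_bed_repeats(path) -> list[RepeatInterval]:
    """Read BED3+class repeat intervals (0-based half-open, kept verbatim;
    overlapping intervals are accepted without merging)."""
    out: list[RepeatInterval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, start, end, cls = parts[:4]
            try:
                out.append(RepeatInterval(chrom, int(start), int(end), cls))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
    return out


def write_bed_repeats(intervals: Iterable[RepeatInterval], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.repeat_class}\n")


# ---------------------------------------------------------------------------
# editing matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: EditingMatrix, path) -> None:
    """Write an EditingMatrix as a wide TSV: site metadata columns followed by
    ``<sample>.alt`` / ``<sample>.total`` pairs; empty cells are NO_COVERAGE."""
    out = matrix.sites.copy()
    for s in matrix.sample_ids:
        out[f"{s}.alt"] = matrix.alt[s]
        out[f"{s}.total"] = matrix.total[s]
    out.to_csv(path, sep="\t", index=True, float_format="%g")


def read_matrix(path) -> EditingMatrix:
    df = pd.read_csv(path, sep="\t", index_col="site_id", dtype={"chrom": str})
    meta_cols = ["chrom", "pos", "strand", "ref_base", "alt_base"]
    samples = sorted(
        {c[: -len(".alt")] for c in df.columns if c.endswith(".alt")},
        key=lambda s: list(df.columns).index(f"{s}.alt"),
    )
    alt = pd.DataFrame({s: df[f"{s}.alt"] for s in samples})
    total = pd.DataFrame({s: df[f"{s}.total"] for s in samples})
    return EditingMatrix(df[meta_cols], alt, total)


# ---------------------------------------------------------------------------
# plain tables (IC50, survival, results)
# ---------------------------------------------------------------------------

def read_table(path, **kwargs) -> pd.DataFrame:
    """Read a headered, tab-delimited table."""
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# coordinate maps (assembly liftover results, precomputed)
# ---------------------------------------------------------------------------

FAILED = "FAILED"


def read_coord_map(path) -> dict[tuple[str, int], tuple[str, int] | None]:
    """Read an old→new coordinate mapping table; FAILED rows map to None."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom_old": str, "chrom_new": str})
    cmap: dict[tuple[str, int], tuple[str, int] | None] = {}
    for row in df.itertuples(index=False):
        key = (row.chrom_old, int(row.pos_old))
        if row.chrom_new == FAILED:
            cmap[key] = None
        else:
            cmap[key] = (row.chrom_new, int(row.pos_new))
    mapped = [v for v in cmap.values() if v is not None]
    if len(set(mapped)) != len(mapped):
        raise ValueError(f"{path}: coordinate map is not injective on mapped rows")
    return cmap


def apply_coord_map(
    sites: list[GenomicSite], cmap: dict[tuple[str, int], tuple[str, int] | None]
) -> tuple[list[GenomicSite], list[GenomicSite]]:
    """Partition sites into (mapped, failed) under a precomputed coordinate map.

    Sites absent from the map, or present with a FAILED target, go to the
    failed partition; mapped sites keep their strand (and hence alleles).
    """
    mapped: list[GenomicSite] = []
    failed: list[GenomicSite] = []
    for s in sites:
        target = cmap.get((s.chrom, s.pos))
        if target is None:
            failed.append(s)
        else:
            mapped.append(GenomicSite(target[0], target[1], s.strand))
    logger.info("coordinate map: %d converted, %d failed", len(mapped), len(failed))
    return mapped, failed


__all__ = [
    "read_site_counts",
    "write_site_counts",
    "read_vcf_variants",
    "write_vcf_variants",
    "read_bed_repeats",
    "write_bed_repeats",
    "write_matrix",
    "read_matrix",
    "read_table",
    "write_table",
    "read_coord_map",
    "apply_coord_map",
    "site_frame",
]
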