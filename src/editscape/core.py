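"""Core in-memory model: genomic sites, the editing matrix, filter reports.

A>I(G) editing is read out of RNA-seq as A>G mismatches on the plus strand
and T>C mismatches on the minus strand.  Every site in the model therefore
carries a strand, and its reference/alternative alleles are fully determined
by that strand (``+`` => A>G, ``-`` => T>C).

Positions are 1-based throughout the in-memory model (VCF-style); BED input
is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allele pair implied by each strand: ref on +/− is A/T, alt is G/C.
STRAND_ALLELES = {"+": ("A", "G"), "-": ("T", "C")}

SITE_COLUMNS = ["chrom", "pos", "strand", "ref_base", "alt_base"]


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A strand-aware candidate editing site (1-based position)."""

    chrom: str
    pos: int
    strand: str
    ref_base: str = field(default="", compare=False)
    alt_base: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.strand not in STRAND_ALLELES:
            raise ValueError(f"unknown strand {self.strand!r} at {self.chrom}:{self.pos}")
        ref, alt = STRAND_ALLELES[self.strand]
        object.__setattr__(self, "ref_base", self.ref_base or ref)
        object.__setattr__(self, "alt_base", self.alt_base or alt)
        if (self.ref_base, self.alt_base) != (ref, alt):
            raise ValueError(
                f"site {self.chrom}:{self.pos}{self.strand} carries alleles "
                f"{self.ref_base}>{self.alt_base}; strand rule requires {ref}>{alt}"
            )

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.strand}"

    @classmethod
    def from_id(cls, site_id: str) -> "GenomicSite":
        chrom, pos, strand = site_id.rsplit(":", 2)
        return cls(chrom, int(pos), strand)


def site_frame(sites: list[GenomicSite]) -> pd.DataFrame:
    """Index a list of sites into the canonical site-metadata frame."""
    df = pd.DataFrame(
        [(s.chrom, s.pos, s.strand, s.ref_base, s.alt_base) for s in sites],
        columns=SITE_COLUMNS,
        index=pd.Index([s.site_id for s in sites], name="site_id"),
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sites: {dups[:5]}")
    return df


class EditingMatrix:
    """Sites x samples matrix of (edited, total) read counts.

    Cells are either OBSERVED, with ``total >= alt >= 0`` (``alt == 0`` is a
    covered reference/reference position, distinct from missing), or
    NO_COVERAGE, stored as NaN in both count layers.
    """

    def __init__(self, sites: pd.DataFrame, alt: pd.DataFrame, total: pd.DataFrame):
        if not sites.index.equals(alt.index) or not sites.index.equals(total.index):
            raise ValueError("site index mismatch between metadata and count layers")
        if not alt.columns.equals(total.columns):
            raise ValueError("sample columns differ between alt and total layers")
        if alt.index.has_duplicates or alt.columns.has_duplicates:
            raise ValueError("site and sample indices must be unique")
        with np.errstate(invalid="ignore"):
            bad = (total.to_numpy() < alt.to_numpy()) | (alt.to_numpy() < 0)
        if np.any(bad & ~np.isnan(alt.to_numpy())):
            raise ValueError("observed cells require total >= alt >= 0")
        self.sites = sites
        self.alt = alt.astype(float)
        self.total = total.astype(float)

    # -- basic geometry -------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return list(self.sites.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.alt.columns)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return self.alt.shape[1]

    def observed(self) -> pd.DataFrame:
        """Boolean mask of cells with coverage."""
        return self.total.notna() & (self.total > 0)

    def editing_levels(self) -> pd.DataFrame:
        """Per-cell editing level alt/(alt+ref) = alt/total; NaN where missing."""
        with np.errstate(invalid="ignore", divide="ignore"):
            lev = self.alt / self.total
        return lev.where(self.observed())

    def subset_sites(self, site_ids) -> "EditingMatrix":
        idx = pd.Index(site_ids)
        return EditingMatrix(self.sites.loc[idx], self.alt.loc[idx], self.total.loc[idx])

    def subset_samples(self, sample_ids) -> "EditingMatrix":
        cols = list(sample_ids)
        return EditingMatrix(self.sites, self.alt[cols], self.total[cols])

    def equals(self, other: "EditingMatrix") -> bool:
        return (
            self.sites.equals(other.sites)
            and self.alt.equals(other.alt)
            and self.total.equals(other.total)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"EditingMatrix({self.n_sites} sites x {self.n_samples} samples)"


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


class FilterReport:
    """Audit trail of the site-filter cascade: input − removed = output per stage."""

    def __init__(self) -> None:
        self.stages: list[FilterStage] = []

    def add(self, name: str, n_in: int, n_removed: int) -> None:
        if self.stages and self.stages[-1].n_out != n_in:
            raise ValueError(
                f"stage {name!r} input {n_in} does not match previous output "
                f"{self.stages[-1].n_out}"
            )
        if n_removed < 0 or n_removed > n_in:
            raise ValueError(f"stage {name!r}: removed {n_removed} of {n_in}")
        self.stages.append(FilterStage(name, n_in, n_removed))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_in, s.n_removed, s.n_out) for s in self.stages],
            columns=["stage", "n_in", "n_removed", "n_out"],
        )

    def __getitem__(self, name: str) -> FilterStage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)
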