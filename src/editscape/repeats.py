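"""Repeat-element annotation: Alu / non-Alu repeat / non-repetitive.

Intervals follow the BED convention — 0-based, half-open — while sites are
1-based, so a site at position ``p`` overlaps ``[start, end)`` iff
``start <= p - 1 < end``.  When a site falls in both an ALU and a non-Alu
repeat interval, ALU wins (Alu elements are the dominant editing substrate
and the classification of interest).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from intervaltree import IntervalTree

ALU = "ALU"
NON_ALU_REPEAT = "NON_ALU_REPEAT"
NON_REPETITIVE = "NON_REPETITIVE"

REPEAT_CLASSES = (ALU, NON_ALU_REPEAT)


@dataclass(frozen=True)
class RepeatInterval:
    """A repeat-annotation interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    repeat_class: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")


class RepeatIndex:
    """Chromosome-keyed interval trees for overlap queries on repeat intervals."""

    def __init__(self, intervals: Iterable[RepeatInterval]):
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv.repeat_class
            )

    def classify(self, chrom: str, pos: int) -> str:
        """Repeat class of a 1-based site position; ALU has precedence."""
        tree = self._trees.get(chrom)
        if tree is None:
            return NON_REPETITIVE
        hits = {h.data for h in tree.at(pos - 1)}
        if ALU in hits:
            return ALU
        if NON_ALU_REPEAT in hits:
            return NON_ALU_REPEAT
        return NON_REPETITIVE


def annotate_repeat_class(sites, repeats: Iterable[RepeatInterval]) -> "pd.Series":
    """Classify each site of a site-metadata frame by repeat overlap.

    Parameters
    ----------
    sites : pandas.DataFrame
        Site metadata with ``chrom`` and 1-based ``pos`` columns
        (``EditingMatrix.sites``).
    repeats : iterable of RepeatInterval

    Returns
    -------
    pandas.Series of {ALU, NON_ALU_REPEAT, NON_REPETITIVE} indexed like `sites`.
    """
    import pandas as pd

    index = RepeatIndex(repeats)
    return pd.Series(
        [index.classify(c, p) for c, p in zip(sites["chrom"], sites["pos"])],
        index=sites.index,
        name="repeat_class",
    )
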