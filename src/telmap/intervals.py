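"""Genomic intervals with 1-based closed-coordinate conventions.

All interval arithmetic in this package uses 1-based, fully closed
intervals, matching the coordinate style of published genome-browser
positions. Width is reported as ``upper - lower`` (not ``+ 1``), the
convention under which the printed kb figures of transposon-mapping
studies round correctly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class ChromosomeMismatchError(ValueError):
    """Raised when two features on different chromosomes are compared."""


def normalize_chrom(label: str) -> str:
    """Strip a ``chr`` prefix so ``chr3R`` and ``3R`` compare equal."""
    return label[3:] if label.lower().startswith("chr") else label


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based closed interval ``[lower, upper]`` on one chromosome."""

    chrom: str
    lower: int
    upper: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(
                f"interval lower bound {self.lower} exceeds upper bound {self.upper}"
            )
        if self.lower < 1:
            raise ValueError("coordinates are 1-based; lower bound must be >= 1")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    def __contains__(self, pos: int) -> bool:
        return self.lower <= pos <= self.upper

    @property
    def width(self) -> int:
        return self.upper - self.lower

    def to_bed(self) -> tuple[str, int, int]:
        """Convert to BED convention: 0-based half-open (chrom, start, end)."""
        return (self.chrom, self.lower - 1, self.upper)


def interval_width_kb(interval: GenomicInterval) -> int:
    """Interval width in kb, rounded half away from zero.

    ``(upper - lower) / 1000`` rounded to the nearest integer; e.g. a
    15,034 bp span prints as 15 kb and a 315,556 bp span as 316 kb.
    """
    w = interval.width / 1000.0
    return int(math.floor(w + 0.5))


def locus_overlap(feature: GenomicInterval, target: GenomicInterval) -> str:
    """Classify how ``feature`` (e.g. a deletion) intersects ``target``.

    Returns ``"covers"`` when the feature contains the whole target,
    ``"disjoint"`` when the closed intervals do not intersect, and
    ``"partial"`` otherwise. Used to book-keep engineered deletions
    against a candidate locus (does the deletion remove it, miss it, or
    clip it).
    """
    if feature.chrom != target.chrom:
        raise ChromosomeMismatchError(
            f"cannot compare {feature.chrom} with {target.chrom}"
        )
    if feature.upper < target.lower or feature.lower > target.upper:
        return "disjoint"
    if feature.lower <= target.lower and feature.upper >= target.upper:
        return "covers"
    return "partial"
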