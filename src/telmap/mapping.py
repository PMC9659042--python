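"""Interval mapping from transposon-induced male recombination.

In *Drosophila* males there is no meiotic recombination, so a
recombinant chromosome recovered from a transposon-bearing
heterozygous male arose at a transposase-induced double-strand break
at the (known) insertion site. A recombinant's flanking eye-colour
marker (``st`` or ``ca``) tells which side of the break derives from
the mutant chromosome; whether that recombinant shows the telomere-
elongation phenotype therefore reveals which side of the insertion the
mutation lies on.

Each informative insertion yields a *side call*: ``Left`` (mutation at
lower coordinates than the insertion) or ``Right`` (higher). Combining
calls, the candidate region is bounded below by the rightmost ``Right``
insertion and above by the leftmost ``Left`` insertion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval, normalize_chrom
from .qpcr import ElongationCall

LEFT = "Left"
RIGHT = "Right"
AMBIGUOUS = "Ambiguous"

MARKER_CLASSES = ("st", "ca")


class UnboundedIntervalError(ValueError):
    """Side calls bound the candidate region on one side only."""


class InconsistentCallsError(ValueError):
    """Side calls admit no coordinate (lower bound >= upper bound)."""


@dataclass(frozen=True)
class TransposonInsertion:
    """One mapped transposon insertion used to induce recombination.

    ``coordinate`` is a 1-based point; insertions whose mapped position
    is a short range carry (low, high) in ``coordinate_range`` instead.
    ``mapping_round`` groups insertions by the experiment round in
    which they were used.
    """

    name: str
    family: str  # "P" or "Minos"
    chrom: str
    coordinate: int | None = None
    coordinate_range: tuple[int, int] | None = None
    mapping_round: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if (self.coordinate is None) == (self.coordinate_range is None):
            raise ValueError(
                f"{self.name}: give exactly one of coordinate / coordinate_range"
            )
        if self.coordinate is not None and self.coordinate < 1:
            raise ValueError(f"{self.name}: coordinate must be positive")
        if self.coordinate_range is not None:
            lo, hi = self.coordinate_range
            if not (1 <= lo <= hi):
                raise ValueError(f"{self.name}: bad coordinate range ({lo}, {hi})")

    @property
    def low(self) -> int:
        """Low end of the insertion position (the point itself if exact)."""
        return self.coordinate if self.coordinate is not None else self.coordinate_range[0]

    @property
    def high(self) -> int:
        return self.coordinate if self.coordinate is not None else self.coordinate_range[1]


@dataclass(frozen=True)
class SideCall:
    """Which side of an insertion the mutation lies on, with support.

    ``counts`` maps marker class -> (n elongated, n total).
    """

    insertion_name: str
    call: str  # Left | Right | Ambiguous
    counts: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.call not in (LEFT, RIGHT, AMBIGUOUS):
            raise ValueError(f"bad side call {self.call!r}")


@dataclass(frozen=True)
class MappedInterval:
    """Candidate interval implied by combined side calls."""

    interval: GenomicInterval
    lower_insertion: str
    upper_insertion: str
    contributing: tuple[str, ...]

    @property
    def lower(self) -> int:
        return self.interval.lower

    @property
    def upper(self) -> int:
        return self.interval.upper


def _class_status(calls: Sequence[ElongationCall]) -> str:
    """'elongated' | 'flat' | 'mixed' | 'none' for one marker class."""
    if not calls:
        return "none"
    flags = {c.elongated for c in calls}
    if flags == {True}:
        return "elongated"
    if flags == {False}:
        return "flat"
    return "mixed"


def infer_side(
    insertion: TransposonInsertion,
    recombinants: Mapping[str, Sequence[ElongationCall]],
    low_side_marker: str = "st",
) -> SideCall:
    """Infer the mutation's side from marker-classed elongation calls.

    ``recombinants`` maps marker class to that class's elongation
    calls. ``low_side_marker`` names the marker class whose recombinant
    chromosomes retain the mutant chromosome's low-coordinate side —
    marker geometry is genetic background, supplied as configuration,
    never inferred from the data.

    A marker class is informative when all its recombinants agree. The
    low-side class elongated implies the mutation sits on the low side
    (``Left``); low-side flat implies ``Right``; the high-side class
    mirrors this. Internal disagreement within a class, or conflict
    between classes, yields ``Ambiguous`` (reported with counts, never
    silently dropped).
    """
    total = sum(len(v) for v in recombinants.values())
    if total == 0:
        raise ValueError(f"{insertion.name}: no recombinants with elongation calls")
    counts = {
        cls: (sum(c.elongated for c in calls), len(calls))
        for cls, calls in recombinants.items()
    }
    votes = set()
    for cls, calls in recombinants.items():
        status = _class_status(calls)
        if status == "mixed":
            return SideCall(insertion.name, AMBIGUOUS, counts)
        if status == "none":
            continue
        low_side = cls == low_side_marker
        elongated = status == "elongated"
        # mutant allele retained on the low side iff (low-side class and
        # elongated) or (high-side class and flat)
        votes.add(LEFT if low_side == elongated else RIGHT)
    if len(votes) != 1:
        return SideCall(insertion.name, AMBIGUOUS, counts)
    return SideCall(insertion.name, votes.pop(), counts)


def combine_sides(
    calls: Iterable[tuple[TransposonInsertion, SideCall]],
    rounds: set[int] | None = None,
) -> MappedInterval:
    """Combine per-insertion side calls into the minimal candidate interval.

    The lower bound is the maximum coordinate among ``Right`` calls and
    the upper bound the minimum among ``Left`` calls; range-valued
    insertion coordinates contribute their conservative end (range high
    for ``Right``, range low for ``Left``) so the interval can never
    exclude the true locus. ``Ambiguous`` calls are ignored. ``rounds``
    restricts to a subset of mapping rounds.
    """
    pairs = [
        (ins, sc) for ins, sc in calls
        if rounds is None or ins.mapping_round in rounds
    ]
    if not pairs:
        raise ValueError("no side calls after round filtering")
    chroms = {ins.chrom for ins, _ in pairs}
    if len(chroms) != 1:
        raise ValueError(f"insertions span multiple chromosomes: {sorted(chroms)}")
    rights = [(ins.high, ins.name) for ins, sc in pairs if sc.call == RIGHT]
    lefts = [(ins.low, ins.name) for ins, sc in pairs if sc.call == LEFT]
    if not rights or not lefts:
        missing = "Right" if not rights else "Left"
        raise UnboundedIntervalError(
            f"interval unbounded: no {missing} side call among "
            f"{[ins.name for ins, _ in pairs]}"
        )
    lower, lower_name = max(rights)
    upper, upper_name = min(lefts)
    if lower >= upper:
        raise InconsistentCallsError(
            f"inconsistent side calls: Right call at {lower} ({lower_name}) is not "
            f"below Left call at {upper} ({upper_name})"
        )
    contributing = tuple(
        ins.name for ins, sc in pairs if sc.call in (LEFT, RIGHT)
    )
    return MappedInterval(
        interval=GenomicInterval(chroms.pop(), lower, upper),
        lower_insertion=lower_name,
        upper_insertion=upper_name,
        contributing=contributing,
    )
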