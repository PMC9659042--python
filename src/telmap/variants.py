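"""Variant representation and left-alignment normalization.

Indel calls from different callers (or from manual alignment
inspection) frequently describe the same haplotype with different
(pos, ref, alt) tuples — right-shifted through a repeat, or padded
with redundant shared bases. Every set operation in this package
(control subtraction, panel exclusion) therefore keys variants by
their *normalized* identity: minimal representation, shifted as far
left as the repeat context allows, with one anchor base retained for
indels (the VCF convention).

The normalization here is the standard left-align/trim algorithm:

1. trim the shared suffix of ref and alt (extending left through the
   reference whenever one allele would become empty);
2. trim the shared prefix, keeping at least one base in each allele.

The procedure is idempotent and haplotype-preserving: applying the
variant to the reference before or after normalization yields the
same sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator

from .intervals import GenomicInterval, normalize_chrom

_BASES = frozenset("ACGTN")


class ReferenceMismatchError(ValueError):
    """A variant's ref allele disagrees with the reference sequence."""


@dataclass(frozen=True, order=True)
class Variant:
    """One VCF-style variant record.

    ``pos`` is the 1-based position of the first ref base (for indels,
    the anchor base preceding the inserted/deleted sequence once
    normalized). ``ref`` and ``alt`` are non-empty uppercase sequences.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        bad = (set(self.ref) | set(self.alt)) - _BASES
        if bad:
            raise ValueError(f"non-ACGTN characters {sorted(bad)} at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def variant_class(self) -> str:
        """One of ``SNP``, ``insertion``, ``deletion``, ``MNP``."""
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNP"
        if len(self.ref) < len(self.alt):
            return "insertion"
        if len(self.ref) > len(self.alt):
            return "deletion"
        return "MNP"

    @property
    def is_indel(self) -> bool:
        return self.variant_class in ("insertion", "deletion")

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def affected_span(self) -> GenomicInterval:
        """Closed interval of reference bases the variant touches."""
        return GenomicInterval(self.chrom, self.pos, self.pos + len(self.ref) - 1)

    def __str__(self) -> str:  # pragma: no cover - display only
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


class RegionSequence:
    """A reference segment with a genomic origin, addressable in
    genomic (1-based) coordinates.

    ``origin`` is the genomic coordinate of the first base of ``seq``,
    so a 79 kb window of a chromosome arm can be carried around without
    the rest of the arm.
    """

    def __init__(self, chrom: str, origin: int, seq: str):
        if origin < 1:
            raise ValueError("origin is a 1-based genomic coordinate")
        self.chrom = normalize_chrom(chrom)
        self.origin = origin
        self.seq = seq.upper()

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        """Genomic coordinate of the last base."""
        return self.origin + len(self.seq) - 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.origin, self.end)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of the closed genomic interval [start, end]."""
        if start < self.origin or end > self.end:
            raise IndexError(
                f"[{start}, {end}] outside region {self.chrom}:{self.origin}-{self.end}"
            )
        if start > end:
            raise IndexError("start > end")
        return self.seq[start - self.origin : end - self.origin + 1]

    def base(self, pos: int) -> str:
        return self.fetch(pos, pos)


def normalize_variant(v: Variant, reference: RegionSequence) -> Variant:
    """Left-align and minimalize a variant against ``reference``.

    Raises :class:`ReferenceMismatchError` if the ref allele does not
    match the reference at ``v.pos``. Idempotent; SNPs pass through
    unchanged.
    """
    if v.chrom != reference.chrom:
        raise ReferenceMismatchError(
            f"variant chromosome {v.chrom} does not match reference {reference.chrom}"
        )
    expected = reference.fetch(v.pos, v.pos + len(v.ref) - 1)
    if expected != v.ref:
        raise ReferenceMismatchError(
            f"ref allele {v.ref} at {v.chrom}:{v.pos} disagrees with reference {expected}"
        )
    pos, ref, alt = v.pos, v.ref, v.alt
    # Trim shared suffix, sliding left through repeats when an allele empties.
    while ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        last = ref[-1]
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos == reference.origin:
                # Cannot extend further left; undo the last trim.
                ref, alt = ref + last, alt + last
                break
            pos -= 1
            pad = reference.base(pos)
            ref, alt = pad + ref, pad + alt
    # Trim shared prefix, keeping one anchor base per allele.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(v, pos=pos, ref=ref, alt=alt)


def apply_variant(seq: str, origin: int, v: Variant) -> str:
    """Reconstruct the alternate haplotype: substitute ``alt`` for
    ``ref`` at the variant's position within ``seq`` (whose first base
    sits at genomic coordinate ``origin``).

    This is the brute-force haplotype oracle used to prove two
    representations equivalent; it is deliberately independent of
    :func:`normalize_variant`.
    """
    i = v.pos - origin
    if i < 0 or i + len(v.ref) > len(seq):
        raise IndexError(f"variant {v} outside sequence window")
    if seq[i : i + len(v.ref)].upper() != v.ref:
        raise ReferenceMismatchError(f"ref mismatch applying {v}")
    return seq[:i] + v.alt + seq[i + len(v.ref) :]


class VariantSet:
    """A strain's variants keyed by normalized identity.

    The container refuses duplicate normalized keys; whether members
    are normalized is tracked so that set algebra can insist on it.
    """

    def __init__(self, strain_id: str, variants: Iterable[Variant] = (),
                 normalized: bool = False):
        self.strain_id = strain_id
        self.normalized = normalized
        self._by_key: dict[tuple[str, int, str, str], Variant] = {}
        for v in variants:
            self.add(v)

    def add(self, v: Variant) -> None:
        if v.key in self._by_key:
            raise ValueError(f"duplicate variant key {v.key} in set {self.strain_id!r}")
        self._by_key[v.key] = v

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[Variant]:
        return iter(sorted(self._by_key.values()))

    def __contains__(self, v: Variant) -> bool:
        return v.key in self._by_key

    def keys(self) -> set[tuple[str, int, str, str]]:
        return set(self._by_key)

    def normalize(self, reference: RegionSequence) -> "VariantSet":
        """Return a new set with every member left-aligned.

        Distinct input representations that normalize to the same key
        collapse to one record.
        """
        out = VariantSet(self.strain_id, normalized=True)
        for v in self._by_key.values():
            n = normalize_variant(v, reference)
            if n.key not in out._by_key:
                out.add(n)
        return out

    def select(self, predicate) -> "VariantSet":
        return VariantSet(
            self.strain_id,
            (v for v in self._by_key.values() if predicate(v)),
            normalized=self.normalized,
        )
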