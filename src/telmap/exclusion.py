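"""Variant exclusion: from hundreds of strain-specific variants to one
candidate.

A spontaneous dominant mutation isolated from a wild-caught strain has
no co-isogenic control, so its genome differs from the reference at
hundreds of positions across any mapped interval. The exclusion logic
here mirrors the standard population-panel strategy:

1. subtract variants shared with a (non-mutant) control strain;
2. restrict to the genetically mapped interval;
3. exclude every variant also carried by any member of a wild-derived
   panel whose phenotype is normal — a variant present in a
   phenotypically normal line cannot be the dominant causative allele;
4. annotate the survivors against gene models.

All set algebra operates on normalized variant keys (see
:mod:`telmap.variants`). Large indels that read-level callers miss are
recovered separately by globally aligning assembly contigs to the
reference region and scanning the alignment for gap runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .intervals import GenomicInterval
from .variants import (
    RegionSequence,
    Variant,
    VariantSet,
    apply_variant,
    normalize_variant,
)

SURVIVED = "survived"


class AlignmentQualityError(ValueError):
    """Contig/reference alignment identity too low to trust gap calls."""


@dataclass(frozen=True)
class PanelLine:
    """One wild-derived panel member used for exclusion.

    ``phenotype`` is ``"normal"`` or ``"outlier"`` (from the copy-number
    screen); outlier lines must not contribute to exclusion sets, since
    they may carry the causative allele themselves. ``variants`` may be
    SNP-only for panels without indel calls; ``windows`` optionally
    holds local sequence around candidate indels for presence testing.
    """

    line_id: str
    phenotype: str
    variants: VariantSet
    windows: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.phenotype not in ("normal", "outlier"):
            raise ValueError(f"phenotype must be 'normal' or 'outlier', got {self.phenotype!r}")


@dataclass(frozen=True)
class Annotation:
    kind: str  # exonic | intronic | intergenic
    gene: str | None = None
    exon_index: int | None = None
    intron_index: int | None = None
    left_gene: str | None = None
    left_distance: float = float("inf")
    right_gene: str | None = None
    right_distance: float = float("inf")


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: ordered exons on one chromosome.

    Exons are 1-based closed (start, end) pairs in genomic order;
    intron *i* lies between exon *i* and exon *i + 1* (1-based count in
    genomic orientation).
    """

    gene_id: str
    chrom: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        object.__setattr__(self, "exons", exons)
        for (a, b), (c, _) in zip(exons, exons[1:]):
            if b >= c:
                raise ValueError(f"{self.gene_id}: exons overlap or touch")
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a_end + 1, b_start - 1)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
        )


@dataclass
class CandidateReport:
    """Survivors plus an exact provenance partition of every input
    variant: each key maps to ``"survived"`` or the filter that removed
    it (e.g. ``"in_control"``, ``"outside_interval"``,
    ``"in_panel:RAL-307"``)."""

    survivors: VariantSet
    provenance: dict[tuple, str] = field(default_factory=dict)
    annotations: dict[tuple, Annotation] = field(default_factory=dict)


def _require_normalized(*sets: VariantSet) -> None:
    for s in sets:
        if not s.normalized:
            raise ValueError(
                f"variant set {s.strain_id!r} is not normalized; call .normalize() first"
            )


def subtract_control(
    mutant: VariantSet, control: VariantSet
) -> tuple[VariantSet, dict[tuple, str]]:
    """Drop mutant variants whose normalized key also occurs in the
    control strain; returns (remaining set, provenance for removed+kept)."""
    _require_normalized(mutant, control)
    control_keys = control.keys()
    provenance: dict[tuple, str] = {}
    out = VariantSet(mutant.strain_id, normalized=True)
    for v in mutant:
        if v.key in control_keys:
            provenance[v.key] = "in_control"
        else:
            out.add(v)
            provenance[v.key] = SURVIVED
    return out, provenance


def restrict_to_interval(
    vset: VariantSet, interval: GenomicInterval
) -> tuple[VariantSet, dict[tuple, str]]:
    """Keep variants lying within the closed interval.

    A variant is kept when any base of its affected reference span is
    inside the interval, so a deletion straddling a boundary is never
    discarded — conservative with respect to a manual scan of the
    region. Variants on another chromosome are dropped (flagged in
    provenance).
    """
    provenance: dict[tuple, str] = {}
    out = VariantSet(vset.strain_id, normalized=vset.normalized)
    for v in vset:
        if v.chrom != interval.chrom:
            provenance[v.key] = "other_chromosome"
            continue
        span = v.affected_span
        if span.upper < interval.lower or span.lower > interval.upper:
            provenance[v.key] = "outside_interval"
        else:
            out.add(v)
            provenance[v.key] = SURVIVED
    return out, provenance


def exclude_by_panel(
    vset: VariantSet,
    panel: list[PanelLine],
    classes: str = "both",
) -> CandidateReport:
    """Exclude variants carried by any phenotypically normal panel line.

    ``classes`` selects which variant classes this panel is allowed to
    exclude: ``"SNP"``, ``"indel"``, or ``"both"`` — SNP and indel
    exclusion typically rest on different panel subsets (dense SNP
    genotypes exist for many lines, indel calls for few), so callers
    run this once per class with the appropriate lines.

    Outlier-phenotype lines are ignored. An empty (or all-outlier)
    panel excludes nothing.
    """
    if classes not in ("SNP", "indel", "both"):
        raise ValueError(f"classes must be 'SNP', 'indel' or 'both', got {classes!r}")
    _require_normalized(vset)
    usable = [ln for ln in panel if ln.phenotype == "normal"]
    for ln in usable:
        _require_normalized(ln.variants)

    def in_scope(v: Variant) -> bool:
        if classes == "both":
            return True
        return v.is_indel if classes == "indel" else v.variant_class == "SNP"

    provenance: dict[tuple, str] = {}
    out = VariantSet(vset.strain_id, normalized=True)
    for v in vset:
        hit = None
        if in_scope(v):
            for ln in usable:
                if v in ln.variants:
                    hit = ln.line_id
                    break
        if hit is None:
            out.add(v)
            provenance[v.key] = SURVIVED
        else:
            provenance[v.key] = f"in_panel:{hit}"
    return CandidateReport(survivors=out, provenance=provenance)


def _gap_aligner(match: float = 1.0, mismatch: float = -2.0,
                 gap_open: float = -6.0, gap_extend: float = -0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def discover_large_indels(
    query: str,
    reference: RegionSequence,
    min_len: int = 5,
    aligner: Align.PairwiseAligner | None = None,
) -> list[Variant]:
    """Find indels of >= ``min_len`` bp by global contig-to-reference
    alignment.

    Read-level callers are reliable only for indels of a few bp; larger
    events are recovered here the way a manual inspection of a contig
    alignment finds them — as gap runs in a global pairwise alignment
    (affine penalties chosen so an isolated >=5 bp gap beats scattered
    mismatches). Each qualifying gap run becomes one anchored,
    normalized :class:`Variant`. Gap runs touching either alignment end
    are ignored (contig overhangs, not variants).

    Quadratic in sequence length: intended for contig-vs-region-window
    comparisons (kb scale), not chromosome arms.
    """
    if not query or not len(reference.seq):
        raise ValueError("query and reference must be non-empty")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    query = query.upper()
    if aligner is None:
        aligner = _gap_aligner()
    alignment = aligner.align(reference.seq, query)[0]
    t_blocks, q_blocks = alignment.aligned

    # identity over aligned columns
    matched = sum(
        1
        for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks)
        for i in range(t1 - t0)
        if reference.seq[t0 + i] == query[q0 + i]
    )
    aligned_cols = sum(t1 - t0 for t0, t1 in t_blocks)
    if aligned_cols == 0 or matched / aligned_cols < 0.2:
        raise AlignmentQualityError(
            "alignment identity below 20%; query likely from a different region"
        )

    variants: list[Variant] = []
    for k in range(len(t_blocks) - 1):
        t_gap_start, t_gap_end = t_blocks[k][1], t_blocks[k + 1][0]
        q_gap_start, q_gap_end = q_blocks[k][1], q_blocks[k + 1][0]
        del_len = t_gap_end - t_gap_start
        ins_len = q_gap_end - q_gap_start
        if max(del_len, ins_len) < min_len or del_len == ins_len:
            continue  # small gap, or a pure substitution block
        if t_gap_start == 0 or q_gap_start == 0:
            continue  # terminal
        anchor_t = t_gap_start - 1  # 0-based index of base before the gap
        anchor_pos = reference.origin + anchor_t
        anchor_base = reference.seq[anchor_t]
        ref_allele = anchor_base + reference.seq[t_gap_start:t_gap_end]
        alt_allele = anchor_base + query[q_gap_start:q_gap_end]
        v = Variant(reference.chrom, anchor_pos, ref_allele, alt_allele)
        variants.append(normalize_variant(v, reference))
    return sorted(variants)


def indel_presence_in_window(
    v: Variant,
    window: str,
    reference: RegionSequence,
    flank: int = 200,
    core: int = 20,
) -> str:
    """Test whether a locally assembled panel window carries a candidate
    indel: ``"present"``, ``"absent"`` or ``"undetermined"``.

    Builds the reference haplotype and the variant-applied (alternate)
    haplotype over +-``flank`` bp and asks which diagnostic core —
    +-``core`` bp around the edit — the window contains as an exact
    substring. Containing both (uninformative repeat context) or
    neither (e.g. an unrelated SNP inside the core) is
    ``"undetermined"``.
    """
    window = window.upper()
    span = v.affected_span
    ref_start = max(reference.origin, span.lower - flank)
    ref_end = min(reference.end, span.upper + flank)
    ref_hap = reference.fetch(ref_start, ref_end)
    alt_hap = apply_variant(ref_hap, ref_start, v)

    core_start = max(reference.origin, span.lower - core)
    core_end = min(reference.end, span.upper + core)
    ref_core = reference.fetch(core_start, core_end)
    # corresponding slice of the alternate haplotype: same left offset,
    # length adjusted by the net indel length
    left = core_start - ref_start
    alt_core_len = (core_end - core_start + 1) + (len(v.alt) - len(v.ref))
    alt_core = alt_hap[left : left + alt_core_len]

    has_ref = ref_core in window
    has_alt = alt_core in window
    if has_alt and not has_ref:
        return "present"
    if has_ref and not has_alt:
        return "absent"
    return "undetermined"


def annotate_candidates(
    vset: VariantSet, genes: list[GeneModel]
) -> CandidateReport:
    """Label each variant exonic / intronic / intergenic against gene
    models, with intron index where applicable and flanking-gene
    distances for intergenic variants.

    The classified position is the first altered base (for indels, the
    base after the anchor). With no gene model on the variant's
    chromosome the variant is intergenic with infinite distances.
    """
    report = CandidateReport(survivors=vset)
    for v in vset:
        edit_pos = v.pos if v.variant_class in ("SNP", "MNP") else v.pos + 1
        ann = None
        for g in (g for g in genes if g.chrom == v.chrom):
            if not (g.start <= edit_pos <= g.end):
                continue
            for i, (a, b) in enumerate(g.exons, start=1):
                if a <= edit_pos <= b:
                    ann = Annotation(kind="exonic", gene=g.gene_id, exon_index=i)
                    break
            if ann is None:
                for i, (a, b) in enumerate(g.introns, start=1):
                    if a <= edit_pos <= b:
                        ann = Annotation(kind="intronic", gene=g.gene_id, intron_index=i)
                        break
            if ann is not None:
                break
        if ann is None:
            left = [(edit_pos - g.end, g.gene_id) for g in genes
                    if g.chrom == v.chrom and g.end < edit_pos]
            right = [(g.start - edit_pos, g.gene_id) for g in genes
                     if g.chrom == v.chrom and g.start > edit_pos]
            ld, lg = min(left) if left else (float("inf"), None)
            rd, rg = min(right) if right else (float("inf"), None)
            ann = Annotation(kind="intergenic", left_gene=lg, left_distance=ld,
                             right_gene=rg, right_distance=rd)
        report.annotations[v.key] = ann
        report.provenance[v.key] = SURVIVED
    return report


def contig_n50(lengths: list[int]) -> int:
    """Assembly N50: the largest length L such that contigs >= L sum to
    at least half the total assembly length."""
    if not lengths:
        raise ValueError("no contig lengths given")
    if any(x <= 0 for x in lengths):
        raise ValueError("contig lengths must be positive")
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    return int(arr[int(np.searchsorted(csum, half))])
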