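"""Synthetic study generator.

Every stage of the identification pipeline — elongation trajectories,
side calls, interval combination, control subtraction, panel exclusion,
annotation — can be exercised end to end on a synthetic study whose
ground truth is known. The generator emulates the statistical structure
the analysis assumes:

* a reference segment of ~79 kb on one chromosome arm;
* a mutant strain carrying ~626 background SNPs and ~115 background
  indels against that segment plus exactly one planted causative
  variant (default: a 3 bp deletion of a ``TGT`` motif written into an
  intron of a synthetic ten-exon gene model);
* a control strain sharing roughly half of the background variants and
  never the causative;
* a wild-derived panel whose lines each carry a random subset of the
  background variants — optionally with *guaranteed coverage*, forcing
  every background variant into at least one line so that panel
  exclusion provably strips all of them — and never the causative;
* panel copy numbers drawn log-normally with a few planted high
  outliers;
* recombinant stocks per transposon insertion whose marker class
  determines whether they retained the causative allele, with dCt
  trajectories drifting downward over generations for elongated stocks
  and flat otherwise.

Randomness derives from one integer seed; each layer draws from its own
spawned substream, so e.g. enlarging the panel does not perturb the
mutant variant layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .exclusion import GeneModel, PanelLine
from .intervals import GenomicInterval
from .mapping import MARKER_CLASSES, TransposonInsertion
from .qpcr import CtMeasurement
from .variants import RegionSequence, Variant, VariantSet, normalize_variant

logger = logging.getLogger(__name__)

TARGET_GENE = "HeT-A_gag"
REFERENCE_GENE = "RpS17"

# substream labels
_L_REFERENCE = 0
_L_MUTANT = 1
_L_CONTROL = 2
_L_PANEL = 3
_L_COVERAGE = 4
_L_COPYNUM = 5
_L_RECOMB = 6


@dataclass(frozen=True)
class CausativeSpec:
    """The planted causative edit.

    ``position`` is the genomic coordinate of the first affected base.
    ``ref_seq`` (bases removed/replaced; written into the reference at
    ``position`` so the edit is guaranteed to exist there) and
    ``alt_seq`` (bases inserted) must not both be empty. The default
    elsewhere is a 3 bp deletion of ``TGT``.
    """

    position: int
    ref_seq: str = "TGT"
    alt_seq: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_seq", self.ref_seq.upper())
        object.__setattr__(self, "alt_seq", self.alt_seq.upper())
        if not self.ref_seq and not self.alt_seq:
            raise ValueError("causative ref_seq and alt_seq cannot both be empty")
        if self.ref_seq == self.alt_seq:
            raise ValueError("causative ref_seq equals alt_seq")

    @property
    def affected_end(self) -> int:
        return self.position + max(len(self.ref_seq), 1) - 1


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults reproduce the scale of the motivating study: a 79 kb
    mapped segment of chromosome arm 3R carrying 626 background SNPs
    and 115 background indels in the mutant, a control sharing ~47% of
    them, a 159-line panel, and three planted copy-number outliers on a
    log10-normal panel distribution.
    """

    chrom: str = "3R"
    region_origin: int = 19_325_278
    region_length: int = 79_001
    gc_fraction: float = 0.42
    n_background_snps: int = 626
    n_background_indels: int = 115
    indel_length_range: tuple[int, int] = (1, 12)
    control_share_prob: float = 0.47
    panel_size: int = 162  # 3 outliers leave 159 normal lines for exclusion
    panel_carry_prob: float = 0.25
    guaranteed_coverage: bool = True
    causative: CausativeSpec = field(
        default_factory=lambda: CausativeSpec(position=19_396_067, ref_seq="TGT")
    )
    n_outlier_lines: int = 3
    outlier_magnitude_sd: float = 5.0
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 0.15
    ct_noise_sd: float = 0.15
    elongation_dct_drift: float = 0.25
    generations: tuple[int, ...] = (0, 6, 9, 12)
    target_base_ct: float = 20.0
    reference_base_ct: float = 15.0
    n_per_class: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_length <= 0:
            raise ValueError("region_length must be positive")
        for name in ("gc_fraction", "control_share_prob", "panel_carry_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not (self.region_origin <= self.causative.position
                and self.causative.affected_end <= self.region_end):
            raise ValueError("causative position must lie inside the region")
        if self.causative.position <= self.region_origin:
            raise ValueError("causative must leave room for an anchor base")
        if self.n_outlier_lines > self.panel_size:
            raise ValueError("n_outlier_lines cannot exceed panel_size")
        lo, hi = self.indel_length_range
        if not (1 <= lo <= hi):
            raise ValueError("indel_length_range must satisfy 1 <= min <= max")
        gens = tuple(self.generations)
        if len(gens) < 2 or gens[0] != 0 or any(a >= b for a, b in zip(gens, gens[1:])):
            raise ValueError("generations must be strictly increasing and start at 0")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be positive")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd cannot be negative")

    @property
    def region_end(self) -> int:
        return self.region_origin + self.region_length - 1

    def rng(self, *key: int) -> np.random.Generator:
        """Deterministic substream for one simulation layer."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))


@dataclass(frozen=True)
class RecombinantRecord:
    """One recombinant stock: marker class plus per-generation Ct data."""

    recombinant_id: str
    insertion_name: str
    marker_class: str
    truth_elongated: bool
    measurements: tuple[tuple[int, CtMeasurement, CtMeasurement], ...]
    # (generation, target measurement, reference-gene measurement)


@dataclass(frozen=True)
class StudyTruth:
    causative: Variant
    interval: GenomicInterval | None
    outlier_lines: tuple[str, ...]
    elongated_recombinants: tuple[str, ...]


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    reference: RegionSequence
    genes: list[GeneModel]
    mutant: VariantSet
    control: VariantSet
    panel: list[PanelLine]
    copy_numbers: dict[str, float]
    insertions: list[TransposonInsertion]
    recombinants: list[RecombinantRecord]
    truth: StudyTruth


def generate_reference(length: int, gc_fraction: float, seed: int) -> str:
    """Random uppercase A/C/G/T sequence with the given expected GC."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_L_REFERENCE,)))
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2,
                  (1 - gc_fraction) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def _build_gene_model(config: SimulationConfig) -> GeneModel:
    """A ten-exon gene placed so that intron 8 contains the causative
    position, scaled down until it fits the region."""
    pos = config.causative.position
    exon_len, intron_len = 200, 800
    while True:
        left_extent = 8 * exon_len + 7 * intron_len + intron_len // 2
        total = 10 * exon_len + 9 * intron_len
        g0 = pos - left_extent
        g_end = g0 + total - 1
        if g0 > config.region_origin and g_end < config.region_end:
            break
        if exon_len <= 10 or intron_len <= 30:
            raise ValueError(
                "region too small to place a ten-exon gene model around the causative"
            )
        exon_len = max(10, exon_len // 2)
        intron_len = max(30, intron_len // 2)
    exons = tuple(
        (g0 + k * (exon_len + intron_len), g0 + k * (exon_len + intron_len) + exon_len - 1)
        for k in range(10)
    )
    return GeneModel(gene_id="geneA", chrom=config.chrom, exons=exons)


def _causative_variant(config: SimulationConfig, reference: RegionSequence) -> Variant:
    spec = config.causative
    if len(spec.ref_seq) == 1 and len(spec.alt_seq) == 1:
        return Variant(config.chrom, spec.position, spec.ref_seq, spec.alt_seq)
    anchor = spec.position - 1
    base = reference.base(anchor)
    return Variant(config.chrom, anchor, base + spec.ref_seq, base + spec.alt_seq)


def plant_variants(
    reference: RegionSequence,
    config: SimulationConfig,
    exclude_from_coverage: frozenset[str] = frozenset(),
) -> tuple[VariantSet, VariantSet, list[VariantSet], Variant]:
    """Plant background + causative variants; derive control and panel sets.

    Returns (mutant set, control set, per-panel-line sets, causative),
    all normalized. The mutant set holds exactly
    ``n_background_snps + n_background_indels + 1`` variants; the
    causative appears in no control or panel set. Background placement
    is collision-free after normalization (re-drawn on collision, at
    most 1000 attempts per variant).
    """
    if len(reference) != config.region_length:
        raise ValueError("reference length does not match config.region_length")
    causative = normalize_variant(_causative_variant(config, reference), reference)
    rng = config.rng(_L_MUTANT)
    lo_len, hi_len = config.indel_length_range
    min_gap = hi_len + 2

    guard_lo = causative.pos - min_gap
    guard_hi = causative.affected_span.upper + min_gap
    taken: list[int] = []
    mutant = VariantSet("mutant", normalized=True)
    mutant.add(causative)
    background: list[Variant] = []
    n_total = config.n_background_snps + config.n_background_indels
    kinds = ["SNP"] * config.n_background_snps + ["indel"] * config.n_background_indels

    lo_pos = config.region_origin + 1
    hi_pos = config.region_end - hi_len - 1
    if hi_pos <= lo_pos:
        raise ValueError("region too small for requested background variants")

    for kind in kinds:
        for attempt in range(1000):
            pos = int(rng.integers(lo_pos, hi_pos + 1))
            if guard_lo <= pos <= guard_hi:
                continue
            if any(abs(pos - t) < min_gap for t in taken):
                continue
            if kind == "SNP":
                ref = reference.base(pos)
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                v = Variant(config.chrom, pos, ref, alt)
            else:
                length = int(rng.integers(lo_len, hi_len + 1))
                base = reference.base(pos)
                if rng.random() < 0.5:  # deletion
                    ref = reference.fetch(pos, pos + length)
                    v = Variant(config.chrom, pos, ref, base)
                else:  # insertion
                    ins = "".join(rng.choice(list("ACGT"), size=length))
                    v = Variant(config.chrom, pos, base, base + ins)
            v = normalize_variant(v, reference)
            if v in mutant or any(abs(v.pos - t) < min_gap for t in taken):
                logger.debug("re-drawing colliding background variant at %d", pos)
                continue
            mutant.add(v)
            background.append(v)
            taken.append(v.pos)
            break
        else:
            raise RuntimeError(
                f"could not place background variant {len(background) + 1}/{n_total} "
                "after 1000 attempts; region too crowded"
            )

    rng_control = config.rng(_L_CONTROL)
    control = VariantSet("control", normalized=True)
    for v in background:
        if rng_control.random() < config.control_share_prob:
            control.add(v)

    panel_sets: list[VariantSet] = []
    for i in range(config.panel_size):
        rng_line = config.rng(_L_PANEL, i)
        s = VariantSet(f"line{i + 1:03d}", normalized=True)
        for v in background:
            if rng_line.random() < config.panel_carry_prob:
                s.add(v)
        panel_sets.append(s)

    if config.guaranteed_coverage and panel_sets:
        # guarantee counts only lines that will survive the phenotype
        # filter: a variant whose sole carrier is an outlier line would
        # escape exclusion downstream
        rng_cov = config.rng(_L_COVERAGE)
        eligible = [s for s in panel_sets
                    if s.strain_id not in exclude_from_coverage]
        if not eligible:
            raise ValueError("no phenotype-normal panel line available for "
                             "guaranteed coverage")
        covered = set()
        for s in eligible:
            covered |= s.keys()
        for v in background:
            if v.key not in covered:
                eligible[int(rng_cov.integers(len(eligible)))].add(v)

    return mutant, control, panel_sets, causative


def simulate_panel_copy_numbers(
    config: SimulationConfig,
) -> list[tuple[str, float, bool]]:
    """Draw panel copy numbers: log10-normal bulk plus planted high
    outliers at ``outlier_magnitude_sd`` log-SDs above the mean."""
    if config.panel_size < 1:
        raise ValueError("panel_size must be >= 1")
    rng = config.rng(_L_COPYNUM)
    outlier_idx = set(
        rng.choice(config.panel_size, size=config.n_outlier_lines, replace=False).tolist()
    )
    out = []
    for i in range(config.panel_size):
        line = f"line{i + 1:03d}"
        if i in outlier_idx:
            log10_v = (config.lognormal_mu
                       + config.outlier_magnitude_sd * config.lognormal_sigma
                       + 0.1 * config.lognormal_sigma * rng.standard_normal())
        else:
            log10_v = config.lognormal_mu + config.lognormal_sigma * rng.standard_normal()
        out.append((line, float(10.0 ** log10_v), i in outlier_idx))
    return out


def _ct_triplicate(rng: np.random.Generator, mean: float, sd: float) -> tuple[float, ...]:
    return tuple(float(mean + sd * rng.standard_normal()) for _ in range(3))


def simulate_recombinants(
    insertions: list[TransposonInsertion],
    causative_pos: int,
    config: SimulationConfig,
    low_side_marker: str = "st",
    n_per_class: int | None = None,
) -> list[RecombinantRecord]:
    """Generate marker-classed recombinant stocks with Ct trajectories.

    A recombinant whose marker class retains the chromosome side
    containing ``causative_pos`` keeps the mutant allele: its dCt drops
    by ``elongation_dct_drift`` per generation. Others stay flat.
    Replicate noise is N(0, ct_noise_sd).
    """
    if not insertions:
        raise ValueError("need at least one insertion")
    n_per_class = config.n_per_class if n_per_class is None else n_per_class
    records = []
    for j, ins in enumerate(insertions):
        if ins.low <= causative_pos <= ins.high:
            raise ValueError(
                f"causative position {causative_pos} coincides with insertion "
                f"{ins.name}; side undefined"
            )
        for marker in MARKER_CLASSES:
            retains_low = marker == low_side_marker
            elongated = (causative_pos < ins.low) if retains_low else (causative_pos > ins.high)
            for r in range(n_per_class):
                rng = config.rng(_L_RECOMB, j, MARKER_CLASSES.index(marker), r)
                rid = f"{ins.name}:{marker}{r + 1}"
                measurements = []
                for g in config.generations:
                    drift = config.elongation_dct_drift * g if elongated else 0.0
                    tgt = CtMeasurement(
                        sample_id=rid, gene=TARGET_GENE, generation=g,
                        replicates=_ct_triplicate(
                            rng, config.target_base_ct - drift, config.ct_noise_sd),
                    )
                    ref = CtMeasurement(
                        sample_id=rid, gene=REFERENCE_GENE, generation=g,
                        replicates=_ct_triplicate(
                            rng, config.reference_base_ct, config.ct_noise_sd),
                    )
                    measurements.append((g, tgt, ref))
                records.append(RecombinantRecord(
                    recombinant_id=rid, insertion_name=ins.name, marker_class=marker,
                    truth_elongated=elongated, measurements=tuple(measurements),
                ))
    return records


def default_insertions(config: SimulationConfig) -> list[TransposonInsertion]:
    """Four informative insertions bracketing the causative position:
    two on each side, assigned to two mapping rounds."""
    pos = config.causative.position
    left_span = pos - config.region_origin
    right_span = config.region_end - config.causative.affected_end
    coords = [
        (pos - int(0.6 * left_span), 1),
        (pos - int(0.2 * left_span), 2),
        (config.causative.affected_end + int(0.2 * right_span), 2),
        (config.causative.affected_end + int(0.6 * right_span), 1),
    ]
    return [
        TransposonInsertion(
            name=f"ins{k + 1}", family="P" if rnd == 1 else "Minos",
            chrom=config.chrom, coordinate=c, mapping_round=rnd,
        )
        for k, (c, rnd) in enumerate(coords)
    ]


def generate_study(
    config: SimulationConfig,
    insertions: list[TransposonInsertion] | None = None,
) -> SyntheticStudy:
    """Generate a complete synthetic study (all layers, one seed)."""
    seq = generate_reference(config.region_length, config.gc_fraction, config.seed)
    # write the causative motif into the reference so the edit is real
    spec = config.causative
    if spec.ref_seq:
        i = spec.position - config.region_origin
        seq = seq[:i] + spec.ref_seq + seq[i + len(spec.ref_seq):]
    reference = RegionSequence(config.chrom, config.region_origin, seq)

    gene = _build_gene_model(config)
    copy_rows = simulate_panel_copy_numbers(config)
    copy_numbers = {line: value for line, value, _ in copy_rows}
    outliers = tuple(line for line, _, flag in copy_rows if flag)
    mutant, control, panel_sets, causative = plant_variants(
        reference, config, exclude_from_coverage=frozenset(outliers)
    )
    panel = [
        PanelLine(
            line_id=s.strain_id,
            phenotype="outlier" if s.strain_id in outliers else "normal",
            variants=s,
        )
        for s in panel_sets
    ]

    if insertions is None:
        insertions = default_insertions(config)
    recombinants = simulate_recombinants(
        insertions, causative.pos, config
    )

    below = [ins.high for ins in insertions if ins.high < causative.pos]
    above = [ins.low for ins in insertions if ins.low > causative.pos]
    interval = (
        GenomicInterval(config.chrom, max(below), min(above))
        if below and above else None
    )
    truth = StudyTruth(
        causative=causative,
        interval=interval,
        outlier_lines=outliers,
        elongated_recombinants=tuple(
            r.recombinant_id for r in recombinants if r.truth_elongated
        ),
    )
    return SyntheticStudy(
        config=config, reference=reference, genes=[gene], mutant=mutant,
        control=control, panel=panel, copy_numbers=copy_numbers,
        insertions=list(insertions), recombinants=recombinants, truth=truth,
    )


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A scaled-down configuration (5 kb region, tens of variants,
    30-line panel) for fast tests and examples; same structure as the
    full-scale default.

    The outlier fraction is kept near the full-scale value (1 of 30 vs
    3 of 162): a one-pass k-SD screen tolerates only a few percent
    contamination before the outliers inflate the fitted spread enough
    to hide themselves, so a faithful miniature must scale the outlier
    count with the panel.
    """
    base = dict(
        region_origin=10_001,
        region_length=5_000,
        n_background_snps=40,
        n_background_indels=10,
        indel_length_range=(1, 8),
        panel_size=30,
        panel_carry_prob=0.4,
        n_outlier_lines=1,
        causative=CausativeSpec(position=13_500, ref_seq="TGT"),
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def write_fixture(study: SyntheticStudy, directory) -> dict:
    """Write a complete study to ``directory`` as plain-text files and
    return the manifest (also saved as ``manifest.json``).

    Layout: ``reference.fasta``, ``mutant.vcf``, ``control.vcf``,
    ``panel/<line>.vcf``, ``mapping.tsv``, ``recombinants.tsv``,
    ``panel_copy_numbers.tsv``, ``genes.gff3``, ``manifest.json``. The
    files round-trip losslessly through the readers in
    :mod:`telmap.io`; the manifest records the seed and the planted
    truth.
    """
    from dataclasses import asdict
    from pathlib import Path

    from . import io as tio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "panel").mkdir(exist_ok=True)

    contig_len = study.reference.end
    tio.write_region_fasta(study.reference, directory / "reference.fasta")
    tio.write_vcf(study.mutant, directory / "mutant.vcf",
                  study.reference.chrom, contig_len)
    tio.write_vcf(study.control, directory / "control.vcf",
                  study.reference.chrom, contig_len)
    panel_files = {}
    for line in study.panel:
        p = directory / "panel" / f"{line.line_id}.vcf"
        tio.write_vcf(line.variants, p, study.reference.chrom, contig_len)
        panel_files[line.line_id] = str(p.relative_to(directory))
    tio.write_gff3(study.genes, directory / "genes.gff3")
    tio.write_recombinant_table(study.recombinants, directory / "recombinants.tsv")
    tio.write_copy_number_table(study.copy_numbers, directory / "panel_copy_numbers.tsv")
    with open(directory / "mapping.tsv", "w") as fh:
        fh.write("\t".join(tio.MAPPING_COLUMNS) + "\n")
        n_rec = 2 * study.config.n_per_class
        for ins in study.insertions:
            coord = (str(ins.coordinate) if ins.coordinate is not None
                     else f"{ins.coordinate_range[0]}-{ins.coordinate_range[1]}")
            fh.write(f"{ins.name}\t{ins.family}\t{ins.chrom}\t{coord}\t"
                     f"{ins.mapping_round}\t{n_rec}\t\n")

    truth = study.truth
    manifest = {
        "seed": study.config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(study.config).items()},
        "truth": {
            "causative": list(truth.causative.key),
            "interval": ([truth.interval.chrom, truth.interval.lower,
                          truth.interval.upper] if truth.interval else None),
            "outlier_lines": list(truth.outlier_lines),
            "elongated_recombinants": list(truth.elongated_recombinants),
        },
        "files": {
            "reference": "reference.fasta",
            "mutant_vcf": "mutant.vcf",
            "control_vcf": "control.vcf",
            "panel_vcfs": panel_files,
            "genes": "genes.gff3",
            "mapping": "mapping.tsv",
            "recombinants": "recombinants.tsv",
            "copy_numbers": "panel_copy_numbers.tsv",
        },
    }
    tio.write_json(manifest, directory / "manifest.json")
    return manifest
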