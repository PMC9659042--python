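"""Full-study orchestration.

``run_pipeline`` executes the identification chain over on-disk inputs:

1. panel copy-number screen → outlier flags → panel phenotype filter;
2. per-recombinant elongation calls → per-insertion side calls →
   candidate interval (optionally restricted to chosen mapping rounds);
3. variant-set normalization → control subtraction → interval
   restriction → panel exclusion (SNPs and indels may use different
   panel subsets) → annotation;
4. a report with survivors, an exact provenance partition of every
   mutant variant, and a machine-readable run log (parameters plus
   sha256 digests of every input file).

Everything is deterministic given the inputs; the pipeline itself
draws no random numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as tio
from .exclusion import (
    SURVIVED,
    CandidateReport,
    PanelLine,
    annotate_candidates,
    exclude_by_panel,
    restrict_to_interval,
    subtract_control,
)
from .intervals import GenomicInterval, interval_width_kb
from .mapping import MappedInterval, SideCall, combine_sides, infer_side
from .qpcr import ElongationCall, call_elongation, delta_ct, flag_outliers
from .variants import VariantSet

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    ``snp_panel_lines`` / ``indel_panel_lines`` restrict which panel
    lines may exclude each variant class (None = all normal lines);
    this mirrors panels with dense SNP genotypes for many lines but
    indel calls for only a few.
    """

    mapping_table: str | Path
    recombinant_table: str | Path
    copy_number_table: str | Path
    mutant_vcf: str | Path
    control_vcf: str | Path
    panel_vcfs: dict[str, str | Path]
    reference_fasta: str | Path
    gff3: str | Path
    out_dir: str | Path
    low_side_marker: str = "st"
    fold_threshold: float = 2.0
    use_regression: bool = False
    outlier_k: float = 3.0
    rounds: set[int] | None = None
    snp_panel_lines: set[str] | None = None
    indel_panel_lines: set[str] | None = None
    use_printed_side_calls: bool = False

    @classmethod
    def for_fixture(cls, directory: str | Path, out_dir: str | Path | None = None,
                    **overrides) -> "PipelineConfig":
        """Configuration pointing at a fixture directory written by
        :func:`telmap.simulate.write_fixture`."""
        d = Path(directory)
        panel = {p.stem: p for p in sorted((d / "panel").glob("*.vcf"))}
        return cls(
            mapping_table=d / "mapping.tsv",
            recombinant_table=d / "recombinants.tsv",
            copy_number_table=d / "panel_copy_numbers.tsv",
            mutant_vcf=d / "mutant.vcf",
            control_vcf=d / "control.vcf",
            panel_vcfs=panel,
            reference_fasta=d / "reference.fasta",
            gff3=d / "genes.gff3",
            out_dir=out_dir if out_dir is not None else d / "out",
            **overrides,
        )


@dataclass
class StudyResult:
    panel_screen: "object"  # PanelScreenResult
    elongation_calls: dict[str, ElongationCall]
    side_calls: list[tuple[str, SideCall]]
    interval: MappedInterval
    report: CandidateReport
    run_log: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


@_stage("panel_screen")
def _screen_panel(config: PipelineConfig):
    values = tio.read_copy_number_table(config.copy_number_table)
    return flag_outliers(values, k=config.outlier_k, tail="high")


@_stage("elongation_calls")
def _call_all_elongation(config: PipelineConfig, records):
    calls: dict[str, ElongationCall] = {}
    for r in records:
        trajectory = [
            (g, delta_ct(tgt, ref).value) for g, tgt, ref in r.measurements
        ]
        calls[r.recombinant_id] = call_elongation(
            r.recombinant_id, trajectory,
            fold_threshold=config.fold_threshold,
            use_regression=config.use_regression,
        )
    return calls


@_stage("side_calls")
def _call_sides(config: PipelineConfig, mapping_rows, records, elongation_calls):
    by_insertion: dict[str, dict[str, list[ElongationCall]]] = {}
    for r in records:
        by_insertion.setdefault(r.insertion_name, {}).setdefault(
            r.marker_class, []
        ).append(elongation_calls[r.recombinant_id])
    pairs = []
    for ins, printed in mapping_rows:
        if config.use_printed_side_calls and printed is not None:
            pairs.append((ins, SideCall(ins.name, printed, {})))
        elif ins.name in by_insertion:
            pairs.append((ins, infer_side(
                ins, by_insertion[ins.name], low_side_marker=config.low_side_marker
            )))
    if not pairs:
        raise ValueError("no insertion has side-call information")
    return pairs


@_stage("exclusion")
def _exclude(config: PipelineConfig, interval: MappedInterval,
             screen) -> tuple[CandidateReport, dict]:
    reference = tio.read_region_fasta(config.reference_fasta)
    mutant = tio.read_vcf(config.mutant_vcf, "mutant").normalize(reference)
    control = tio.read_vcf(config.control_vcf, "control").normalize(reference)

    flagged = set(screen.flagged)
    panel: list[PanelLine] = []
    for line_id, path in sorted(config.panel_vcfs.items()):
        panel.append(PanelLine(
            line_id=line_id,
            phenotype="outlier" if line_id in flagged else "normal",
            variants=tio.read_vcf(path, line_id).normalize(reference),
        ))

    provenance: dict[tuple, str] = {}
    after_control, prov = subtract_control(mutant, control)
    provenance.update({k: v for k, v in prov.items() if v != SURVIVED})

    in_interval, prov = restrict_to_interval(after_control, interval.interval)
    provenance.update({k: v for k, v in prov.items() if v != SURVIVED})

    def lines_for(selector: set[str] | None) -> list[PanelLine]:
        if selector is None:
            return panel
        return [ln for ln in panel if ln.line_id in selector]

    snp_rep = exclude_by_panel(
        in_interval.select(lambda v: v.variant_class == "SNP"),
        lines_for(config.snp_panel_lines), classes="SNP",
    )
    indel_rep = exclude_by_panel(
        in_interval.select(lambda v: v.variant_class != "SNP"),
        lines_for(config.indel_panel_lines), classes="both",
    )
    survivors = VariantSet("mutant", normalized=True)
    for rep in (snp_rep, indel_rep):
        for k, v in rep.provenance.items():
            if v != SURVIVED:
                provenance[k] = v
        for v in rep.survivors:
            survivors.add(v)

    genes = tio.read_gff3(config.gff3)
    report = annotate_candidates(survivors, genes)
    provenance.update(report.provenance)
    report.provenance = {v.key: provenance[v.key] for v in mutant}
    counts = {
        "n_mutant": len(mutant),
        "n_after_control": len(after_control),
        "n_in_interval": len(in_interval),
        "n_survivors": len(survivors),
    }
    return report, counts


def run_pipeline(config: PipelineConfig) -> StudyResult:
    """Execute the full study; persists stage outputs under
    ``config.out_dir`` and returns the in-memory result."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        screen = _screen_panel(config)
        logger.info("panel screen: %d lines, %d outliers flagged",
                    len(screen.values), len(screen.flagged))
        mapping_rows = tio.read_mapping_table(config.mapping_table)
        records = tio.read_recombinant_table(config.recombinant_table)
        elongation_calls = _call_all_elongation(config, records)
        side_calls = _call_sides(config, mapping_rows, records, elongation_calls)
        try:
            interval = combine_sides(side_calls, rounds=config.rounds)
        except Exception as exc:
            raise StageError("interval", exc) from exc
        logger.info("candidate interval %s:%d-%d (~%d kb)",
                    interval.interval.chrom, interval.lower, interval.upper,
                    interval_width_kb(interval.interval))
        report, counts = _exclude(config, interval, screen)
    except StageError:
        (out_dir / "FAILED").touch()
        raise

    run_log = {
        "parameters": {
            "low_side_marker": config.low_side_marker,
            "fold_threshold": config.fold_threshold,
            "use_regression": config.use_regression,
            "outlier_k": config.outlier_k,
            "rounds": sorted(config.rounds) if config.rounds else None,
            "use_printed_side_calls": config.use_printed_side_calls,
        },
        "input_digests": {
            str(p): tio.file_digest(p)
            for p in [config.mapping_table, config.recombinant_table,
                      config.copy_number_table, config.mutant_vcf,
                      config.control_vcf, config.reference_fasta, config.gff3]
            + sorted(config.panel_vcfs.values())
        },
        "counts": counts,
    }
    result = StudyResult(
        panel_screen=screen, elongation_calls=elongation_calls,
        side_calls=[(ins.name, sc) for ins, sc in side_calls],
        interval=interval, report=report, run_log=run_log,
    )
    write_report(result, out_dir)
    return result


def write_report(result: StudyResult, directory: str | Path) -> None:
    """Persist a StudyResult as JSON + TSV + BED."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iv = result.interval
    payload = {
        "interval": {
            "chrom": iv.interval.chrom, "lower": iv.lower, "upper": iv.upper,
            "width_kb": interval_width_kb(iv.interval),
            "lower_insertion": iv.lower_insertion,
            "upper_insertion": iv.upper_insertion,
        },
        "panel_screen": {
            "log_mean": result.panel_screen.log_mean,
            "log_sd": result.panel_screen.log_sd,
            "k": result.panel_screen.k,
            "flagged": list(result.panel_screen.flagged),
        },
        "side_calls": [
            {"insertion": name, "call": sc.call,
             "counts": {cls: list(c) for cls, c in sc.counts.items()}}
            for name, sc in result.side_calls
        ],
        "survivors": [
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "class": v.variant_class,
                "annotation": _annotation_dict(result.report.annotations.get(v.key)),
            }
            for v in result.report.survivors
        ],
        "provenance_counts": _tally(result.report.provenance),
        "run_log": result.run_log,
    }
    tio.write_json(payload, directory / "report.json")
    tio.write_interval_bed(iv.interval, directory / "interval.bed")
    with open(directory / "provenance.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tstatus\n")
        for (chrom, pos, ref, alt), status in sorted(result.report.provenance.items()):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{status}\n")


def _annotation_dict(ann) -> dict | None:
    if ann is None:
        return None
    return {
        "kind": ann.kind, "gene": ann.gene,
        "exon_index": ann.exon_index, "intron_index": ann.intron_index,
        "left_gene": ann.left_gene,
        "left_distance": None if ann.left_distance == float("inf") else ann.left_distance,
        "right_gene": ann.right_gene,
        "right_distance": None if ann.right_distance == float("inf") else ann.right_distance,
    }


def _tally(provenance: dict[tuple, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for status in provenance.values():
        bucket = status.split(":", 1)[0]
        counts[bucket] = counts.get(bucket, 0) + 1
    return counts
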