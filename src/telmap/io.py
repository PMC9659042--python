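"""Format readers and writers.

Conventions:

* FASTA — single-record reference segment via Biopython, wrapped at 60
  columns; the record description carries ``region_origin=<pos>`` so a
  sub-chromosomal segment keeps its genomic coordinates.
* VCF v4.2 — single-sample, uncompressed, via pysam; positions are
  genomic (1-based); chromosome labels carry no ``chr`` prefix.
* GFF3 — gene/mRNA/exon/intron features (1-based closed, per the
  format).
* TSV — header rows; schemas below. Parse errors cite file and line.
* BED — interval output only; 0-based half-open conversion happens at
  the boundary, never internally.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exclusion import GeneModel
from .intervals import GenomicInterval
from .mapping import MARKER_CLASSES, SideCall, TransposonInsertion
from .qpcr import CtMeasurement
from .simulate import REFERENCE_GENE, TARGET_GENE, RecombinantRecord
from .variants import RegionSequence, Variant, VariantSet


class SchemaError(ValueError):
    """A table or file does not match its declared schema."""


def _schema_error(path, line_no, msg) -> SchemaError:
    return SchemaError(f"{path}:{line_no}: {msg}")


# ---------------------------------------------------------------- FASTA

def write_region_fasta(region: RegionSequence, path: str | Path) -> None:
    rec = SeqRecord(
        Seq(region.seq),
        id=region.chrom,
        description=f"region_origin={region.origin}",
    )
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")


def read_region_fasta(path: str | Path) -> RegionSequence:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise SchemaError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    origin = 1
    for token in rec.description.split():
        if token.startswith("region_origin="):
            origin = int(token.split("=", 1)[1])
    return RegionSequence(rec.id, origin, str(rec.seq))


# ------------------------------------------------------------------ VCF

def write_vcf(
    vset: VariantSet,
    path: str | Path,
    contig: str,
    contig_length: int,
    provenance: dict[tuple, str] | None = None,
) -> None:
    """Single-sample VCF v4.2; optional per-variant provenance goes in
    INFO/FILTERED_BY."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line('##INFO=<ID=FILTERED_BY,Number=1,Type=String,'
                    'Description="Pipeline stage that removed this variant, or survived">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(vset.strain_id or "SAMPLE")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in vset:
            rec = out.new_record(
                contig=contig, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            if provenance is not None and v.key in provenance:
                rec.info["FILTERED_BY"] = provenance[v.key].replace(";", ",")
            rec.samples[0]["GT"] = (1, 1)
            out.write(rec)


def read_vcf(path: str | Path, strain_id: str | None = None) -> VariantSet:
    """Read a single-sample VCF into a (not-yet-normalized) VariantSet."""
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise SchemaError(f"{path}: not a parseable VCF ({exc})") from exc
    with vf:
        sid = strain_id or (vf.header.samples[0] if list(vf.header.samples) else Path(path).stem)
        vset = VariantSet(sid)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise SchemaError(
                    f"{path}: record at {rec.chrom}:{rec.pos} must have exactly one ALT"
                )
            vset.add(Variant(rec.chrom, rec.pos, rec.ref, rec.alts[0]))
    return vset


# ----------------------------------------------------------------- GFF3

def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            rows = [
                (g.chrom, "telmap", "gene", g.start, g.end,
                 f"ID=gene:{g.gene_id};Name={g.gene_id}"),
                (g.chrom, "telmap", "mRNA", g.start, g.end,
                 f"ID=mrna:{g.gene_id};Parent=gene:{g.gene_id}"),
            ]
            for i, (a, b) in enumerate(g.exons, start=1):
                rows.append((g.chrom, "telmap", "exon", a, b,
                             f"ID=exon:{g.gene_id}.{i};Parent=mrna:{g.gene_id}"))
            for i, (a, b) in enumerate(g.introns, start=1):
                rows.append((g.chrom, "telmap", "intron", a, b,
                             f"ID=intron:{g.gene_id}.{i};Parent=mrna:{g.gene_id}"))
            for chrom, src, kind, a, b, attrs in rows:
                fh.write(f"{chrom}\t{src}\t{kind}\t{a}\t{b}\t.\t{g.strand}\t.\t{attrs}\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Rebuild GeneModels from gene + exon features (introns are
    derived, not read)."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise _schema_error(path, line_no, f"expected 9 GFF3 columns, got {len(parts)}")
            chrom, _, kind, start, end, _, strand, _, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if kind == "gene":
                gid = attr.get("Name") or attr["ID"].split(":", 1)[-1]
                genes[gid] = {"chrom": chrom, "strand": strand, "exons": []}
            elif kind == "exon":
                gid = attr["Parent"].split(":", 1)[-1]
                if gid not in genes:
                    raise _schema_error(path, line_no, f"exon for unknown gene {gid!r}")
                genes[gid]["exons"].append((int(start), int(end)))
    return [
        GeneModel(gene_id=gid, chrom=g["chrom"], exons=tuple(g["exons"]),
                  strand=g["strand"])
        for gid, g in genes.items()
    ]


# ------------------------------------------------------------------ TSV

MAPPING_COLUMNS = ["name", "family", "chrom", "coordinate", "round", "n_recombinants", "side"]


def read_mapping_table(path: str | Path) -> list[tuple[TransposonInsertion, str | None]]:
    """Mapping-experiment table: one row per transposon insertion.

    Columns: name, family, chrom, coordinate (point or ``lo-hi``
    range), round, n_recombinants, and optionally a printed side call
    (Left/Right; empty for uncalled rows).
    """
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = set(MAPPING_COLUMNS[:5])
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise SchemaError(
                f"{path}: mapping table needs columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for line_no, row in enumerate(reader, start=2):
            coord = row["coordinate"].replace(",", "").strip()
            kwargs: dict = {}
            try:
                if "-" in coord:
                    lo, hi = coord.split("-")
                    kwargs["coordinate_range"] = (int(lo), int(hi))
                else:
                    kwargs["coordinate"] = int(coord)
                ins = TransposonInsertion(
                    name=row["name"], family=row["family"], chrom=row["chrom"],
                    mapping_round=int(row["round"]), **kwargs,
                )
            except (ValueError, KeyError) as exc:
                raise _schema_error(path, line_no, f"bad mapping row ({exc})") from exc
            side = (row.get("side") or "").strip() or None
            if side is not None and side not in ("Left", "Right", "Ambiguous"):
                raise _schema_error(path, line_no, f"bad side call {side!r}")
            out.append((ins, side))
    return out


def side_calls_from_table(
    rows: list[tuple[TransposonInsertion, str | None]]
) -> list[tuple[TransposonInsertion, SideCall]]:
    """Adapt printed side calls to (insertion, SideCall) pairs for
    combine_sides; rows without a call are skipped."""
    return [
        (ins, SideCall(insertion_name=ins.name, call=side, counts={}))
        for ins, side in rows
        if side is not None
    ]


RECOMBINANT_COLUMNS = [
    "insertion", "recombinant", "marker_class", "generation",
    "target_ct_1", "target_ct_2", "target_ct_3",
    "reference_ct_1", "reference_ct_2", "reference_ct_3",
]


def write_recombinant_table(records: list[RecombinantRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(RECOMBINANT_COLUMNS)
        for r in records:
            for g, tgt, ref in r.measurements:
                w.writerow(
                    [r.insertion_name, r.recombinant_id, r.marker_class, g]
                    + [f"{c:.4f}" for c in tgt.replicates]
                    + [f"{c:.4f}" for c in ref.replicates]
                )


def read_recombinant_table(path: str | Path) -> list[RecombinantRecord]:
    rows: dict[str, dict] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != RECOMBINANT_COLUMNS:
            raise SchemaError(
                f"{path}: recombinant table must have columns {RECOMBINANT_COLUMNS}"
            )
        for line_no, row in enumerate(reader, start=2):
            try:
                rid = row["recombinant"]
                g = int(row["generation"])
                tgt = CtMeasurement(
                    sample_id=rid, gene=TARGET_GENE, generation=g,
                    replicates=tuple(float(row[f"target_ct_{i}"]) for i in (1, 2, 3)),
                )
                ref = CtMeasurement(
                    sample_id=rid, gene=REFERENCE_GENE, generation=g,
                    replicates=tuple(float(row[f"reference_ct_{i}"]) for i in (1, 2, 3)),
                )
            except (KeyError, ValueError) as exc:
                raise _schema_error(path, line_no, f"bad recombinant row ({exc})") from exc
            if row["marker_class"] not in MARKER_CLASSES:
                raise _schema_error(path, line_no,
                                    f"unknown marker class {row['marker_class']!r}")
            entry = rows.setdefault(rid, {
                "insertion": row["insertion"], "marker": row["marker_class"],
                "measurements": [],
            })
            entry["measurements"].append((g, tgt, ref))
    return [
        RecombinantRecord(
            recombinant_id=rid, insertion_name=e["insertion"], marker_class=e["marker"],
            truth_elongated=False,  # unknown for real data; truth lives in manifests
            measurements=tuple(sorted(e["measurements"], key=lambda m: m[0])),
        )
        for rid, e in rows.items()
    ]


def write_copy_number_table(values: dict[str, float], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["line", "copy_number"])
        for line, v in values.items():
            w.writerow([line, f"{v:.6g}"])


def read_copy_number_table(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != ["line", "copy_number"]:
            raise SchemaError(f"{path}: copy-number table must have columns line, copy_number")
        for line_no, row in enumerate(reader, start=2):
            try:
                out[row["line"]] = float(row["copy_number"])
            except (KeyError, ValueError) as exc:
                raise _schema_error(path, line_no, f"bad copy-number row ({exc})") from exc
    return out


# ------------------------------------------------------------ BED / misc

def write_interval_bed(interval: GenomicInterval, path: str | Path,
                       name: str = "candidate_interval") -> None:
    chrom, start, end = interval.to_bed()
    with open(path, "w") as fh:
        fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
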