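"""Full synthetic study: from raw tables and VCFs to one candidate.

Generates a scaled-down study (5 kb region, 50 background variants,
30-line panel, one planted 3 bp TGT deletion in intron 8 of a synthetic
gene), writes it to disk as FASTA/VCF/GFF3/TSV, and runs the complete
pipeline: outlier screen -> elongation calls -> side calls -> interval
-> normalization -> control subtraction -> interval restriction ->
panel exclusion -> annotation.
"""

import tempfile

from telmap import PipelineConfig, generate_study, run_pipeline, small_config, write_fixture
from telmap.intervals import interval_width_kb

study = generate_study(small_config(seed=7))
print(f"planted causative: {study.truth.causative} "
      f"({study.truth.causative.indel_length} bp deletion)")
print(f"mutant variants: {len(study.mutant)}, control: {len(study.control)}, "
      f"panel: {len(study.panel)} lines")

with tempfile.TemporaryDirectory() as d:
    write_fixture(study, d)
    result = run_pipeline(PipelineConfig.for_fixture(d))

iv = result.interval
print(f"\nmapped interval: {iv.interval.chrom}:{iv.lower:,}-{iv.upper:,} "
      f"(~{interval_width_kb(iv.interval)} kb)")
print(f"panel lines flagged as outliers: {sorted(result.panel_screen.flagged)}")
print(f"provenance: {result.run_log['counts']}")
for v in result.report.survivors:
    ann = result.report.annotations[v.key]
    print(f"surviving candidate: {v} -> {ann.kind}, gene {ann.gene}, "
          f"intron {ann.intron_index}")
print("\nWith guaranteed panel coverage every background variant is held "
      "by some phenotypically normal line, so exclusion reduces the "
      "candidate list to exactly the planted mutation.")
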