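"""telmap: Mendelian mutation identification by transposon-recombination
interval mapping, population-panel variant exclusion, and qPCR
copy-number phenotyping."""

from importlib.resources import files

from .intervals import GenomicInterval, interval_width_kb, locus_overlap
from .mapping import (
    MappedInterval,
    SideCall,
    TransposonInsertion,
    combine_sides,
    infer_side,
)
from .qpcr import (
    Amplicon,
    CtMeasurement,
    ElongationCall,
    PanelScreenResult,
    call_elongation,
    delta_ct,
    fit_panel_distribution,
    flag_outliers,
    in_silico_pcr,
    relative_copy_number,
)
from .variants import (
    RegionSequence,
    Variant,
    VariantSet,
    apply_variant,
    normalize_variant,
)
from .exclusion import (
    Annotation,
    CandidateReport,
    GeneModel,
    PanelLine,
    annotate_candidates,
    contig_n50,
    discover_large_indels,
    exclude_by_panel,
    indel_presence_in_window,
    restrict_to_interval,
    subtract_control,
)
from .simulate import (
    CausativeSpec,
    RecombinantRecord,
    SimulationConfig,
    SyntheticStudy,
    generate_reference,
    generate_study,
    simulate_panel_copy_numbers,
    simulate_recombinants,
    small_config,
    write_fixture,
)
from .pipeline import PipelineConfig, StudyResult, run_pipeline

__version__ = "0.1.0"


def mapping_table_path():
    """Path to the packaged transposon mapping-experiment table
    (14 insertions with printed side calls)."""
    return files("telmap").joinpath("data/tel1_mapping_table.tsv")
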