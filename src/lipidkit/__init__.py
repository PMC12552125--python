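"""lipidkit: quantitative shotgun-lipidomics analysis.

Pipeline stages: shorthand nomenclature parsing, dataset assembly and
validation, blank-based species filtering with group-wise reintroduction,
class composition and percent-of-total normalization, double-bond
saturation profiles, differential lipotype statistics with BH correction
and PCA, plus a synthetic lipidome generator for fully offline testing.
"""

from .blank_filter import FilterParams, FilterReport, apply_blank_filter, blank_threshold
from .io import (
    LipidomicsDataset,
    SampleAnnotation,
    build_dataset,
    read_concentration_table,
    read_dataset,
    read_metadata,
    to_tidy,
    validate_dataset,
    write_dataset,
)
from .nomenclature import (
    PHOSPHOLIPID_POOL,
    LipidClass,
    ParsedLipid,
    annotation_frame,
    canonical_name,
    default_registry,
    parse_species,
    sum_composition,
)
from .pipeline import PipelineConfig, run_pipeline
from .quantify import class_totals, log2_fold_change, percent_of_total, zscore_rows
from .saturation import SaturationProfile, double_bond_profile, profile_to_frame
from .stats import (
    DifferentialResult,
    PcaResult,
    aggregate_replicates,
    bh_adjust,
    differential_test,
    pca_lipotypes,
    select_test,
)
from .synthetic import (
    EffectSpec,
    GroupSpec,
    LipotypeTemplate,
    TargetSelector,
    make_effects,
    make_templates,
    null_effect,
    simulate_dataset,
)

__version__ = "0.1.0"
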