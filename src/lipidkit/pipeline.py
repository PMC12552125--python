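"""End-to-end pipeline: validate -> filter -> quantify -> saturation -> stats.

Every run writes its figure-payload CSVs, a machine-readable JSON log
(stage, parameters, counts, wall time) and the effective configuration
next to the outputs, so results are reproducible from the bundle alone.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .blank_filter import FilterParams, apply_blank_filter
from .errors import DesignError, LipidkitError
from .io import (
    LipidomicsDataset,
    build_dataset,
    read_concentration_table,
    read_metadata,
    validate_dataset,
)
from .quantify import class_totals, log2_fold_change, percent_of_total, zscore_rows
from .saturation import double_bond_profile, profile_to_frame
from .stats import aggregate_replicates, differential_test, pca_lipotypes

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_FLOAT_FORMAT = "%.12g"


@dataclass
class PipelineConfig:
    """Serializable configuration for one pipeline run."""

    matrix: str
    metadata: str
    control_group: str
    case_groups: list[str] | None = None
    orientation: str = "species_rows"
    unit: str = "uM"
    blank_fold: float = 2.0
    global_fraction: float = 0.8
    group_fraction: float = 0.6
    blank_statistic: str = "mean"
    paired: bool = False
    test_override: str | None = None
    use_experiment_means: bool = False
    normality_alpha: float = 0.05
    saturation_pools: list[str] = field(
        default_factory=lambda: ["TG", "CE", "phospholipids"])
    include_sm_in_phospholipids: bool = False
    pca_scale: bool = False
    pseudocount: float = 0.0
    output_dir: str = "results"
    seed: int | None = None

    @property
    def filter_params(self) -> FilterParams:
        return FilterParams(blank_fold=self.blank_fold,
                            global_fraction=self.global_fraction,
                            group_fraction=self.group_fraction,
                            blank_statistic=self.blank_statistic)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    output_dir: Path
    log: list[dict]
    paths: dict[str, str]


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, float_format=_FLOAT_FORMAT, index=index)


def run_pipeline(config: PipelineConfig,
                 dataset: LipidomicsDataset | None = None) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    A pre-built ``dataset`` may be supplied (e.g. straight from the
    simulator); otherwise the matrix and metadata paths are read.  On any
    stage error a ``FAILED`` marker naming the stage is written and the
    error re-raised; partial outputs are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    paths: dict[str, str] = {}
    stage = "setup"

    def record(name: str, t0: float, **info):
        log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 4),
                    **info})

    try:
        stage = "load"
        t0 = time.perf_counter()
        if dataset is None:
            matrix = read_concentration_table(config.matrix, config.orientation)
            annotations = read_metadata(config.metadata)
            report = validate_dataset(matrix, annotations)
            (out / "validation.json").write_text(json.dumps({
                "hard_failures": report.hard_failures,
                "warnings": report.warnings,
                "n_blanks": report.n_blanks,
                "group_counts": report.group_counts,
            }, indent=2) + "\n")
            paths["validation"] = str(out / "validation.json")
            dataset = build_dataset(matrix, annotations, unit=config.unit)
        record("load", t0, n_species=dataset.concentrations.shape[0],
               n_samples=dataset.concentrations.shape[1])

        stage = "design"
        groups = dataset.groups()
        if config.control_group not in groups:
            raise DesignError(
                f"control group {config.control_group!r} not among "
                f"groups {sorted(groups)}")
        case_groups = config.case_groups or [
            g for g in groups if g != config.control_group]

        stage = "filter"
        t0 = time.perf_counter()
        filtered, freport = apply_blank_filter(dataset, config.filter_params)
        _write_csv(freport.table, out / "filter_report.csv")
        (out / "filter_summary.json").write_text(
            json.dumps(freport.summary(), indent=2) + "\n")
        paths["filter_report"] = str(out / "filter_report.csv")
        record("filter", t0, **freport.counts)

        stage = "quantify"
        t0 = time.perf_counter()
        profile = class_totals(filtered)
        bio_ids = filtered.sample_ids("biological")
        species_bio = filtered.concentrations[bio_ids]
        species_percent = percent_of_total(species_bio, totals=profile.total_lipid)
        z = zscore_rows(profile.percent)
        control_ids = groups[config.control_group]
        class_fc = log2_fold_change(profile.percent, control_ids,
                                    pseudocount=config.pseudocount)
        species_fc = log2_fold_change(species_percent, control_ids,
                                      pseudocount=config.pseudocount)
        _write_csv(profile.totals, out / "class_totals.csv")
        _write_csv(profile.percent, out / "class_percent.csv")
        _write_csv(species_percent, out / "species_percent.csv")
        _write_csv(z.values, out / "class_zscore.csv")
        _write_csv(class_fc, out / "log2fc_class.csv")
        _write_csv(species_fc, out / "log2fc_species.csv")
        for key in ("class_totals", "class_percent", "species_percent",
                    "class_zscore", "log2fc_class", "log2fc_species"):
            paths[key] = str(out / f"{key}.csv")
        record("quantify", t0, n_classes=profile.totals.shape[0])

        stage = "saturation"
        t0 = time.perf_counter()
        for pool in config.saturation_pools:
            prof = double_bond_profile(
                filtered, pool, config.control_group,
                include_sm=(pool == "phospholipids"
                            and config.include_sm_in_phospholipids))
            path = out / f"saturation_{pool}.csv"
            _write_csv(profile_to_frame(prof), path, index=False)
            paths[f"saturation_{pool}"] = str(path)
        record("saturation", t0, pools=list(config.saturation_pools))

        stage = "stats"
        t0 = time.perf_counter()
        group_of = filtered.group_of()
        class_matrix, species_matrix = profile.percent, species_percent
        pair_of = None
        if config.use_experiment_means:
            replicate_of = filtered.replicate_of()
            class_matrix, agg_groups = aggregate_replicates(
                class_matrix, replicate_of, group_of)
            species_matrix, _ = aggregate_replicates(
                species_matrix, replicate_of, group_of)
            group_of = agg_groups
            if config.paired:
                pair_of = {c: c.split(":", 1)[1] for c in class_matrix.columns}
        elif config.paired:
            pair_of = filtered.replicate_of()

        diff_tables = {"class": [], "species": []}
        n_sig = {}
        for case in case_groups:
            for family, matrix_f in (("class", class_matrix),
                                     ("species", species_matrix)):
                res = differential_test(
                    matrix_f, group_of, case, config.control_group,
                    paired=config.paired, pair_of=pair_of, family=family,
                    test_override=config.test_override,
                    normality_alpha=config.normality_alpha)
                tbl = res.table.reset_index()
                tbl.insert(0, "control_group", config.control_group)
                tbl.insert(0, "case_group", case)
                diff_tables[family].append(tbl)
                n_sig[f"{family}:{case}"] = int((res.table["q"] < 0.05).sum())
        for family, tables in diff_tables.items():
            path = out / f"differential_{family}.csv"
            _write_csv(pd.concat(tables, ignore_index=True), path, index=False)
            paths[f"differential_{family}"] = str(path)

        pca = pca_lipotypes(species_matrix, scale=config.pca_scale)
        _write_csv(pca.scores, out / "pca_scores.csv")
        _write_csv(pca.loadings, out / "pca_loadings.csv")
        pd.DataFrame({"component": pca.scores.columns,
                      "variance_fraction": pca.explained_variance_ratio}
                     ).to_csv(out / "pca_variance.csv", index=False,
                              float_format=_FLOAT_FORMAT)
        for key in ("pca_scores", "pca_loadings", "pca_variance"):
            paths[key] = str(out / f"{key}.csv")
        record("stats", t0, **n_sig)

        stage = "finalize"
        (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(),
                                                        sort_keys=True))
        (out / "pipeline_log.json").write_text(json.dumps(log, indent=2) + "\n")
        paths["log"] = str(out / "pipeline_log.json")
        return PipelineResult(output_dir=out, log=log, paths=paths)

    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, LipidkitError):
            raise
        raise LipidkitError(f"pipeline failed at stage {stage!r}: {exc}") from exc
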