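"""Blank-based species filtering with group-wise reintroduction.

A species must reach ``blank_fold`` times the blank background in at
least ``global_fraction`` of the biological samples to be retained.  A
globally failing species is reintroduced when it reaches the same
threshold in at least ``group_fraction`` of the samples of any single
experimental group (groups = concatenated grouping variables).  Missing
values never pass and are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyDesignError, NoBlankError
from .io import LipidomicsDataset

__all__ = ["FilterParams", "FilterReport", "blank_threshold", "apply_blank_filter"]

#: Tolerance for "at least" fraction comparisons, so that e.g. 8/10 >= 0.8
#: holds regardless of binary rounding.
_FRACTION_EPS = 1e-12


@dataclass(frozen=True)
class FilterParams:
    """Defaults reproduce the 2x-blank / 80% / 60% rule."""

    blank_fold: float = 2.0
    global_fraction: float = 0.8
    group_fraction: float = 0.6
    blank_statistic: str = "mean"  # "mean" | "max" over blank samples

    def __post_init__(self):
        if self.blank_fold <= 0:
            raise ValueError("blank_fold must be positive")
        for name in ("global_fraction", "group_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.blank_statistic not in ("mean", "max"):
            raise ValueError("blank_statistic must be 'mean' or 'max'")


@dataclass
class FilterReport:
    """Per-species verdicts with pass fractions.

    ``table`` columns: threshold, n_pass, n_biological, global_fraction,
    one ``group_fraction:<label>`` column per group, max_group_fraction,
    verdict (retained | reintroduced | removed).
    """

    table: pd.DataFrame
    params: FilterParams
    group_labels: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        vc = self.table["verdict"].value_counts()
        return {v: int(vc.get(v, 0)) for v in ("retained", "reintroduced", "removed")}

    def kept_species(self) -> list[str]:
        keep = self.table["verdict"].isin(["retained", "reintroduced"])
        return list(self.table.index[keep])

    def summary(self) -> dict:
        return {
            "params": {
                "blank_fold": self.params.blank_fold,
                "global_fraction": self.params.global_fraction,
                "group_fraction": self.params.group_fraction,
                "blank_statistic": self.params.blank_statistic,
            },
            "n_species": int(len(self.table)),
            "counts": self.counts,
            "groups": list(self.group_labels),
        }


def blank_threshold(dataset: LipidomicsDataset,
                    params: FilterParams = FilterParams()) -> pd.Series:
    """Per-species threshold: ``blank_fold x blank_statistic`` over blanks.

    Missing blank values are treated as 0 (a species absent from the
    blanks gets threshold 0 and trivially passes everywhere).
    """
    blank_ids = dataset.sample_ids("blank")
    if not blank_ids:
        raise NoBlankError("dataset contains no blank samples")
    blanks = dataset.concentrations[blank_ids].fillna(0.0)
    stat = blanks.mean(axis=1) if params.blank_statistic == "mean" else blanks.max(axis=1)
    return (params.blank_fold * stat).rename("threshold")


def apply_blank_filter(dataset: LipidomicsDataset,
                       params: FilterParams = FilterParams()
                       ) -> tuple[LipidomicsDataset, FilterReport]:
    """Apply the blank filter; return (filtered dataset, report).

    Pass fractions are computed over biological samples only.  The
    filtered dataset keeps retained and reintroduced species and all
    samples; missing values stay missing.
    """
    bio_ids = dataset.sample_ids("biological")
    if not bio_ids:
        raise EmptyDesignError("no biological samples to filter on")

    thresholds = blank_threshold(dataset, params)
    bio = dataset.concentrations[bio_ids]
    passes = bio.notna() & bio.ge(thresholds, axis=0)
    n_bio = len(bio_ids)
    n_pass = passes.sum(axis=1)
    global_frac = n_pass / n_bio

    groups = dataset.groups()
    group_fracs = pd.DataFrame(index=dataset.concentrations.index)
    for label, ids in groups.items():
        group_fracs[label] = passes[ids].sum(axis=1) / len(ids)

    retained = global_frac + _FRACTION_EPS >= params.global_fraction
    if groups:
        max_group = group_fracs.max(axis=1)
    else:
        max_group = pd.Series(0.0, index=dataset.concentrations.index)
    reintroduced = (~retained) & (max_group + _FRACTION_EPS >= params.group_fraction)

    verdict = np.where(retained, "retained",
                       np.where(reintroduced, "reintroduced", "removed"))
    table = pd.DataFrame({
        "threshold": thresholds,
        "n_pass": n_pass.astype(int),
        "n_biological": n_bio,
        "global_fraction": global_frac,
    })
    for label in groups:
        table[f"group_fraction:{label}"] = group_fracs[label]
    table["max_group_fraction"] = max_group
    table["verdict"] = verdict
    table.index.name = "species"

    report = FilterReport(table=table, params=params, group_labels=list(groups))
    filtered = dataset.subset_species(report.kept_species())
    return filtered, report
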