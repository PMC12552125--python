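"""Class aggregation, percent-of-total normalization, z-scores, fold changes.

Missing species values contribute 0 to sums (absent lipid) but remain
missing for species-level statistics; no imputation anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnnotationError, ZeroTotalError
from .io import LipidomicsDataset

__all__ = [
    "ClassProfile",
    "ZScoreResult",
    "class_totals",
    "percent_of_total",
    "zscore_rows",
    "log2_fold_change",
]


@dataclass
class ClassProfile:
    """Class x sample totals with a companion percent-of-total matrix."""

    totals: pd.DataFrame          # class x sample summed concentrations
    percent: pd.DataFrame         # class x sample, columns sum to 100
    total_lipid: pd.Series        # per-sample total over all species


def class_totals(dataset: LipidomicsDataset,
                 sample_types: tuple[str, ...] = ("biological",)) -> ClassProfile:
    """Sum member species per class and sample.

    Classes present in the registry annotations but without retained
    members appear as all-zero rows.  Missing values count as 0.
    """
    ids = [s.sample_id for s in dataset.samples if s.sample_type in sample_types]
    conc = dataset.concentrations[ids]

    missing = [sp for sp in conc.index if sp not in dataset.species_annotations]
    if missing:
        raise AnnotationError(f"species without annotation: {missing[:5]}"
                              + ("..." if len(missing) > 5 else ""))

    class_of = pd.Series(
        {sp: dataset.species_annotations[sp].lipid_class.code for sp in conc.index})
    totals = conc.fillna(0.0).groupby(class_of).sum()
    # keep every registry class that appears in annotations, plus stable order
    all_codes = sorted({p.lipid_class.code for p in dataset.species_annotations.values()})
    totals = totals.reindex(all_codes, fill_value=0.0)
    totals.index.name = "class"

    total_lipid = totals.sum(axis=0).rename("total_lipid")
    percent = percent_of_total(totals, totals=total_lipid)
    return ClassProfile(totals=totals, percent=percent, total_lipid=total_lipid)


def percent_of_total(matrix: pd.DataFrame,
                     totals: pd.Series | None = None) -> pd.DataFrame:
    """``value * 100 / sample total`` per column.

    ``totals`` lets species-level and class-level matrices share one
    denominator (the summed concentration of all retained species).  When
    omitted, the column sums of ``matrix`` (missing as 0) are used.

    Raises
    ------
    ZeroTotalError
        Naming every sample whose total is zero (or missing).
    """
    if totals is None:
        totals = matrix.fillna(0.0).sum(axis=0)
    totals = totals.reindex(matrix.columns)
    bad = [str(c) for c, t in totals.items() if not np.isfinite(t) or t <= 0]
    if bad:
        raise ZeroTotalError(bad)
    return matrix.div(totals, axis=1) * 100.0


@dataclass
class ZScoreResult:
    """Row-wise z-scores; constant rows are zeroed and flagged."""

    values: pd.DataFrame
    constant_features: list = field(default_factory=list)


def zscore_rows(matrix: pd.DataFrame, ddof: int = 1) -> ZScoreResult:
    """Z-score each row across samples: ``(x - mean) / sd`` (sample sd).

    Rows with zero standard deviation become all zeros and are listed in
    ``constant_features``.  Requires at least 2 samples.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=ddof)
    constant = sd.fillna(0.0) == 0.0
    safe_sd = sd.where(~constant, 1.0)
    z = matrix.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    return ZScoreResult(values=z, constant_features=list(matrix.index[constant]))


def log2_fold_change(matrix: pd.DataFrame,
                     control_samples: list[str],
                     case_samples: list[str] | None = None,
                     per_sample: bool = True,
                     pseudocount: float = 0.0):
    """Log2 fold change against the mean of the control samples.

    Per-sample mode returns a feature x case-sample frame of
    ``log2(x_s / mean(control))``; per-group mode returns one value per
    feature, ``log2(mean(case) / mean(control))``.  Features whose control
    mean is 0 are reported as missing (NaN) unless a ``pseudocount`` is
    supplied.
    """
    if not control_samples:
        raise ValueError("control group is empty")
    if case_samples is None:
        case_samples = [c for c in matrix.columns if c not in set(control_samples)]

    ctrl_mean = matrix[control_samples].mean(axis=1) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        if per_sample:
            num = matrix[case_samples] + pseudocount
            fc = np.log2(num.div(ctrl_mean, axis=0))
            fc[~np.isfinite(fc)] = np.nan
            return fc
        case_mean = matrix[case_samples].mean(axis=1) + pseudocount
        fc = np.log2(case_mean / ctrl_mean)
        return fc.where(np.isfinite(fc)).rename("log2fc")
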