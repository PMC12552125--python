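"""Double-bond (unsaturation) profiles for TG, CE and pooled phospholipids.

For a class pool, species are binned by total double bonds (sum
composition); the per-bin sums are normalized over each sample's total
lipid concentration, and fold changes are taken against the mean of the
control samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, EmptyPoolError
from .io import LipidomicsDataset
from .nomenclature import PHOSPHOLIPID_POOL

__all__ = ["SaturationProfile", "double_bond_profile", "profile_to_frame", "POOLS"]

POOLS: dict[str, frozenset[str]] = {
    "TG": frozenset({"TG"}),
    "CE": frozenset({"CE"}),
    "phospholipids": PHOSPHOLIPID_POOL,
}


@dataclass
class SaturationProfile:
    """Per-double-bond-count sums, normalized values and fold changes."""

    pool: str
    summed: pd.DataFrame       # double_bonds x sample
    normalized: pd.DataFrame   # summed / total lipid per sample
    fold_change: pd.DataFrame  # normalized / mean over control samples
    control_samples: list[str]


def double_bond_profile(dataset: LipidomicsDataset,
                        pool: str,
                        control_group: str,
                        include_sm: bool = False,
                        sample_types: tuple[str, ...] = ("biological",)
                        ) -> SaturationProfile:
    """Compute the saturation profile of ``pool`` against ``control_group``.

    ``pool`` is ``"TG"``, ``"CE"`` or ``"phospholipids"`` (the 7
    glycerophospholipid classes; ``include_sm=True`` adds SM).  The
    normalization denominator is the sample's total over *all* retained
    species, not just the pool.  Double-bond counts with zero abundance in
    every sample are omitted; counts with zero control mean have missing
    fold changes.
    """
    if pool not in POOLS:
        raise ValueError(f"unknown pool {pool!r}; expected one of {sorted(POOLS)}")
    codes = set(POOLS[pool])
    if include_sm and pool == "phospholipids":
        codes.add("SM")

    groups = dataset.groups()
    if control_group not in groups:
        raise DesignError(
            f"control group {control_group!r} not among groups {sorted(groups)}")
    ids = [s.sample_id for s in dataset.samples if s.sample_type in sample_types]
    control_ids = [s for s in groups[control_group] if s in set(ids)]
    if not control_ids:
        raise DesignError(f"control group {control_group!r} has no samples "
                          f"of type {sample_types}")

    conc = dataset.concentrations[ids]
    pool_species = [sp for sp in conc.index
                    if dataset.species_annotations[sp].lipid_class.code in codes]
    if not pool_species:
        raise EmptyPoolError(f"no species left in pool {pool!r} after filtering")

    db_of = pd.Series({sp: dataset.species_annotations[sp].total_double_bonds
                       for sp in pool_species})
    summed = conc.loc[pool_species].fillna(0.0).groupby(db_of).sum()
    summed = summed.loc[summed.any(axis=1)]  # drop all-zero double-bond bins
    summed.index.name = "double_bonds"
    summed = summed.sort_index()

    total_lipid = conc.fillna(0.0).sum(axis=0)
    normalized = summed.div(total_lipid, axis=1)

    ctrl_mean = normalized[control_ids].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_change = normalized.div(ctrl_mean, axis=0)
    fold_change = fold_change.where(np.isfinite(fold_change))

    return SaturationProfile(pool=pool, summed=summed, normalized=normalized,
                             fold_change=fold_change, control_samples=control_ids)


def profile_to_frame(profile: SaturationProfile) -> pd.DataFrame:
    """Long-format export: pool, double_bonds, sample, summed, normalized,
    fold_change."""
    parts = []
    for name, frame in (("summed", profile.summed),
                        ("normalized", profile.normalized),
                        ("fold_change", profile.fold_change)):
        long = (frame.rename_axis(index="double_bonds", columns="sample")
                .stack(future_stack=True).rename(name))
        parts.append(long)
    out = pd.concat(parts, axis=1).reset_index()
    out.insert(0, "pool", profile.pool)
    return out
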