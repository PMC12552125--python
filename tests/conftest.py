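"""Shared fixtures: hand-built small datasets and random dataset factories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lipidkit.io import LipidomicsDataset, SampleAnnotation, build_dataset


def make_dataset(values: dict[str, list], sample_specs: list[tuple],
                 unit: str = "uM") -> LipidomicsDataset:
    """Build a dataset from a {species: row} dict and sample specs.

    Each sample spec is ``(sample_id, sample_type, group_vars_dict)`` or
    ``(sample_id, sample_type, group_vars_dict, replicate_id)``.
    """
    sample_ids = [s[0] for s in sample_specs]
    matrix = pd.DataFrame(values, index=sample_ids).T
    annotations = []
    for spec in sample_specs:
        sid, stype, gvars = spec[0], spec[1], spec[2]
        rep = spec[3] if len(spec) > 3 else None
        annotations.append(SampleAnnotation(sid, stype, dict(gvars), rep))
    return build_dataset(matrix, annotations, unit=unit)


@pytest.fixture
def tiny_dataset() -> LipidomicsDataset:
    """3 species x (4 biological + 2 blank + 1 qc), two groups."""
    samples = [
        ("s1", "biological", {"genotype": "E3"}),
        ("s2", "biological", {"genotype": "E3"}),
        ("s3", "biological", {"genotype": "E4"}),
        ("s4", "biological", {"genotype": "E4"}),
        ("b1", "blank", {}),
        ("b2", "blank", {}),
        ("q1", "qc", {}),
    ]
    values = {
        "CE 18:1": [2.0, 3.0, 4.0, 5.0, 0.1, 0.1, 3.0],
        "TG 16:0_18:1_18:2": [5.0, 5.0, 6.0, 4.0, 0.2, 0.2, 5.0],
        "PC 16:0/20:4": [10.0, 12.0, 9.0, 11.0, 0.1, 0.3, 10.0],
    }
    return make_dataset(values, samples)


def random_small_dataset(rng: np.random.Generator,
                         force_boundaries: bool = False) -> LipidomicsDataset:
    """Random dataset for filter-oracle comparisons.

    <= 12 species x <= 10 biological samples in <= 3 groups, 1-2 blanks.
    With ``force_boundaries`` the sample counts are chosen so that pass
    fractions can land exactly on 0.8 and 0.6.
    """
    species_pool = [
        "CE 16:0", "CE 18:1", "CE 20:4", "TG 48:1", "TG 52:3", "TG 54:6",
        "PC 16:0_18:1", "PC 18:0_20:4", "PE 16:0_18:1", "SM 34:1",
        "FFA 18:1", "LPC 16:0",
    ]
    n_species = int(rng.integers(3, 13))
    species = list(rng.choice(species_pool, size=n_species, replace=False))

    if force_boundaries:
        n_bio, n_groups = 10, 2  # groups of 5: fractions in steps of 0.2 / 0.1
    else:
        n_bio = int(rng.integers(4, 11))
        n_groups = int(rng.integers(1, 4))
    n_blanks = int(rng.integers(1, 3))

    samples = []
    for i in range(n_bio):
        group = f"g{i % n_groups}"
        samples.append((f"s{i}", "biological", {"group": group}))
    for i in range(n_blanks):
        samples.append((f"b{i}", "blank", {}))

    values = {}
    for sp in species:
        blank_vals = rng.uniform(0.5, 2.0, size=n_blanks)
        bio_vals = rng.uniform(0.0, 8.0, size=n_bio)
        # sprinkle missing values
        miss = rng.random(n_bio) < 0.15
        bio_vals = np.where(miss, np.nan, bio_vals)
        values[sp] = list(bio_vals) + list(blank_vals)
    return make_dataset(values, samples)
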