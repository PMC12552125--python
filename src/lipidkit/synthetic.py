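"""Synthetic shotgun-lipidomics datasets with realistic lipotype structure.

The generator emulates the statistical shape of a targeted
Lipidyzer/SLA-style species table: cell-type lipotype templates over the
16-class registry, multiplicative log-normal noise, blank background,
experiment nesting for paired designs, and injectable class/species-level
effects.  Everything here is synthetic: class fractions, species rosters
and effect sizes are the generator's own documented parameters, not
measurements, chosen only to satisfy the qualitative orderings the
analysis is meant to detect.

Concentration model, per biological sample ``s`` and species ``i``::

    c[s, i] = total * class_fraction * weight_i * multiplier(i, group) * exp(eps)

with ``eps ~ Normal(0, sigma^2)``, ``sigma = sqrt(ln(1 + cv^2))``.  Blank
samples draw independent log-normals at ``blank_level`` times the typical
biological signal.  A configurable number of species is rescaled to blank
level (exercising removal) and a configurable number is expressed in only
one group (exercising group-wise reintroduction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError
from .io import LipidomicsDataset, SampleAnnotation, build_dataset
from .nomenclature import PHOSPHOLIPID_POOL, ParsedLipid, parse_species

__all__ = [
    "LipotypeTemplate",
    "TargetSelector",
    "EffectSpec",
    "GroupSpec",
    "make_templates",
    "make_effects",
    "null_effect",
    "simulate_dataset",
    "default_rosters",
]

# ---------------------------------------------------------------------------
# species rosters (synthetic grids; NOT a vendor panel)

_CHAINS_MAIN = ("14:0", "16:0", "16:1", "18:0", "18:1", "18:2", "18:3",
                "20:3", "20:4", "20:5", "22:4", "22:5", "22:6", "24:0")
_CHAINS_MINOR = _CHAINS_MAIN[:10]


def _pairs(class_code: str, chains: Sequence[str]) -> list[str]:
    out = []
    for a, b in itertools.combinations_with_replacement(chains, 2):
        out.append(f"{class_code} {a}_{b}")
    return out


def _grid(class_code: str, carbons: Sequence[int], dbs: Sequence[int]) -> list[str]:
    return [f"{class_code} {c}:{d}" for c in carbons for d in dbs]


@lru_cache(maxsize=4)
def default_rosters(size: str = "full") -> dict[str, list[str]]:
    """Species names per class. ``size``: "full" (>= 1000 names) or "small"
    (a few per class, for fast simulation loops)."""
    if size == "small":
        rosters = {
            "CE": _grid("CE", [16, 18, 20], [0, 1]),
            "CER": _grid("CER", [34, 40], [1]),
            "DCER": _grid("DCER", [34, 40], [0]),
            "HCER": _grid("HCER", [34, 40], [1]),
            "LCER": _grid("LCER", [34, 40], [1]),
            "DG": ["DG 16:0_18:1", "DG 18:1_18:1", "DG 18:1_18:2"],
            "FFA": _grid("FFA", [16, 18, 22], [0, 1]),
            "LPC": _grid("LPC", [16, 18], [0, 1]),
            "LPE": _grid("LPE", [16, 18], [0, 1]),
            "PC": ["PC 16:0_18:1", "PC 16:0_20:4", "PC 18:0_18:1", "PC 18:1_18:2"],
            "PE": ["PE 16:0_18:1", "PE 18:0_20:4", "PE 18:1_18:1"],
            "PG": ["PG 16:0_18:1", "PG 18:1_18:1"],
            "PI": ["PI 16:0_20:4", "PI 18:0_20:4"],
            "PS": ["PS 18:0_18:1", "PS 18:0_20:4"],
            "SM": _grid("SM", [34, 36, 42], [1, 2]),
            "TG": _grid("TG", [48, 52, 54], [0, 1, 3, 6]),
        }
        return rosters
    if size != "full":
        raise ValueError(f"unknown roster size {size!r}")
    rosters = {
        "PC": _pairs("PC", _CHAINS_MAIN),
        "PE": _pairs("PE", _CHAINS_MAIN),
        "PG": _pairs("PG", _CHAINS_MINOR),
        "PI": _pairs("PI", _CHAINS_MINOR),
        "PS": _pairs("PS", _CHAINS_MINOR),
        "LPC": [f"LPC {c}" for c in _CHAINS_MAIN],
        "LPE": [f"LPE {c}" for c in _CHAINS_MAIN],
        "SM": _grid("SM", range(30, 45, 2), range(0, 4)),
        "CER": _grid("CER", range(30, 45, 2), range(0, 3)),
        "DCER": _grid("DCER", range(30, 45, 2), range(0, 3)),
        "HCER": _grid("HCER", range(30, 45, 2), range(0, 3)),
        "LCER": _grid("LCER", range(30, 45, 2), range(0, 3)),
        "CE": _grid("CE", range(12, 25), range(0, 8)),
        "FFA": _grid("FFA", range(12, 25), range(0, 8)),
        "DG": _pairs("DG", _CHAINS_MINOR),
        "TG": _grid("TG", range(40, 65, 2), range(0, 16)),
    }
    return rosters


def _roster_weights(names: Sequence[str]) -> np.ndarray:
    """Deterministic unimodal within-class weights (sum to 1)."""
    parsed = [parse_species(n) for n in names]
    carbons = np.array([p.total_carbons for p in parsed], dtype=float)
    dbs = np.array([p.total_double_bonds for p in parsed], dtype=float)
    c_mid = (carbons.min() + carbons.max()) / 2.0
    c_span = max(carbons.max() - carbons.min(), 1.0)
    w = np.exp(-((carbons - c_mid) / (c_span / 2.5)) ** 2
               - ((dbs - 1.5) / 3.0) ** 2)
    return w / w.sum()


# ---------------------------------------------------------------------------
# templates

@dataclass(frozen=True)
class LipotypeTemplate:
    """Target class fractions + per-class species rosters with weights."""

    name: str
    class_fractions: Mapping[str, float]
    species_weights: Mapping[str, tuple[tuple[str, float], ...]]
    noise_cv: float = 0.2
    blank_level: float = 0.01

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"class fractions sum to {total}, expected 1")
        for code, pairs in self.species_weights.items():
            wsum = sum(w for _, w in pairs)
            if not np.isclose(wsum, 1.0, atol=1e-9):
                raise ValueError(f"weights for {code} sum to {wsum}")

    def species(self) -> list[str]:
        return [name for pairs in self.species_weights.values()
                for name, _ in pairs]

    def expected_concentrations(self, total_lipid: float = 1.0) -> pd.Series:
        """Noise-free expected concentration per species."""
        data = {}
        for code, pairs in self.species_weights.items():
            frac = self.class_fractions[code]
            for name, w in pairs:
                data[name] = total_lipid * frac * w
        return pd.Series(data)


# Synthetic class fractions.  Chosen (not measured) to satisfy the
# qualitative cross-cell-type orderings the analysis must recover:
# PC+PE dominant everywhere and maximal in neurons; SM microglia >
# astrocyte > neuron; CE/DG maximal in astrocytes; CER/LPC/LPE maximal in
# neurons; TG/FFA/PS maximal in microglia; PG low in microglia.
_TEMPLATE_FRACTIONS: dict[str, dict[str, float]] = {
    "iNeuron": {
        "PC": 0.36, "PE": 0.27, "PI": 0.04, "PS": 0.025, "PG": 0.02,
        "LPC": 0.035, "LPE": 0.025, "SM": 0.01, "CER": 0.05, "DCER": 0.008,
        "HCER": 0.012, "LCER": 0.005, "CE": 0.015, "DG": 0.03, "TG": 0.06,
        "FFA": 0.035,
    },
    "iAstrocyte": {
        "PC": 0.30, "PE": 0.219, "PI": 0.045, "PS": 0.05, "PG": 0.03,
        "LPC": 0.02, "LPE": 0.012, "SM": 0.04, "CER": 0.03, "DCER": 0.006,
        "HCER": 0.009, "LCER": 0.004, "CE": 0.06, "DG": 0.05, "TG": 0.08,
        "FFA": 0.045,
    },
    "iMicroglia": {
        "PC": 0.30, "PE": 0.232, "PI": 0.04, "PS": 0.055, "PG": 0.012,
        "LPC": 0.015, "LPE": 0.01, "SM": 0.07, "CER": 0.02, "DCER": 0.005,
        "HCER": 0.01, "LCER": 0.006, "CE": 0.03, "DG": 0.04, "TG": 0.10,
        "FFA": 0.055,
    },
}


def make_templates(noise_cv: float = 0.2, blank_level: float = 0.01,
                   roster_size: str = "full") -> dict[str, LipotypeTemplate]:
    """Built-in cell-type templates: iNeuron, iAstrocyte, iMicroglia."""
    rosters = default_rosters(roster_size)
    templates = {}
    for name, fractions in _TEMPLATE_FRACTIONS.items():
        weights = {}
        for code, names in rosters.items():
            w = _roster_weights(names)
            weights[code] = tuple(zip(names, w.tolist()))
        total = sum(fractions.values())
        fracs = {k: v / total for k, v in fractions.items()}
        templates[name] = LipotypeTemplate(
            name=name, class_fractions=fracs, species_weights=weights,
            noise_cv=noise_cv, blank_level=blank_level)
    return templates


# ---------------------------------------------------------------------------
# effects

@dataclass(frozen=True)
class TargetSelector:
    """Selects species by class set, double-bond window and/or explicit set."""

    classes: frozenset[str] | None = None
    min_double_bonds: int | None = None
    max_double_bonds: int | None = None
    species: frozenset[str] | None = None

    def matches(self, parsed: ParsedLipid, canonical: str) -> bool:
        if self.species is not None and canonical not in self.species:
            return False
        if self.classes is not None and parsed.lipid_class.code not in self.classes:
            return False
        db = parsed.total_double_bonds
        if self.min_double_bonds is not None and db < self.min_double_bonds:
            return False
        if self.max_double_bonds is not None and db > self.max_double_bonds:
            return False
        return True


@dataclass(frozen=True)
class EffectSpec:
    """Named set of (selector, multiplier) perturbations for one group."""

    name: str
    targets: tuple[tuple[TargetSelector, float], ...] = ()

    def __post_init__(self):
        for _, mult in self.targets:
            if not (np.isfinite(mult) and mult > 0):
                raise ValueError(f"multiplier must be finite and positive: {mult}")

    def multiplier(self, parsed: ParsedLipid, canonical: str) -> float:
        m = 1.0
        for selector, mult in self.targets:
            if selector.matches(parsed, canonical):
                m *= mult
        return m


def null_effect() -> EffectSpec:
    return EffectSpec("null", ())


def make_effects(ce_up: float = 2.0, tg_up: float = 1.6, sm_down: float = 0.6,
                 ce_down: float = 0.4, tg_down: float = 0.5,
                 sat_pl_up: float = 1.5, lcer_up: float = 2.0,
                 hcer_up: float = 1.8) -> dict[str, EffectSpec]:
    """Built-in effect signatures (synthetic default multipliers).

    ``apoe4``: all CE species up; saturated/monounsaturated and highly
    polyunsaturated (>5 double bonds) TGs up; SM down.  ``reactive``: CE
    and TG down; saturated/monounsaturated phospholipids up; LacCER and
    HexCER up.  ``cholesterol_load``: CE up plus saturated phospholipids
    up.
    """
    pl = frozenset(PHOSPHOLIPID_POOL)
    apoe4 = EffectSpec("apoe4", (
        (TargetSelector(classes=frozenset({"CE"})), ce_up),
        (TargetSelector(classes=frozenset({"TG"}), max_double_bonds=1), tg_up),
        (TargetSelector(classes=frozenset({"TG"}), min_double_bonds=6), tg_up),
        (TargetSelector(classes=frozenset({"SM"})), sm_down),
    ))
    reactive = EffectSpec("reactive", (
        (TargetSelector(classes=frozenset({"CE"})), ce_down),
        (TargetSelector(classes=frozenset({"TG"})), tg_down),
        (TargetSelector(classes=pl, max_double_bonds=1), sat_pl_up),
        (TargetSelector(classes=frozenset({"LCER"})), lcer_up),
        (TargetSelector(classes=frozenset({"HCER"})), hcer_up),
    ))
    cholesterol_load = EffectSpec("cholesterol_load", (
        (TargetSelector(classes=frozenset({"CE"})), ce_up),
        (TargetSelector(classes=pl, max_double_bonds=1), 1.4),
    ))
    return {"apoe4": apoe4, "reactive": reactive,
            "cholesterol_load": cholesterol_load}


# ---------------------------------------------------------------------------
# simulation

@dataclass
class GroupSpec:
    """One experimental group: name, size, template and optional effect."""

    name: str
    n_samples: int
    template: LipotypeTemplate
    effect: EffectSpec | None = None
    group_vars: dict[str, str] = field(default_factory=dict)

    def vars_or_default(self) -> dict[str, str]:
        return dict(self.group_vars) if self.group_vars else {"condition": self.name}


def _sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def simulate_dataset(groups: Sequence[GroupSpec],
                     seed: int,
                     n_experiments: int = 3,
                     n_blanks: int = 2,
                     n_qc: int = 1,
                     total_lipid: float = 1000.0,
                     noise_cv: float | None = None,
                     n_near_blank: int = 20,
                     n_group_exclusive: int = 4,
                     missing_rate: float = 0.0,
                     unit: str = "uM") -> tuple[LipidomicsDataset, dict]:
    """Simulate a dataset; same seed -> byte-identical matrices.

    All groups must share one species roster (templates may differ in
    class fractions).  ``n_near_blank`` species are rescaled to blank
    level (candidates for removal); ``n_group_exclusive`` species are
    expressed in a single group only (candidates for reintroduction;
    requires >= 2 groups to matter).  ``replicate_id`` encodes experiment
    nesting (samples assigned round-robin to ``exp1..expN`` within each
    group) for paired tests.

    Returns (dataset, generation manifest).
    """
    if not groups:
        raise DesignError("at least one group required")
    for g in groups:
        if g.n_samples < 1:
            raise DesignError(f"group {g.name!r} must have n >= 1")
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise DesignError(f"duplicate group names: {names}")
    if n_blanks < 1:
        raise DesignError("need at least one blank sample")
    if n_experiments < 1:
        raise DesignError("need at least one experiment")
    if not 0.0 <= missing_rate < 1.0:
        raise DesignError("missing_rate must be in [0, 1)")

    species = groups[0].template.species()
    for g in groups[1:]:
        if g.template.species() != species:
            raise DesignError("all group templates must share one species roster")
    n_species = len(species)
    parsed = {name: parse_species(name) for name in species}
    canonical = {name: parsed[name].canonical for name in species}

    rng = np.random.default_rng(seed)

    # per-group noise-free expectations, including effect multipliers
    base_by_group = {}
    for g in groups:
        base = g.template.expected_concentrations(total_lipid)[species].to_numpy()
        if g.effect is not None:
            mult = np.array([g.effect.multiplier(parsed[n], canonical[n])
                             for n in species])
            base = base * mult
        base_by_group[g.name] = base

    blank_level = groups[0].template.blank_level
    typical = np.mean(np.stack([g.template.expected_concentrations(total_lipid)
                                [species].to_numpy() for g in groups]), axis=0)
    blank_base = blank_level * typical

    # species drawn near blank level / expressed in one group only
    pick = rng.permutation(n_species)
    n_near = min(n_near_blank, n_species)
    near_blank_idx = pick[:n_near]
    n_excl = min(n_group_exclusive, n_species - n_near)
    exclusive_idx = pick[n_near:n_near + n_excl]
    host_of = {int(i): groups[k % len(groups)].name
               for k, i in enumerate(exclusive_idx)}

    for g in groups:
        base = base_by_group[g.name]
        base[near_blank_idx] = blank_base[near_blank_idx]
        for i, host in host_of.items():
            if host != g.name:
                base[i] = base[i] * 0.01

    columns: dict[str, np.ndarray] = {}
    annotations: list[SampleAnnotation] = []
    for g in groups:
        cv = g.template.noise_cv if noise_cv is None else noise_cv
        sigma = _sigma(cv)
        for i in range(g.n_samples):
            sid = f"{g.name}_{i + 1:02d}"
            eps = rng.normal(0.0, sigma, size=n_species) if sigma > 0 else 0.0
            columns[sid] = base_by_group[g.name] * np.exp(eps)
            annotations.append(SampleAnnotation(
                sample_id=sid, sample_type="biological",
                group_vars=g.vars_or_default(),
                replicate_id=f"exp{(i % n_experiments) + 1}"))

    blank_sigma = _sigma(groups[0].template.noise_cv if noise_cv is None
                         else noise_cv)
    for i in range(n_blanks):
        sid = f"blank_{i + 1}"
        eps = rng.normal(0.0, blank_sigma, size=n_species)
        columns[sid] = blank_base * np.exp(eps)
        annotations.append(SampleAnnotation(sample_id=sid, sample_type="blank"))

    qc_base = np.mean(np.stack(list(base_by_group.values())), axis=0)
    for i in range(n_qc):
        sid = f"qc_{i + 1}"
        eps = rng.normal(0.0, blank_sigma, size=n_species)
        columns[sid] = qc_base * np.exp(eps)
        annotations.append(SampleAnnotation(sample_id=sid, sample_type="qc"))

    matrix = pd.DataFrame(columns, index=[canonical[n] for n in species])
    matrix.index.name = "species"

    if missing_rate > 0:
        bio_ids = [a.sample_id for a in annotations if a.sample_type == "biological"]
        mask = rng.random((n_species, len(bio_ids))) < missing_rate
        sub = matrix[bio_ids].to_numpy()
        sub[mask] = np.nan
        matrix[bio_ids] = sub

    dataset = build_dataset(matrix, annotations, unit=unit)
    manifest = {
        "synthetic": True,
        "seed": int(seed),
        "total_lipid": total_lipid,
        "n_experiments": n_experiments,
        "groups": [
            {"name": g.name, "n_samples": g.n_samples,
             "template": g.template.name,
             "noise_cv": g.template.noise_cv if noise_cv is None else noise_cv,
             "effect": g.effect.name if g.effect else None}
            for g in groups
        ],
        "blank_level": blank_level,
        "n_blanks": n_blanks,
        "n_qc": n_qc,
        "near_blank_species": sorted(canonical[species[int(i)]]
                                     for i in near_blank_idx),
        "group_exclusive_species": {canonical[species[i]]: host
                                    for i, host in host_of.items()},
        "missing_rate": missing_rate,
        "n_species": n_species,
    }
    return dataset, manifest
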