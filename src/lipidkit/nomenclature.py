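"""Lipid shorthand nomenclature: parsing, validation and canonical names.

Species are written in the compact shorthand convention used by targeted
shotgun-lipidomics platforms, e.g. ``"CE 18:1"``, ``"PC 16:0/20:4"`` or
``"TG 16:0_18:1_18:2"``: a class token followed by one or more
``carbons:double_bonds`` chain descriptors.  ``/`` separates chains whose
sn-positions are known, ``_`` chains whose positions are not.  A single
chain descriptor on a multi-chain class denotes the *sum composition*
(total carbons : total double bonds over all chains).

The default registry covers the 16 classes quantified by the
Lipidyzer/SLA panel.  Ether/oxygen-modified species (``O-``/``P-``
prefixes) are deliberately rejected: the panel does not report them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Iterable

import pandas as pd

from .errors import ParseError, UnknownClassError

__all__ = [
    "LipidCategory",
    "LipidClass",
    "ParsedLipid",
    "default_registry",
    "parse_species",
    "sum_composition",
    "canonical_name",
    "annotation_frame",
    "PHOSPHOLIPID_POOL",
    "SYNONYMS",
    "DIALECTS",
]


class LipidCategory(str, Enum):
    NEUTRAL = "neutral/storage"
    PHOSPHOLIPID = "phospholipid"
    LYSOPHOSPHOLIPID = "lysophospholipid"
    SPHINGOLIPID = "sphingolipid"
    FATTY_ACID = "fatty acid"


@dataclass(frozen=True)
class LipidClass:
    """One entry of the class registry.

    ``n_chains`` is the number of chain descriptors expected at full
    molecular-species resolution (the backbone counts as a chain for
    sphingolipids, matching how the panel writes them).
    """

    code: str
    display_name: str
    category: LipidCategory
    n_chains: int


_DEFAULT_CLASSES: tuple[LipidClass, ...] = (
    LipidClass("CE", "CE", LipidCategory.NEUTRAL, 1),
    LipidClass("CER", "CER", LipidCategory.SPHINGOLIPID, 2),
    LipidClass("DCER", "dhCER", LipidCategory.SPHINGOLIPID, 2),
    LipidClass("HCER", "HexCER", LipidCategory.SPHINGOLIPID, 2),
    LipidClass("LCER", "LacCER", LipidCategory.SPHINGOLIPID, 2),
    LipidClass("DG", "DAG", LipidCategory.NEUTRAL, 2),
    LipidClass("FFA", "FFA", LipidCategory.FATTY_ACID, 1),
    LipidClass("LPC", "LPC", LipidCategory.LYSOPHOSPHOLIPID, 1),
    LipidClass("LPE", "LPE", LipidCategory.LYSOPHOSPHOLIPID, 1),
    LipidClass("PC", "PC", LipidCategory.PHOSPHOLIPID, 2),
    LipidClass("PE", "PE", LipidCategory.PHOSPHOLIPID, 2),
    LipidClass("PG", "PG", LipidCategory.PHOSPHOLIPID, 2),
    LipidClass("PI", "PI", LipidCategory.PHOSPHOLIPID, 2),
    LipidClass("PS", "PS", LipidCategory.PHOSPHOLIPID, 2),
    LipidClass("SM", "SM", LipidCategory.SPHINGOLIPID, 2),
    LipidClass("TG", "TAG", LipidCategory.NEUTRAL, 3),
)

#: Glycerophospholipid + lyso pool used for saturation profiling.
PHOSPHOLIPID_POOL = frozenset({"PC", "PE", "PG", "PI", "PS", "LPC", "LPE"})

#: Upper-cased synonym -> registry code.
SYNONYMS = {
    "TAG": "TG",
    "DAG": "DG",
    "FA": "FFA",
    "HEXCER": "HCER",
    "LACCER": "LCER",
    "DHCER": "DCER",
    "CHE": "CE",
}

DIALECTS = ("lipidyzer", "lipidmaps-2020")


def default_registry() -> dict[str, LipidClass]:
    """Return the default 16-class registry as ``{code: LipidClass}``."""
    return {c.code: c for c in _DEFAULT_CLASSES}


_REGISTRY = default_registry()


@dataclass(frozen=True)
class ParsedLipid:
    """A species name decomposed into class and chain composition."""

    lipid_class: LipidClass
    chains: tuple[tuple[int, int], ...]
    chain_level: str  # "sum-only" | "molecular-species"
    positions_known: bool = False

    @property
    def canonical(self) -> str:
        return canonical_name(self)

    @property
    def total_carbons(self) -> int:
        return sum(c for c, _ in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(d for _, d in self.chains)


_CHAIN_RE = re.compile(r"^(\d+):(\d+)$")
_ETHER_RE = re.compile(r"^[OoPp]-")
_CLASS_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)\s*[\s(]\s*")


@lru_cache(maxsize=200_000)
def _parse_cached(stripped: str, offset: int, dialect: str) -> ParsedLipid:
    m = _CLASS_RE.match(stripped)
    if m is None:
        raise ParseError(f"cannot split class token from {stripped!r}",
                         position=offset)
    token = m.group(1)
    code = SYNONYMS.get(token.upper(), token.upper())
    lipid_class = _REGISTRY.get(code)
    if lipid_class is None:
        raise UnknownClassError(token, position=offset)

    rest = stripped[m.end():].rstrip()
    rest_offset = offset + m.end()
    if rest.endswith(")"):
        rest = rest[:-1].rstrip()
    if not rest:
        raise ParseError("missing chain specification", position=rest_offset)

    if "/" in rest and "_" in rest:
        raise ParseError("mixed '/' and '_' chain separators",
                         position=rest_offset + rest.index("_"))
    positions_known = "/" in rest

    chains: list[tuple[int, int]] = []
    cursor = 0
    for part in re.split(r"[/_]", rest):
        pos = rest_offset + cursor
        cursor += len(part) + 1
        spec = part.strip()
        if _ETHER_RE.match(spec):
            raise ParseError(
                f"ether/oxygen-modified chain {spec!r} not supported",
                position=pos)
        cm = _CHAIN_RE.match(spec.replace(" ", ""))
        if cm is None:
            raise ParseError(f"malformed chain spec {part.strip()!r}",
                             position=pos)
        chains.append((int(cm.group(1)), int(cm.group(2))))

    if len(chains) == 1:
        chain_level = "sum-only"
        positions_known = False
    else:
        if len(chains) != lipid_class.n_chains:
            raise ParseError(
                f"class {lipid_class.code} expects {lipid_class.n_chains} "
                f"chains, got {len(chains)}", position=rest_offset)
        chain_level = "molecular-species"

    return ParsedLipid(lipid_class, tuple(chains), chain_level, positions_known)


def parse_species(name: str, dialect: str = "lipidyzer") -> ParsedLipid:
    """Parse a shorthand species name into a :class:`ParsedLipid`.

    Class tokens are case-insensitive and synonyms (TAG, DAG, FA, HexCER,
    LacCER, ...) are mapped onto the 16-code registry.  Both chain
    separators are accepted; whitespace around tokens is ignored.

    Raises
    ------
    UnknownClassError
        If the class token is not in the registry.
    ParseError
        For malformed chain specs (with the character position) and for
        ether-modified species.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if name is None or not str(name).strip():
        raise ParseError("empty species name", position=0)
    name = str(name)
    offset = len(name) - len(name.lstrip())
    # Single-token names ("CE 18:1" has a space; "CE18:1" does not) --
    # normalize by inserting a space before the first digit if needed.
    stripped = name.strip()
    if " " not in stripped and "(" not in stripped:
        m = re.search(r"\d", stripped)
        if m is None:
            raise ParseError(f"cannot split class token from {stripped!r}",
                             position=offset)
        stripped = stripped[:m.start()] + " " + stripped[m.start():]
    return _parse_cached(stripped, offset, dialect)


def sum_composition(p: ParsedLipid) -> tuple[int, int]:
    """Total (carbons, double bonds) over all chains of ``p``."""
    return (p.total_carbons, p.total_double_bonds)


def canonical_name(p: ParsedLipid) -> str:
    """Deterministic canonical string form of a parsed species.

    Chains are sorted ascending by (carbons, double bonds); the separator
    is ``/`` when sn-positions were declared known, otherwise ``_``.
    """
    sep = "/" if p.positions_known else "_"
    chains = sorted(p.chains)
    return f"{p.lipid_class.code} " + sep.join(f"{c}:{d}" for c, d in chains)


def annotation_frame(species: Iterable[str],
                     dialect: str = "lipidyzer") -> pd.DataFrame:
    """Annotation export: one row per species.

    Columns: ``species, class, total_carbons, total_double_bonds, canonical``.
    """
    rows = []
    for name in species:
        p = parse_species(name, dialect=dialect)
        tc, td = sum_composition(p)
        rows.append({
            "species": name,
            "class": p.lipid_class.code,
            "total_carbons": tc,
            "total_double_bonds": td,
            "canonical": canonical_name(p),
        })
    return pd.DataFrame(rows, columns=[
        "species", "class", "total_carbons", "total_double_bonds", "canonical"])
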