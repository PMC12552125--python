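"""Reading/writing concentration tables and metadata; dataset assembly.

Input contract: a wide CSV/TSV concentration table (rows = species in
shorthand notation, columns = samples, one consistent unit) plus a sample
metadata sheet carrying sample type (biological / blank / qc) and any
number of grouping variables.  Zeros are measured zeros; only the tokens
``""``, ``NA`` and ``NaN`` denote missing values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateSpeciesError,
    MetadataError,
    ParseError,
    ValidationError,
)
from .nomenclature import ParsedLipid, parse_species, sum_composition

__all__ = [
    "SampleAnnotation",
    "LipidomicsDataset",
    "ValidationReport",
    "read_concentration_table",
    "read_metadata",
    "validate_dataset",
    "build_dataset",
    "write_dataset",
    "read_dataset",
    "to_tidy",
    "GROUP_SEPARATOR",
]

#: Missing-value tokens (case-insensitive).  "0" is a measured zero.
MISSING_TOKENS = frozenset({"", "na", "nan"})

#: Separator used when concatenating grouping variables into one label.
GROUP_SEPARATOR = "|"

_RESERVED_ID = ("sample_id", "sample id", "sampleid", "sample")
_RESERVED_TYPE = ("sample_type", "sample type", "type")
_RESERVED_REPLICATE = ("replicate_id", "replicate", "experiment")

_TYPE_ALIASES = {
    "sample": "biological",
    "biological": "biological",
    "bio": "biological",
    "blank": "blank",
    "qc": "qc",
    "pool": "qc",
}

_FLOAT_FORMAT = "%.12g"


@dataclass
class SampleAnnotation:
    """Per-sample metadata: type, grouping variables, optional pairing key."""

    sample_id: str
    sample_type: str  # "biological" | "blank" | "qc"
    group_vars: dict[str, str] = field(default_factory=dict)
    replicate_id: str | None = None
    extras: dict[str, str] = field(default_factory=dict)

    @property
    def group_label(self) -> str:
        """All grouping variables concatenated (declared order) or ``all``."""
        if not self.group_vars:
            return "all"
        return GROUP_SEPARATOR.join(str(v) for v in self.group_vars.values())


@dataclass
class LipidomicsDataset:
    """Species x sample concentration matrix plus sample/species annotations."""

    concentrations: pd.DataFrame  # index: canonical species, columns: sample ids
    species_annotations: dict[str, ParsedLipid]
    samples: list[SampleAnnotation]
    unit: str = "uM"

    def sample_ids(self, sample_type: str | None = None) -> list[str]:
        if sample_type is None:
            return [s.sample_id for s in self.samples]
        return [s.sample_id for s in self.samples if s.sample_type == sample_type]

    @property
    def biological_samples(self) -> list[SampleAnnotation]:
        return [s for s in self.samples if s.sample_type == "biological"]

    def groups(self) -> dict[str, list[str]]:
        """Group label -> biological sample ids, preserving sample order."""
        out: dict[str, list[str]] = {}
        for s in self.biological_samples:
            out.setdefault(s.group_label, []).append(s.sample_id)
        return out

    def group_of(self) -> dict[str, str]:
        """Biological sample id -> group label."""
        return {s.sample_id: s.group_label for s in self.biological_samples}

    def replicate_of(self) -> dict[str, str]:
        return {s.sample_id: s.replicate_id for s in self.biological_samples
                if s.replicate_id is not None}

    def annotation(self, species: str) -> ParsedLipid:
        return self.species_annotations[species]

    def subset_species(self, species: Iterable[str]) -> "LipidomicsDataset":
        keep = [sp for sp in self.concentrations.index if sp in set(species)]
        return LipidomicsDataset(
            concentrations=self.concentrations.loc[keep].copy(),
            species_annotations={sp: self.species_annotations[sp] for sp in keep},
            samples=list(self.samples),
            unit=self.unit,
        )

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {"sample_id": s.sample_id, "sample_type": s.sample_type,
                   "replicate_id": s.replicate_id if s.replicate_id is not None else ""}
            row.update(s.group_vars)
            rows.append(row)
        return pd.DataFrame(rows)


def _canonical_or_raw(name: str) -> str:
    try:
        return parse_species(name).canonical
    except ParseError:
        return name


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                       index_col=0)


def read_concentration_table(path: str | Path,
                             orientation: str = "species_rows") -> pd.DataFrame:
    """Read a wide concentration table into a species x sample float frame.

    ``orientation`` is ``species_rows`` (default: first column = species
    names) or ``samples_rows`` (transposed layout).  Species names that
    parse are replaced by their canonical form; unparseable names are kept
    verbatim for :func:`validate_dataset` to report.

    Raises
    ------
    DuplicateSpeciesError
        If two rows collapse onto the same canonical species name.
    ParseError
        For non-numeric cells, with (row, column) coordinates.
    """
    if orientation not in ("species_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_delimited(path)
    if orientation == "samples_rows":
        raw = raw.T

    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, idx in enumerate(raw.index):
            cell = str(raw.iat[i, j]).strip()
            if cell.lower() in MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(f"non-numeric cell {cell!r}",
                                 coordinates=(idx, col)) from None

    matrix = pd.DataFrame(values, index=raw.index.astype(str).str.strip(),
                          columns=raw.columns.astype(str).str.strip())

    canonical = [_canonical_or_raw(n) for n in matrix.index]
    collisions: dict[str, list[str]] = {}
    seen: dict[str, str] = {}
    for raw_name, canon in zip(matrix.index, canonical):
        if canon in seen:
            collisions.setdefault(canon, [seen[canon]]).append(raw_name)
        else:
            seen[canon] = raw_name
    if collisions:
        raise DuplicateSpeciesError(collisions)
    matrix.index = pd.Index(canonical, name="species")
    matrix.columns.name = "sample"
    return matrix


def _find_column(columns: Sequence[str], aliases: Sequence[str]) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    return None


def read_metadata(path: str | Path, group_columns: Sequence[str] | None = None,
                  orientation: str = "auto") -> list[SampleAnnotation]:
    """Read a sample metadata sheet into :class:`SampleAnnotation` records.

    The sheet may list samples as rows (default layout) or as columns with
    field names in the first column (the upload-template layout);
    ``orientation="auto"`` detects the latter by looking for a reserved
    field name in the first column.

    Reserved fields: sample id, sample type, replicate/experiment.  All
    other columns are grouping variables unless ``group_columns``
    restricts them; non-grouping extras are carried as pass-through
    annotations.
    """
    sheet = _read_delimited(path).reset_index()
    sheet.columns = [str(c).strip() for c in sheet.columns]

    if orientation == "auto":
        first_col = [str(v).lower().strip() for v in sheet.iloc[:, 0]]
        transposed = any(v in _RESERVED_ID + _RESERVED_TYPE for v in first_col)
        orientation = "fields_rows" if transposed else "samples_rows"
    if orientation == "fields_rows":
        sheet = sheet.set_index(sheet.columns[0]).T.reset_index(drop=True)
        sheet.columns = [str(c).strip() for c in sheet.columns]

    id_col = _find_column(sheet.columns, _RESERVED_ID) or sheet.columns[0]
    type_col = _find_column(sheet.columns, _RESERVED_TYPE)
    if type_col is None:
        raise MetadataError(
            "metadata sheet is missing a sample-type field "
            f"(expected one of {list(_RESERVED_TYPE)})")
    rep_col = _find_column(sheet.columns, _RESERVED_REPLICATE)

    reserved = {id_col, type_col} | ({rep_col} if rep_col else set())
    other = [c for c in sheet.columns if c not in reserved]
    if group_columns is None:
        group_cols, extra_cols = other, []
    else:
        missing = [c for c in group_columns if c not in sheet.columns]
        if missing:
            raise MetadataError(f"declared group columns not in sheet: {missing}")
        group_cols = list(group_columns)
        extra_cols = [c for c in other if c not in group_cols]

    annotations: list[SampleAnnotation] = []
    seen_ids: set[str] = set()
    for _, row in sheet.iterrows():
        sid = str(row[id_col]).strip()
        if not sid:
            raise MetadataError("empty sample id in metadata sheet")
        if sid in seen_ids:
            raise MetadataError(f"duplicate sample id {sid!r}")
        seen_ids.add(sid)
        stype_raw = str(row[type_col]).strip().lower()
        stype = _TYPE_ALIASES.get(stype_raw)
        if stype is None:
            raise MetadataError(
                f"unknown sample type {stype_raw!r} for sample {sid!r}")
        gvars = {c: str(row[c]).strip() for c in group_cols}
        if stype != "biological":
            gvars = {}  # blanks/QCs do not belong to experimental groups
        rep = None
        if rep_col is not None:
            rep_val = str(row[rep_col]).strip()
            rep = rep_val or None
        extras = {c: str(row[c]).strip() for c in extra_cols}
        annotations.append(SampleAnnotation(sid, stype, gvars, rep, extras))
    return annotations


@dataclass
class ValidationReport:
    """Mechanical consistency checks between matrix and metadata."""

    hard_failures: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    samples_missing_in_metadata: list[str] = field(default_factory=list)
    samples_missing_in_matrix: list[str] = field(default_factory=list)
    unparseable_species: list[str] = field(default_factory=list)
    n_negative_values: int = 0
    n_blanks: int = 0
    group_counts: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.hard_failures


def validate_dataset(matrix: pd.DataFrame,
                     annotations: Sequence[SampleAnnotation]) -> ValidationReport:
    """Cross-check a concentration matrix against sample annotations."""
    report = ValidationReport()
    meta_ids = [a.sample_id for a in annotations]

    report.samples_missing_in_metadata = [
        c for c in matrix.columns if c not in set(meta_ids)]
    report.samples_missing_in_matrix = [
        s for s in meta_ids if s not in set(matrix.columns)]
    for s in report.samples_missing_in_metadata:
        report.hard_failures.append(f"sample {s!r} in matrix but not in metadata")
    for s in report.samples_missing_in_matrix:
        report.hard_failures.append(f"sample {s!r} in metadata but not in matrix")

    for name in matrix.index:
        try:
            parse_species(name)
        except ParseError as exc:
            report.unparseable_species.append(name)
            report.hard_failures.append(f"species {name!r} failed parsing: {exc}")

    with np.errstate(invalid="ignore"):
        report.n_negative_values = int((matrix.to_numpy() < 0).sum())
    if report.n_negative_values:
        report.hard_failures.append(
            f"{report.n_negative_values} negative concentration value(s)")

    report.n_blanks = sum(1 for a in annotations if a.sample_type == "blank")
    if report.n_blanks == 0:
        report.warnings.append("no blank samples: blank filtering unavailable")

    for a in annotations:
        if a.sample_type == "biological":
            report.group_counts[a.group_label] = (
                report.group_counts.get(a.group_label, 0) + 1)
    if not report.group_counts:
        report.warnings.append("no biological samples")
    return report


def _species_sort_key(name: str):
    p = parse_species(name)
    tc, td = sum_composition(p)
    return (p.lipid_class.code, tc, td, name)


def build_dataset(matrix: pd.DataFrame,
                  annotations: Sequence[SampleAnnotation],
                  unit: str = "uM") -> LipidomicsDataset:
    """Validate and assemble a canonical :class:`LipidomicsDataset`.

    Species are sorted by (class, sum composition) and samples by id, so
    assembly is independent of input row/column order.

    Raises
    ------
    ValidationError
        If :func:`validate_dataset` reports any hard failure.
    """
    report = validate_dataset(matrix, annotations)
    if not report.ok:
        raise ValidationError(report)

    species_order = sorted(matrix.index, key=_species_sort_key)
    by_id = {a.sample_id: a for a in annotations}
    sample_order = sorted(matrix.columns)
    ordered_annotations = [by_id[s] for s in sample_order]
    conc = matrix.loc[species_order, sample_order].astype(float)
    conc.index = pd.Index(species_order, name="species")
    conc.columns = pd.Index(sample_order, name="sample")
    parsed = {name: parse_species(name) for name in species_order}
    return LipidomicsDataset(conc, parsed, ordered_annotations, unit=unit)


def to_tidy(dataset: LipidomicsDataset) -> pd.DataFrame:
    """Long-format export: one (species, sample, concentration) row per value."""
    long = (dataset.concentrations
            .rename_axis(index="species", columns="sample")
            .stack(future_stack=True)
            .rename("concentration")
            .reset_index())
    return long.dropna(subset=["concentration"]).reset_index(drop=True)


def write_dataset(dataset: LipidomicsDataset, directory: str | Path,
                  manifest_extra: Mapping | None = None) -> dict:
    """Write a canonical dataset bundle (matrix + annotations + manifest).

    The matrix CSV uses a fixed column order and fixed float formatting so
    that write -> read -> write is bit-stable.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    matrix_path = directory / "concentrations.csv"
    dataset.concentrations.to_csv(matrix_path, float_format=_FLOAT_FORMAT)
    dataset.sample_table().to_csv(directory / "samples.csv", index=False)

    species_rows = []
    for name, p in dataset.species_annotations.items():
        tc, td = sum_composition(p)
        species_rows.append({"species": name, "class": p.lipid_class.code,
                             "total_carbons": tc, "total_double_bonds": td,
                             "canonical": p.canonical})
    pd.DataFrame(species_rows).to_csv(directory / "species.csv", index=False)

    manifest = {
        "format_version": "1.0",
        "unit": dataset.unit,
        "n_species": int(dataset.concentrations.shape[0]),
        "n_samples": int(dataset.concentrations.shape[1]),
        "matrix_sha256": hashlib.sha256(matrix_path.read_bytes()).hexdigest(),
    }
    if manifest_extra:
        manifest.update(dict(manifest_extra))
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def read_dataset(directory: str | Path) -> LipidomicsDataset:
    """Read a dataset bundle written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    matrix = read_concentration_table(directory / "concentrations.csv")
    annotations = read_metadata(directory / "samples.csv")
    return build_dataset(matrix, annotations, unit=manifest.get("unit", "uM"))


def group_label_from(values: Mapping[str, str]) -> str:
    """Concatenate grouping-variable values into one group label."""
    if not values:
        return "all"
    return GROUP_SEPARATOR.join(str(v) for v in values.values())
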