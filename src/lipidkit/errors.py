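"""Exception hierarchy shared across lipidkit modules."""

from __future__ import annotations


class LipidkitError(Exception):
    """Base class for all lipidkit errors."""


class ParseError(LipidkitError):
    """A species name or table cell could not be parsed.

    Parameters
    ----------
    message
        Human-readable description.
    position
        Character offset in the offending string, if known.
    coordinates
        ``(row, column)`` labels for table cells, if applicable.
    """

    def __init__(self, message: str, position: int | None = None,
                 coordinates: tuple | None = None):
        self.position = position
        self.coordinates = coordinates
        if position is not None:
            message = f"{message} (at position {position})"
        if coordinates is not None:
            message = f"{message} (at row={coordinates[0]!r}, column={coordinates[1]!r})"
        super().__init__(message)


class UnknownClassError(ParseError):
    """Class token not present in the registry (after synonym mapping)."""

    def __init__(self, token: str, position: int | None = None):
        self.token = token
        super().__init__(f"unknown lipid class token {token!r}", position=position)


class DuplicateSpeciesError(LipidkitError):
    """Two or more input rows collapse to the same canonical species name."""

    def __init__(self, collisions: dict):
        self.collisions = dict(collisions)
        detail = "; ".join(
            f"{canon!r} <- {sorted(raw)}" for canon, raw in self.collisions.items()
        )
        super().__init__(f"duplicate species after canonicalization: {detail}")


class MetadataError(LipidkitError):
    """Malformed or incomplete sample metadata sheet."""


class ValidationError(LipidkitError):
    """Dataset assembly refused because of hard validation failures."""

    def __init__(self, report):
        self.report = report
        super().__init__(
            "dataset validation failed: " + "; ".join(report.hard_failures)
        )


class NoBlankError(LipidkitError):
    """Blank filtering requested but the dataset contains no blank samples."""


class EmptyDesignError(LipidkitError):
    """No biological samples available for filtering or testing."""


class AnnotationError(LipidkitError):
    """A species in the matrix lacks a parsed annotation."""


class ZeroTotalError(LipidkitError):
    """A sample has zero total lipid, so percent-of-total is undefined."""

    def __init__(self, samples):
        self.samples = list(samples)
        super().__init__(f"total lipid is zero for sample(s): {self.samples}")


class EmptyPoolError(LipidkitError):
    """No species left in the requested class pool after filtering."""


class InsufficientReplicatesError(LipidkitError):
    """Fewer than the minimum usable values per group for a statistical test."""


class InsufficientSamplesError(LipidkitError):
    """Too few samples for the requested multivariate analysis."""


class DomainError(LipidkitError):
    """Numeric input outside its mathematical domain (e.g. p-values)."""


class DesignError(LipidkitError):
    """Invalid simulation or comparison design."""
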