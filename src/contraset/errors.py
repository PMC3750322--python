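"""Exception hierarchy.

Parse-time errors carry the 1-based line number of the offending line in
``.line`` and include it in the message, so a user can locate the problem
in the original file.
"""

from __future__ import annotations


class ContrasetError(Exception):
    """Base class for all errors raised by this package."""


# --- idMAPS / ID-list parsing -------------------------------------------------

class IdMapsParseError(ContrasetError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class MalformedHeaderError(IdMapsParseError):
    pass


class DuplicateContrastNameError(IdMapsParseError):
    pass


class MissingMError(IdMapsParseError):
    pass


class InconsistentGroupOrderError(IdMapsParseError):
    pass


class RowLengthMismatchError(IdMapsParseError):
    pass


class BadPValueError(IdMapsParseError):
    pass


class BadValueError(IdMapsParseError):
    pass


class MissingHeaderKeyError(IdMapsParseError):
    pass


class EmptyListError(IdMapsParseError):
    pass


class InvalidDatasetError(ContrasetError):
    """A ContrastDataset violates its invariants (e.g. on write)."""


# --- ID mapping / collapsing --------------------------------------------------

class UnknownIdTypeError(ContrasetError):
    pass


class EmptyRecordListError(ContrasetError):
    pass


class StrategyRequiresColumnError(ContrasetError):
    pass


class EmptyAfterMappingError(ContrasetError):
    pass


class MappingTableError(ContrasetError):
    """Malformed mapping-table file (bad status vocabulary, missing version...)."""


# --- gene-set extraction ------------------------------------------------------

class UnknownContrastError(ContrasetError):
    pass


class NoStatisticColumnError(ContrasetError):
    pass


# --- store --------------------------------------------------------------------

class DuplicateDatasetNameError(ContrasetError):
    pass


class DuplicateGeneSetNameError(ContrasetError):
    pass


class EmptySelectionError(ContrasetError):
    pass


class MissingSourceDataError(ContrasetError):
    pass


# --- enrichment ---------------------------------------------------------------

class MissingColumnError(ContrasetError):
    pass


class EmptyDegListError(ContrasetError):
    pass


class EmptyIntersectionError(ContrasetError):
    pass


class SetEqualsUniverseError(ContrasetError):
    pass


class NoSetsPassSizeFilterError(ContrasetError):
    pass


class EmptyUniverseError(ContrasetError):
    pass


class ValueOutOfRangeError(ContrasetError):
    pass


# --- results post-processing --------------------------------------------------

class NoResultsError(ContrasetError):
    pass


class UnknownColumnError(ContrasetError):
    pass


class NoSetPassesThresholdError(ContrasetError):
    pass
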