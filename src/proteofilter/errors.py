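"""Exception hierarchy shared across the package.

Each family maps to a distinct CLI exit code (see :mod:`proteofilter.cli`),
and every message is expected to name the offending artifact — file, sheet,
section, column, or query position.
"""

from __future__ import annotations


class ProteoFilterError(Exception):
    """Base class for all errors raised by this package."""


class InputError(ProteoFilterError):
    """An input file is missing or unreadable."""


class SelectorError(ProteoFilterError):
    """A requested sheet or mzTab section does not exist in the source."""


class SchemaError(ProteoFilterError):
    """The table structure is invalid (duplicate headers, ragged rows, no header)."""


class FormatError(ProteoFilterError):
    """A file violates its format's line-level rules."""


class OutputError(ProteoFilterError):
    """The output file cannot be written."""


class QueryParseError(ProteoFilterError):
    """The query string is not grammatical.

    Carries the zero-based character position where parsing failed.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class ValidationError(ProteoFilterError):
    """A parsed query cannot run against the given table schema."""


class EvaluationError(ProteoFilterError):
    """A statement hit an ill-typed comparison at evaluation time."""


class ConfigurationError(ProteoFilterError):
    """A run is missing a required ingredient (annotations, species, id column)."""
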