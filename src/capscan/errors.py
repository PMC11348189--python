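"""Exception hierarchy.

Exit-code mapping used by the CLI: validation errors -> 2, data errors -> 3,
anything else -> 4.
"""


class CapscanError(Exception):
    """Base class for all package errors."""


class ValidationError(CapscanError):
    """Invalid user input: bad config values, malformed specs, bad arguments."""


class DataError(CapscanError):
    """Problems with the data itself (files, selections, degenerate geometry)."""


class ParseError(DataError):
    """A coordinate or profile file could not be parsed."""


class FormatError(DataError):
    """Unknown or unsupported file format."""


class MappingError(DataError):
    """Chain could not be mapped onto the reference sequence."""


class SelectionError(DataError):
    """An atom/residue selector resolved to zero or multiple atoms."""


class DegeneracyError(DataError):
    """Geometric operation on rank-deficient or too-small input."""


class GenerationError(CapscanError):
    """Synthetic-data generation failed (e.g. self-avoidance unsatisfiable)."""
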