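"""Exception hierarchy.

Each class maps to a distinct CLI exit code (see :mod:`sinephylo.cli`).
"""


class SinephyloError(Exception):
    """Base class for package errors."""

    exit_code = 1


class InputError(SinephyloError):
    """Invalid user-supplied data (bad taxa, malformed records, ...)."""

    exit_code = 2


class MatrixFormatError(InputError):
    """Malformed character-matrix file."""

    exit_code = 2


class SearchError(SinephyloError):
    """Tree search cannot proceed (too few taxa, no signal)."""

    exit_code = 3


class ConfigurationError(SinephyloError):
    """Inconsistent configuration (thresholds, window sizes, ...)."""

    exit_code = 4


class NoCallError(SinephyloError):
    """A confounding-event classification could not be made."""

    exit_code = 5
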