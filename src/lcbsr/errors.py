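"""Exception hierarchy.

Each top-level error class maps to a distinct CLI exit code so shell
pipelines can distinguish bad files from bad configuration from bad data.
"""


class LcbsrError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputOutputError(LcbsrError):
    """Unreadable or unwritable file."""

    exit_code = 10


class ConfigurationError(LcbsrError):
    """Invalid parameter, missing radius, inconsistent options."""

    exit_code = 11


class DataError(LcbsrError):
    """Structurally invalid input data."""

    exit_code = 12


class EmptyStructureError(DataError):
    """A structure file yielded no atoms."""


class MissingEnergyError(DataError):
    """A docked pose has no binding energy attached."""


class FormatError(DataError):
    """Malformed record or inconsistent pose atom counts."""


class FixtureError(LcbsrError):
    """A synthetic-fixture prescription is unrealizable."""

    exit_code = 13
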