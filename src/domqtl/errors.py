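"""Exception hierarchy.

``ConfigError`` and ``DataError`` map to CLI exit codes 2 and 3; everything
else is an ordinary ``DomqtlError`` (exit code 1 from the CLI).
"""


class DomqtlError(Exception):
    """Base class for all package errors."""


class ConfigError(DomqtlError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(DomqtlError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


class DegenerateTraitError(DataError):
    """A trait with no usable variation (all values equal, or too few)."""


class UnsupportedLipidClassError(DomqtlError):
    """Lipid-class bookkeeping requested for a class the package does not model."""
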