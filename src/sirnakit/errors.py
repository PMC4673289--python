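"""Exception hierarchy.

Validation failures (bad sequences, malformed annotation files, missing
reference genes) raise :class:`ValidationError`; the CLI maps these to exit
code 2 so scripted callers can tell bad input from internal failures.
"""


class SirnakitError(Exception):
    """Base class for all package errors."""


class ValidationError(SirnakitError, ValueError):
    """Invalid input data or parameters."""


class LoadError(ValidationError):
    """A file could not be parsed into a valid object; names the record."""
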