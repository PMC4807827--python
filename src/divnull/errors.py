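"""Exception hierarchy.

``InputError`` covers anything a user can fix in their input files or
configuration; ``InternalError`` flags conditions that indicate a bug in the
pipeline itself. The CLI maps these to exit codes 1 and 2 respectively.
"""


class DivnullError(Exception):
    """Base class for all package errors."""


class InputError(DivnullError):
    """Invalid or inconsistent user input (files, tables, configuration)."""


class ValidationError(InputError):
    """A domain object violated one of its invariants."""


class InternalError(DivnullError):
    """An internal consistency check failed; indicates a bug."""
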