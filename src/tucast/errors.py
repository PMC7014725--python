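"""Exception hierarchy.

The CLI maps :class:`InputError` to exit code 2 and
:class:`InvariantError` to exit code 3.
"""


class TucastError(Exception):
    """Base class for all package errors."""


class InputError(TucastError):
    """Malformed or inconsistent user input (files, tables, parameters)."""


class ConfigError(InputError):
    """Invalid simulation or pipeline configuration."""


class InvariantError(TucastError):
    """An internal invariant was violated (e.g. a stage produced a non-partition)."""
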