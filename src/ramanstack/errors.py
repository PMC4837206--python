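"""Exception hierarchy shared across the pipeline.

``ConfigError`` marks invalid user input (configuration, preconditions);
``DataError`` marks problems with the data itself (missing files, corrupt
cubes, degenerate spectra).  The CLI maps them to distinct exit codes.
"""


class RamanStackError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RamanStackError):
    """Invalid configuration or violated precondition."""


class DataError(RamanStackError):
    """Malformed, missing, or degenerate data."""
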