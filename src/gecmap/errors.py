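"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI: InputError -> 2, ParameterError -> 3.
"""


class GecmapError(Exception):
    """Base class for all package errors."""


class InputError(GecmapError):
    """Malformed, inconsistent or missing input data."""

    exit_code = 2


class ParameterError(GecmapError):
    """A parameter or configuration value outside its documented range."""

    exit_code = 3


class ConfigurationError(ParameterError):
    """An invalid simulation/pipeline configuration field (named in the message)."""
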