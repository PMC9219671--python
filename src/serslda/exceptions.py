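"""Exception types shared across the package."""


class SersldaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SersldaError, ValueError):
    """A parameter or profile is invalid before any computation runs."""


class DegenerateInputError(SersldaError, ValueError):
    """Input is structurally valid but degenerate for the requested operation
    (constant spectrum, single-member group, empty selection, ...)."""
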