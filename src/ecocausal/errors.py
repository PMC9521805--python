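"""Exception hierarchy shared across the package."""


class EcoCausalError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EcoCausalError, ValueError):
    """A user-supplied option, mapping or parameter is invalid."""


class DataError(EcoCausalError, ValueError):
    """Input data violate a structural requirement (too few rows, empty network, ...)."""


class DegenerateInputError(EcoCausalError, ValueError):
    """A numeric input is degenerate for the requested operation (constant vector, all ties, ...)."""
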