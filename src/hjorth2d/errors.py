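"""Exception hierarchy shared across the package."""


class Hjorth2DError(Exception):
    """Base class for all package errors."""


class InputError(Hjorth2DError):
    """Unreadable file, malformed table, or invalid sample layout."""


class DimensionError(Hjorth2DError):
    """Image or plane shapes violate a size/shape precondition."""


class DegenerateInputError(Hjorth2DError):
    """Mathematically undefined case (constant image, zero variance, ...)."""


class ConfigurationError(Hjorth2DError):
    """Invalid parameter combination in a spec or config object."""
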