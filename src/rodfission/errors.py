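"""Exception types shared across the package."""


class RodfissionError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RodfissionError):
    """Invalid configuration (unknown model/distribution name, missing seed...)."""


class ValidationError(RodfissionError):
    """Input values violate a documented precondition."""


class FormatError(RodfissionError):
    """Malformed input data (ragged alignment, non-2-D image, unknown query...)."""


class PlacementError(RodfissionError):
    """Cells could not be placed without overlap within the attempt budget."""
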