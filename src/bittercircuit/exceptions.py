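"""Exception hierarchy shared across the pipeline stages."""


class BitterCircuitError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(BitterCircuitError, ValueError):
    """A parameter violates its documented constraints."""


class ProtocolError(BitterCircuitError, ValueError):
    """A stimulus protocol is malformed or incompatible with the request."""


class WindowError(BitterCircuitError, ValueError):
    """An analysis window does not fit inside the available data."""


class EmptyInputError(BitterCircuitError, ValueError):
    """An operation received an empty data structure it cannot act on."""


class QualityError(BitterCircuitError, ValueError):
    """Too much missing data inside an analysis window."""


class InvalidTraceError(BitterCircuitError, ValueError):
    """A fluorescence trace violates baseline requirements."""


class FormatError(BitterCircuitError, ValueError):
    """An input table cannot be parsed under the declared dialect."""


class LabelingError(BitterCircuitError, ValueError):
    """A graph cell is missing a required label or annotation."""


class ConfigError(BitterCircuitError, ValueError):
    """A run configuration is invalid; message lists the offending keys."""
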