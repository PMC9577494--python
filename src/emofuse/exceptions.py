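"""Exception types shared across the package."""


class EmofuseError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EmofuseError, ValueError):
    """A parameter is outside its valid range or the combination is infeasible."""


class InsufficientDataError(EmofuseError, ValueError):
    """Not enough data survives preprocessing to compute the requested quantity."""


class ShapeError(EmofuseError, ValueError):
    """Array shapes are inconsistent with the requested operation."""


class DegenerateDataError(EmofuseError, ValueError):
    """The data has a degenerate structure (e.g. a single class) that blocks the protocol."""
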