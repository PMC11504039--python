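"""Exception hierarchy shared across valvekit."""


class ValvekitError(Exception):
    """Base class for all package errors."""


class ParameterError(ValvekitError, ValueError):
    """A generator or operation parameter is invalid; message names the field."""


class DataError(ValvekitError, ValueError):
    """Input data violate a structural precondition (lengths, cycles, masks...)."""


class DomainError(ValvekitError, ValueError):
    """A numeric argument is outside the mathematical domain of the operation."""


class EstimationError(ValvekitError, RuntimeError):
    """A fit or estimate could not be produced from the data."""


class SegmentationError(ValvekitError, RuntimeError):
    """Image segmentation produced no usable foreground."""


class CalibrationError(ValvekitError, RuntimeError):
    """Pixel-size calibration failed (e.g. no holder rim detected)."""
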