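"""Exception types shared across lamellometer modules."""


class LamellometerError(Exception):
    """Base class for all lamellometer errors."""


class InvalidApertureError(LamellometerError, ValueError):
    """Numerical aperture incompatible with the immersion-side index."""


class NoWedgeError(LamellometerError, ValueError):
    """No foil-side intensity peak detected above background."""


class AmbiguousOffsetError(LamellometerError, ValueError):
    """Reflectivity trace covers less than one interference period."""


class TableQualityError(LamellometerError, ValueError):
    """Monte-Carlo lookup table is not strictly monotone in thickness."""


class OutOfRangeError(LamellometerError, ValueError):
    """Measured quantity lies outside the calibrated lookup range."""


class FormatError(LamellometerError, ValueError):
    """Unreadable or inconsistent image stack / sidecar."""
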