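"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates an operation's precondition."""


class FormatError(ValueError):
    """A file on disk does not conform to the expected format."""


class OutOfRangeError(ValueError):
    """A requested wavelength or index falls outside the valid range."""


class DegenerateInputError(ValueError):
    """The input carries no usable signal for the requested operation."""


class PlacementError(RuntimeError):
    """Synthetic sample disks could not be placed without overlap."""
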