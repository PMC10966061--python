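"""Exception hierarchy shared across the pipeline."""


class RonistegError(Exception):
    """Base class for all package errors."""


class UnsupportedFormatError(RonistegError):
    """Input file is not a monochrome single-frame DICOM or grayscale PNG."""


class RangeError(RonistegError, ValueError):
    """Pixel values violate the declared bit depth."""


class DegenerateRangeError(RonistegError, ValueError):
    """Constant image: min-max normalization is undefined."""


class AlignmentError(RonistegError, ValueError):
    """Shapes or bit depths of two operands do not match."""


class ParameterError(RonistegError, ValueError):
    """A tuning parameter is outside its valid domain."""


class CapacityError(RonistegError):
    """Message needs more 4x4 tiles than the insignificant region provides."""

    def __init__(self, required: int, available: int):
        self.required = required
        self.available = available
        super().__init__(
            f"payload needs {required} embeddable 4x4 tiles, "
            f"but the insignificant region provides only {available}"
        )


class TruncationError(RonistegError):
    """Stego image offers fewer tiles than the recorded message requires."""


class QRCapacityError(RonistegError, ValueError):
    """Payload text does not fit any supported QR version."""


class QRDecodeError(RonistegError):
    """Bitmap is not a decodable QR symbol (corrupted extraction)."""


class VerificationWarning(UserWarning):
    """Post-embed self-check recovered bits differing from the embedded ones."""
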