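"""Exception types shared across the package."""


class IrfpQuantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IrfpQuantError, ValueError):
    """Input file is not a supported single-channel grayscale TIFF."""


class IntegrityError(IrfpQuantError, ValueError):
    """Pixel data violates the declared bit-depth or sign constraints."""


class BoundsError(IrfpQuantError, IndexError):
    """A crop box or index falls outside the image."""


class ShapeError(IrfpQuantError, ValueError):
    """Array shapes are incompatible (binning factor, mask congruence)."""


class DegenerateInputError(IrfpQuantError, ValueError):
    """Input carries no usable information (all-zero image, constant
    surface, empty region, single-pixel background)."""


class DomainError(IrfpQuantError, ValueError):
    """A numeric argument is outside its meaningful domain."""
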