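"""Raw imaging TIFF input/output, cropping, detector binning and
saturation detection.

Small-animal fluorescence platforms export single-channel grayscale
TIFFs of integer photon-derived counts.  Detectors differ in bit depth:
16-bit for IVIS-class (XVI) and Bruker-class (BIX) instruments, 22-bit
for the Li-Cor Pearl class (LPT), whose data travel in a 32-bit
container with a *logical* ceiling of ``2**22 - 1``.  All validation in
this module uses the logical ceiling, never the container's.

Conventions
-----------
* Pixel coordinates are 0-based, half-open ``[start, stop)`` in
  ``(row, col)`` order.
* Binning is block **summation** (not averaging): a k x k bin multiplies
  per-pixel signal by k**2, e.g. 8 x 8 binning multiplies intensity by 64.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import BoundsError, FormatError, IntegrityError, ShapeError

__all__ = [
    "RawImage",
    "CropBox",
    "SaturationReport",
    "read_tiff",
    "write_tiff",
    "crop",
    "bin_image",
    "detect_saturation",
    "read_manifest",
]

#: Bit depths of the supported detector classes.
SUPPORTED_BIT_DEPTHS = (16, 22)

#: Manifest columns required by :func:`read_manifest`.
MANIFEST_COLUMNS = ("path", "mouse_id", "day", "platform", "units", "bit_depth")


@dataclass(frozen=True)
class RawImage:
    """A single-channel raw-count image with platform metadata.

    Parameters
    ----------
    pixels
        2-D array of non-negative integer counts.
    bit_depth
        Logical detector bit depth, 16 or 22.
    platform
        Free-text instrument tag, e.g. ``"XVI"``, ``"BIX"``, ``"LPT"``.
    units
        Free-text intensity-unit tag, e.g. ``"radiant efficiency"``,
        ``"counts"``, ``"signal"``.
    overflowed
        True when the values are allowed to exceed the logical bit-depth
        ceiling (set only by :func:`bin_image` when summation overflows
        and clipping was not requested).
    """

    pixels: np.ndarray
    bit_depth: int = 16
    platform: str = ""
    units: str = ""
    overflowed: bool = False

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        if pixels.ndim != 2:
            raise FormatError(
                f"expected a 2-D single-channel image, got ndim={pixels.ndim}"
            )
        if pixels.shape[0] < 1 or pixels.shape[1] < 1:
            raise FormatError(f"image must be at least 1x1, got {pixels.shape}")
        if not np.issubdtype(pixels.dtype, np.integer):
            raise FormatError(
                f"raw counts must be integers, got dtype {pixels.dtype}"
            )
        if self.bit_depth not in SUPPORTED_BIT_DEPTHS:
            raise IntegrityError(
                f"bit_depth must be one of {SUPPORTED_BIT_DEPTHS}, "
                f"got {self.bit_depth}"
            )
        if pixels.min() < 0:
            raise IntegrityError("raw counts must be non-negative")
        if not self.overflowed and pixels.max() > self.ceiling:
            raise IntegrityError(
                f"pixel value {pixels.max()} exceeds the {self.bit_depth}-bit "
                f"ceiling {self.ceiling}"
            )
        object.__setattr__(self, "pixels", pixels)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def ceiling(self) -> int:
        """Largest representable count, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    def with_pixels(self, pixels: np.ndarray, **overrides) -> "RawImage":
        """Copy metadata onto a new pixel grid."""
        kwargs = dict(
            bit_depth=self.bit_depth,
            platform=self.platform,
            units=self.units,
            overflowed=self.overflowed,
        )
        kwargs.update(overrides)
        return RawImage(pixels, **kwargs)


@dataclass(frozen=True)
class CropBox:
    """0-based, half-open rectangular region ``[row_start, row_stop) x
    [col_start, col_stop)``."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        for start, stop, axis in (
            (self.row_start, self.row_stop, "row"),
            (self.col_start, self.col_stop, "col"),
        ):
            if start < 0 or start >= stop:
                raise BoundsError(
                    f"{axis} range [{start}, {stop}) is empty or negative"
                )

    def compose(self, inner: "CropBox") -> "CropBox":
        """Box equivalent to cropping with ``self`` then ``inner``."""
        return CropBox(
            self.row_start + inner.row_start,
            self.row_start + inner.row_stop,
            self.col_start + inner.col_start,
            self.col_start + inner.col_stop,
        )


@dataclass(frozen=True)
class SaturationReport:
    """Pixels pinned at the detector ceiling."""

    count: int
    mask: np.ndarray = field(repr=False)


def _container_dtype(bit_depth: int) -> np.dtype:
    return np.dtype(np.uint16) if bit_depth <= 16 else np.dtype(np.uint32)


def read_tiff(
    path: str | Path,
    bit_depth: int = 16,
    platform: str = "",
    units: str = "",
) -> RawImage:
    """Read a single-channel grayscale TIFF into a :class:`RawImage`.

    The stored sample values are taken verbatim; any value above the
    logical ``2**bit_depth - 1`` ceiling is rejected as corrupt, since a
    detector cannot produce counts beyond its own range.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected single-channel grayscale TIFF, "
            f"got array of shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: expected integer samples, got {arr.dtype}")
    ceiling = (1 << bit_depth) - 1
    if arr.max(initial=0) > ceiling:
        raise IntegrityError(
            f"{path}: value {arr.max()} exceeds declared {bit_depth}-bit "
            f"ceiling {ceiling}"
        )
    return RawImage(
        arr.astype(_container_dtype(bit_depth)),
        bit_depth=bit_depth,
        platform=platform,
        units=units,
    )


def write_tiff(image: RawImage, path: str | Path) -> None:
    """Write a :class:`RawImage` losslessly.

    16-bit data is stored as uint16; 22-bit data (and overflowed sums)
    in a uint32 container so that no value is truncated.
    """
    pixels = image.pixels
    if image.overflowed or image.bit_depth > 16:
        out = pixels.astype(np.uint32)
    else:
        out = pixels.astype(np.uint16)
    tifffile.imwrite(str(path), out, photometric="minisblack")


def crop(image: RawImage, box: CropBox) -> RawImage:
    """Extract a rectangular region; values and metadata are preserved."""
    if box.row_stop > image.height or box.col_stop > image.width:
        raise BoundsError(
            f"crop box {box} exceeds image bounds "
            f"({image.height}, {image.width})"
        )
    sub = image.pixels[
        box.row_start : box.row_stop, box.col_start : box.col_stop
    ].copy()
    return image.with_pixels(sub)


def bin_image(image: RawImage, k: int, clip: bool = False) -> RawImage:
    """Sum k x k pixel blocks into single pixels.

    Summation conserves total intensity and multiplies per-pixel signal
    by ``k**2`` on a uniform field.  ``k`` must divide both dimensions
    exactly (no padding, so sums stay exact).  If block sums exceed the
    bit-depth ceiling, ``clip=True`` pins them at the ceiling (emulating
    detector clipping); otherwise the image keeps the wider values and
    is flagged ``overflowed``.
    """
    if k < 1:
        raise ShapeError(f"binning factor must be >= 1, got {k}")
    if k == 1:
        return image.with_pixels(image.pixels.copy())
    h, w = image.pixels.shape
    if h % k or w % k:
        raise ShapeError(
            f"binning factor {k} does not divide image dimensions ({h}, {w})"
        )
    summed = (
        image.pixels.astype(np.uint64)
        .reshape(h // k, k, w // k, k)
        .sum(axis=(1, 3))
    )
    overflow = bool(summed.max() > image.ceiling)
    if clip:
        summed = np.minimum(summed, image.ceiling)
        overflow = False
    dtype = _container_dtype(image.bit_depth) if not overflow else np.uint64
    return image.with_pixels(summed.astype(dtype), overflowed=overflow)


def detect_saturation(image: RawImage) -> SaturationReport:
    """Flag pixels pinned at the ``2**bit_depth - 1`` ceiling.

    Saturated (clipped) pixels under-report true intensity, so their
    count inside a tumour region is carried through to measurements as
    a quality flag.
    """
    mask = image.pixels == image.ceiling
    return SaturationReport(count=int(mask.sum()), mask=mask)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a CSV manifest of images to analyse.

    Required columns: ``path, mouse_id, day, platform, units, bit_depth``.
    Optional column ``crop`` in ``r0:r1:c0:c1`` half-open form.
    """
    df = pd.read_csv(path, dtype={"platform": str, "units": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path} missing columns: {missing}")
    return df


def parse_crop_spec(spec: str) -> CropBox:
    """Parse ``r0:r1:c0:c1`` (0-based, half-open) into a :class:`CropBox`."""
    parts = spec.split(":")
    if len(parts) != 4:
        raise FormatError(f"crop spec must be r0:r1:c0:c1, got {spec!r}")
    try:
        r0, r1, c0, c1 = (int(p) for p in parts)
    except ValueError as exc:
        raise FormatError(f"non-integer crop spec {spec!r}") from exc
    return CropBox(r0, r1, c0, c1)
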