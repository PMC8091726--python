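"""Raw-unit tumour intensity measurement, background estimation,
presence/absence detection calls and calliper volume.

The central convention: segmentation happens on the *normalized*
surface, but every measurement is taken from the raw, unscaled counts.
The plane's raw-unit height acts as the per-pixel background level and
is subtracted once (``net_total = total_raw - raw_level * area``); the
independently drawn elliptical background region is used for detection
calls and quality control, never for a second subtraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, DomainError, ShapeError
from .image_io import RawImage
from .segmentation import RegionMask, ThresholdPlane

__all__ = [
    "IntensityMeasurement",
    "BackgroundEstimate",
    "measure_region",
    "estimate_background",
    "detect_signal",
    "calliper_volume",
    "ellipse_region",
]


@dataclass(frozen=True)
class IntensityMeasurement:
    """Background-subtracted raw-unit totals for one region.

    ``net_total`` is the headline quantity: the summed raw counts inside
    the mask minus the plane background (``raw_level``) once per pixel.
    ``mean_net`` is the same quantity per pixel.  ``saturated_in_mask``
    counts ceiling-pinned pixels inside the mask, which under-report
    true intensity.
    """

    total_raw: float
    background_raw_level: float
    area_px: int
    net_total: float
    mean_net: float
    saturated_in_mask: int
    units: str = ""
    mouse_id: str = ""
    day: int | None = None


@dataclass(frozen=True)
class BackgroundEstimate:
    """Mean and sample (n-1) standard deviation of a background region,
    in raw units."""

    region: RegionMask = field(repr=False)
    mean: float
    sd: float


def measure_region(
    image: RawImage,
    mask: RegionMask,
    plane: ThresholdPlane,
    units: str | None = None,
    mouse_id: str = "",
    day: int | None = None,
) -> IntensityMeasurement:
    """Sum raw counts in the mask and subtract the plane background.

    The plane must come from this image's own normalization so that its
    ``raw_level`` is on the image's raw scale.
    """
    if mask.mask.shape != image.pixels.shape:
        raise ShapeError(
            f"mask shape {mask.mask.shape} does not match image shape "
            f"{image.pixels.shape}"
        )
    area = mask.n_pixels
    if area == 0:
        return IntensityMeasurement(
            total_raw=0.0,
            background_raw_level=plane.raw_level,
            area_px=0,
            net_total=0.0,
            mean_net=0.0,
            saturated_in_mask=0,
            units=units if units is not None else image.units,
            mouse_id=mouse_id,
            day=day,
        )
    region = image.pixels[mask.mask].astype(np.float64)
    total_raw = float(region.sum())
    net_total = total_raw - plane.raw_level * area
    saturated = int((image.pixels[mask.mask] == image.ceiling).sum())
    return IntensityMeasurement(
        total_raw=total_raw,
        background_raw_level=plane.raw_level,
        area_px=area,
        net_total=net_total,
        mean_net=net_total / area,
        saturated_in_mask=saturated,
        units=units if units is not None else image.units,
        mouse_id=mouse_id,
        day=day,
    )


def estimate_background(image: RawImage, region: RegionMask) -> BackgroundEstimate:
    """Mean and sample sd of raw counts inside a background region.

    The region is typically an ellipse over tumour-free tissue (e.g. the
    contralateral shoulder), similar in size to the tumour.  With a
    single pixel the sample sd is undefined and reported as NaN.
    """
    if region.n_pixels == 0:
        raise DegenerateInputError("background region is empty")
    if region.mask.shape != image.pixels.shape:
        raise ShapeError("background region does not match image shape")
    vals = image.pixels[region.mask].astype(np.float64)
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
    return BackgroundEstimate(region=region, mean=float(vals.mean()), sd=sd)


def detect_signal(
    image: RawImage,
    candidate: RegionMask,
    background: BackgroundEstimate,
    k: float = 3.0,
) -> bool:
    """Presence call: candidate mean above background mean + k * sd.

    Formalizes the visual "is there a tumour here today" judgement as a
    k-sigma rule on raw counts; ``k = 3`` by default.
    """
    if candidate.n_pixels == 0:
        raise DegenerateInputError("candidate region is empty")
    if not np.isfinite(background.sd):
        raise DegenerateInputError(
            "background sd undefined (single-pixel region)"
        )
    mean = float(image.pixels[candidate.mask].astype(np.float64).mean())
    return mean > background.mean + k * background.sd


def calliper_volume(length: float, width: float) -> float:
    """Tumour volume estimate (length x width^2) / 2 in mm^3.

    Standard ellipsoid approximation for external calliper measurement
    of palpable subcutaneous tumours; ``length`` is the longer axis.
    """
    if length < 0 or width < 0:
        raise DomainError("calliper dimensions must be non-negative")
    if width > length:
        warnings.warn(
            "width exceeds length; axes may be swapped", stacklevel=2
        )
    return length * width**2 / 2.0


def ellipse_region(
    shape: tuple[int, int],
    center_row: float,
    center_col: float,
    semi_row: float,
    semi_col: float,
) -> RegionMask:
    """Elliptical region mask, the digital analogue of the ellipse tool
    used to outline background areas."""
    if semi_row <= 0 or semi_col <= 0:
        raise DomainError("ellipse semi-axes must be positive")
    rows, cols = np.indices(shape)
    inside = ((rows - center_row) / semi_row) ** 2 + (
        (cols - center_col) / semi_col
    ) ** 2 <= 1.0
    return RegionMask.from_array(inside)
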