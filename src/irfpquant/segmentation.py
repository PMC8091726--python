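"""Intensity-surface normalization and plane-threshold segmentation.

The quantification model treats a cropped fluorescence image as a 3-D
surface: pixel position in x/y and normalized intensity in z.  A
horizontal plane cut through this surface separates tumour signal
(above the plane) from the mouse-body and bed background (below).  An
automatic initial plane level is computed by Kapur maximum-entropy
histogram thresholding — the level that maximizes the summed Shannon
entropies of the below- and above-plane intensity partitions — and may
then be overridden manually, mirroring how an operator would nudge the
plane while watching the 3-D rendering.

All segmentation happens in normalized units (the image maximum maps
to 1), which makes the mask invariant to any positive rescaling of the
raw counts; measurements are later taken from the *raw* image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DegenerateInputError, DomainError, ShapeError
from .image_io import RawImage

__all__ = [
    "NormalizedSurface",
    "ThresholdPlane",
    "RegionMask",
    "normalize",
    "entropy_threshold",
    "manual_plane",
    "plane_segment",
    "build_surface_export",
    "surface_from_export",
    "mask_to_rle",
    "rle_to_mask",
    "save_mask_png",
]

_FOUR_CONNECTED = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class NormalizedSurface:
    """Image rescaled so its maximum is exactly 1.

    ``raw_max`` is kept so plane levels can be converted back to raw
    detector units for background subtraction.
    """

    values: np.ndarray
    raw_max: float
    source: RawImage | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ShapeError(f"surface must be 2-D, got ndim={values.ndim}")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ThresholdPlane:
    """A horizontal cut through the normalized surface.

    ``level`` lives in normalized [0, 1] units; ``raw_level`` is the
    same height in raw detector units (``level * raw_max``) and doubles
    as the per-pixel background estimate subtracted during measurement.
    """

    level: float
    raw_level: float
    method: str = "auto_entropy"

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise DomainError(f"plane level must be in [0, 1], got {self.level}")


@dataclass(frozen=True)
class RegionMask:
    """Boolean signal mask plus its boundary pixels.

    Boundary pixels are mask pixels 4-adjacent to a background pixel or
    to the image edge, grouped per connected component and ordered
    lexicographically by (row, col).
    """

    mask: np.ndarray = field(repr=False)
    n_pixels: int
    boundary: tuple[np.ndarray, ...] = field(default=(), repr=False, compare=False)

    @classmethod
    def from_array(cls, mask: np.ndarray) -> "RegionMask":
        mask = np.asarray(mask, dtype=bool)
        return cls(mask=mask, n_pixels=int(mask.sum()),
                   boundary=_boundary_pixels(mask))


def _boundary_pixels(mask: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-component (row, col) arrays of 4-connectivity boundary pixels."""
    if not mask.any():
        return ()
    interior = ndimage.binary_erosion(
        mask, structure=_FOUR_CONNECTED, border_value=0
    )
    edge = mask & ~interior
    labels, n = ndimage.label(mask, structure=_FOUR_CONNECTED)
    groups = []
    for lab in range(1, n + 1):
        coords = np.argwhere(edge & (labels == lab))
        if len(coords):
            groups.append(coords[np.lexsort((coords[:, 1], coords[:, 0]))])
    return tuple(groups)


def normalize(image: RawImage) -> NormalizedSurface:
    """Map raw counts to [0, 1] by dividing by the image maximum.

    Raises :class:`DegenerateInputError` on an all-zero image, which
    carries no signal to scale.
    """
    raw_max = float(image.pixels.max())
    if raw_max <= 0:
        raise DegenerateInputError("all-zero image cannot be normalized")
    values = image.pixels.astype(np.float64) / raw_max
    return NormalizedSurface(values=values, raw_max=raw_max, source=image)


def _partition_entropy(counts: np.ndarray) -> float:
    """Shannon entropy of one histogram partition (zero bins skipped)."""
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def entropy_threshold(surface: NormalizedSurface, n_bins: int = 256) -> ThresholdPlane:
    """Kapur maximum-entropy initial plane level.

    Intensities are histogrammed into ``n_bins`` uniform bins over
    [0, 1].  For each of the ``n_bins - 1`` candidate cuts the Shannon
    entropies of the below-cut and above-cut partitions are summed; the
    cut maximizing the sum is returned, ties broken toward the lowest
    level (the most inclusive mask).  The returned level is the bin
    edge at the cut, so the mask criterion ``value > level`` assigns
    whole bins consistently.
    """
    if n_bins < 2:
        raise DomainError(f"need at least 2 bins, got {n_bins}")
    values = surface.values
    if float(values.min()) == float(values.max()):
        raise DegenerateInputError(
            "constant surface has no threshold separating signal from noise"
        )
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    best_level, best_score = 0.0, -np.inf
    for cut in range(1, n_bins):
        below, above = counts[:cut], counts[cut:]
        if below.sum() == 0 or above.sum() == 0:
            continue
        score = _partition_entropy(below) + _partition_entropy(above)
        if score > best_score + 1e-12:
            best_score = score
            best_level = float(edges[cut])
    if not np.isfinite(best_score):
        raise DegenerateInputError("all mass in a single histogram bin")
    return ThresholdPlane(
        level=best_level,
        raw_level=best_level * surface.raw_max,
        method="auto_entropy",
    )


def manual_plane(surface: NormalizedSurface, level: float) -> ThresholdPlane:
    """Operator-chosen plane level in normalized units."""
    if not 0.0 <= level <= 1.0:
        raise DomainError(f"manual level must be in [0, 1], got {level}")
    return ThresholdPlane(
        level=float(level),
        raw_level=float(level) * surface.raw_max,
        method="manual",
    )


def plane_segment(
    surface: NormalizedSurface,
    plane: ThresholdPlane,
    largest_component_only: bool = False,
) -> RegionMask:
    """Cut the surface with the plane: signal is strictly above it.

    Pixels with value ``> level`` form the tumour mask; pixels at or
    below the plane are background/noise.  The strict inequality means
    a plane at 1.0 yields an empty mask and a plane at 0.0 selects every
    positive pixel.  By default the mask keeps all components (the image
    is expected to be pre-cropped to a tumour neighbourhood); set
    ``largest_component_only`` to keep only the biggest 4-connected
    blob, which discards isolated noise pixels poking above the plane
    (4-connectivity is used throughout the package; it also keeps
    pixel-level noise from percolating into one giant component).
    """
    mask = surface.values > plane.level
    if largest_component_only and mask.any():
        labels, n = ndimage.label(mask, structure=_FOUR_CONNECTED)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return RegionMask.from_array(mask)


def build_surface_export(
    surface: NormalizedSurface, plane: ThresholdPlane | None = None
) -> dict:
    """Lossless grid/mesh export of the surface for 3-D rendering.

    Vertices are emitted with x = column, y = row, z = normalized
    value; plane metadata and a sub-pixel boundary polyline (contour of
    the plane cut) are included when a plane is given.  Rendering is
    left to plotting backends.
    """
    rows, cols = np.indices(surface.shape)
    export: dict = {
        "shape": list(surface.shape),
        "raw_max": surface.raw_max,
        "vertices": {
            "x": cols.ravel().tolist(),
            "y": rows.ravel().tolist(),
            "z": surface.values.ravel().tolist(),
        },
        "grid": surface.values.tolist(),
    }
    if plane is not None:
        export["plane"] = {
            "level": plane.level,
            "raw_level": plane.raw_level,
            "method": plane.method,
        }
        contours = measure.find_contours(surface.values, plane.level)
        export["boundary"] = [c.tolist() for c in contours]
    return export


def surface_from_export(export: dict) -> NormalizedSurface:
    """Rebuild a surface from :func:`build_surface_export` output."""
    return NormalizedSurface(
        values=np.asarray(export["grid"], dtype=np.float64),
        raw_max=float(export["raw_max"]),
    )


def write_surface_export(
    surface: NormalizedSurface,
    plane: ThresholdPlane | None,
    csv_path: str | Path,
    json_path: str | Path,
) -> None:
    """Write the surface grid as CSV and plane metadata as JSON."""
    np.savetxt(csv_path, surface.values, delimiter=",")
    meta = {"raw_max": surface.raw_max, "shape": list(surface.shape)}
    if plane is not None:
        meta["plane"] = {
            "level": plane.level,
            "raw_level": plane.raw_level,
            "method": plane.method,
        }
    Path(json_path).write_text(json.dumps(meta, indent=2))


def mask_to_rle(mask: np.ndarray) -> list[tuple[int, int, int]]:
    """Row-wise run-length encoding: (row, col_start, length) runs."""
    runs = []
    for r, row in enumerate(np.asarray(mask, dtype=bool)):
        padded = np.diff(np.concatenate(([0], row.astype(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        stops = np.flatnonzero(padded == -1)
        runs.extend((r, int(s), int(e - s)) for s, e in zip(starts, stops))
    return runs


def rle_to_mask(runs: list[tuple[int, int, int]], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for r, c, length in runs:
        mask[r, c : c + length] = True
    return mask


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write the mask as an 8-bit PNG (signal 255, background 0)."""
    import imageio.v3 as iio

    iio.imwrite(str(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))
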