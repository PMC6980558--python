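"""Striatal ROI delineation and shape/intensity features on the summed image.

The headline feature is circularity, 4*pi*S / L**2 for ROI area S and
perimeter L: 1 for a circle, lower for elongated regions.  A normal comma-
shaped striatum is elongated (low circularity); with putaminal loss the
uptake region shrinks toward the round caudate head (high circularity), so
circularity rises in Parkinson-like images.

Manual ROI tracing is replaced by a reproducible surrogate: per hemifield,
threshold at a fraction of the hemifield maximum and keep the largest
8-connected component.

Perimeter convention
--------------------
L is the length of the 0.5 iso-contour polygon (marching squares) after two
midpoint corner-cutting passes.  The raw staircase polygon overestimates
smooth perimeters by ~6%, which would bias circularity down ~12%; two
corner-cutting passes bring rasterized disks within 5% of circularity 1
while keeping circularity <= 1 on convex shapes.  The convention is frozen
because circularity is the headline feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .summed import SummedImage

logger = logging.getLogger(__name__)

__all__ = [
    "RoiMask",
    "ShapeFeatures",
    "IntensityFeatures",
    "SegmentationError",
    "segment_striatum",
    "compute_shape_features",
    "compute_intensity_features",
    "mask_perimeter",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


class SegmentationError(ValueError):
    """Raised when a hemifield has no suprathreshold uptake.

    This is the phantom analogue of a burst-striatum image (near-total
    bilateral uptake loss), which the analysis excludes by design.
    """


@dataclass(frozen=True)
class RoiMask:
    """A single-striatum 2D binary ROI congruent with the summed image."""

    mask: np.ndarray
    side: str
    pixel_mm: tuple[float, float] = (2.0, 2.0)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if not mask.any():
            raise ValueError("ROI mask is empty")
        _, n = ndimage.label(mask, structure=_STRUCT8)
        if n != 1:
            raise ValueError(f"ROI mask must be a single 8-connected component, got {n}")
        object.__setattr__(self, "mask", mask)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ShapeFeatures:
    """The six shape descriptors, in mm-based units.

    area (mm^2), perimeter (mm), equivalent_diameter (mm),
    major/minor_axis_length (mm, axes of the ellipse with the same
    normalized second central moments), circularity (dimensionless).
    """

    area: float
    equivalent_diameter: float
    major_axis_length: float
    minor_axis_length: float
    perimeter: float
    circularity: float

    def __post_init__(self) -> None:
        for name in ("area", "equivalent_diameter", "major_axis_length",
                     "minor_axis_length", "perimeter", "circularity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.major_axis_length < self.minor_axis_length:
            raise ValueError("major axis must be >= minor axis")


@dataclass(frozen=True)
class IntensityFeatures:
    """Max, min and mean pixel count over the ROI foreground."""

    max_count: float
    min_count: float
    mean_count: float

    def __post_init__(self) -> None:
        if not self.min_count <= self.mean_count <= self.max_count:
            raise ValueError("intensity features must satisfy min <= mean <= max")


def segment_striatum(
    image: SummedImage,
    threshold_fraction: float = 0.5,
    midline: int | None = None,
) -> tuple[RoiMask, RoiMask]:
    """Delineate the left and right striatal ROIs on a summed image.

    Per hemifield (split at the ``midline`` column of axis 0), pixels at or
    above a fractional level between the hemifield background and peak,

        level = bg + threshold_fraction * (peak - bg),

    are kept, the largest 8-connected component is selected, and interior
    holes are filled.  ``bg`` is the median of the strictly positive
    hemifield pixels, a robust estimate of the nonspecific (occipital-like)
    uptake level.  Anchoring the threshold to the background keeps the ROI
    striatal even when the striatum-to-background ratio is low — a plain
    fraction-of-maximum cut floods into the background once the peak falls
    below twice the background.  On a zero background the level reduces to
    a fraction-of-maximum threshold.

    Returns ``(left, right)`` masks on the full image grid.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    data = image.data
    if not data.any():
        raise SegmentationError("summed image is identically zero")
    mid = data.shape[0] // 2 if midline is None else int(midline)
    if not 0 < mid < data.shape[0]:
        raise ValueError(f"midline column {mid} outside the image")

    out = []
    for side, sl in (("left", slice(0, mid)), ("right", slice(mid, data.shape[0]))):
        hemi = data[sl]
        peak = hemi.max()
        if peak <= 0:
            raise SegmentationError(
                f"no positive uptake in the {side} hemifield "
                "(burst-striatum-like input)"
            )
        bg = float(np.median(hemi[hemi > 0]))
        level = bg + threshold_fraction * (peak - bg)
        fg = hemi >= level
        if not fg.any():
            raise SegmentationError(
                f"no suprathreshold uptake in the {side} hemifield "
                "(burst-striatum-like input)"
            )
        labels, n = ndimage.label(fg, structure=_STRUCT8)
        largest = int(np.argmax(ndimage.sum_labels(fg, labels, range(1, n + 1)))) + 1
        comp = labels == largest
        filled = ndimage.binary_fill_holes(comp)
        if filled.sum() != comp.sum():
            logger.info("filled %d interior hole pixel(s) in the %s ROI",
                        int(filled.sum() - comp.sum()), side)
        full = np.zeros_like(data, dtype=bool)
        full[sl] = filled
        out.append(RoiMask(mask=full, side=side, pixel_mm=image.voxel_mm))
    return out[0], out[1]


def mask_perimeter(mask: np.ndarray) -> float:
    """Perimeter of a binary mask in pixels under the frozen convention.

    0.5-level marching-squares contour of the zero-padded mask, two
    midpoint corner-cutting passes, then the closed polygon length.  The
    mask must contain a single filled component; the longest contour is
    taken as the outer boundary.
    """
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("mask has no contour")
    contour = max(contours, key=len)[:-1]  # closed: drop duplicate endpoint
    for _ in range(2):
        contour = (contour + np.roll(contour, -1, axis=0)) / 2.0
    seg = contour - np.roll(contour, -1, axis=0)
    return float(np.sqrt((seg**2).sum(axis=1)).sum())


def compute_shape_features(roi: RoiMask) -> ShapeFeatures:
    """Compute the six shape descriptors of one striatal ROI.

    Area is the pixel count times the pixel area; the perimeter follows the
    corner-cut marching-squares convention of :func:`mask_perimeter`; axis
    lengths come from the ellipse with identical normalized second central
    moments (4 * sqrt of the covariance eigenvalues); equivalent diameter
    and circularity are exact functions of area and perimeter.
    """
    px, py = roi.pixel_mm
    if abs(px - py) > 1e-9:
        raise ValueError("anisotropic in-plane pixels are not supported")
    mask = ndimage.binary_fill_holes(roi.mask)
    if mask.sum() != roi.n_pixels:
        logger.info("filled %d hole pixel(s) before shape analysis",
                    int(mask.sum() - roi.n_pixels))

    area_px = float(mask.sum())
    perim_px = mask_perimeter(mask)
    props = measure.regionprops(mask.astype(np.uint8))[0]

    area = area_px * px * py
    perimeter = perim_px * px
    return ShapeFeatures(
        area=area,
        equivalent_diameter=float(np.sqrt(4.0 * area / np.pi)),
        major_axis_length=float(props.axis_major_length) * px,
        minor_axis_length=float(props.axis_minor_length) * px,
        perimeter=perimeter,
        circularity=float(4.0 * np.pi * area / perimeter**2),
    )


def compute_intensity_features(roi: RoiMask, image: SummedImage) -> IntensityFeatures:
    """Max/min/mean pixel count over the ROI foreground of the summed image."""
    if roi.mask.shape != image.data.shape:
        raise ValueError("ROI mask and summed image shapes differ")
    vals = image.data[roi.mask]
    return IntensityFeatures(
        max_count=float(vals.max()),
        min_count=float(vals.min()),
        mean_count=float(vals.mean()),
    )
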