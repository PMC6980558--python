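"""Axial slice selection and summed-image construction.

DAT-SPECT quantification works on a single 2D image with high
striatum-to-background contrast.  The axial slice with the hottest striatal
signal is located (searching only above the parotid glands, which can be
hotter than the striatum), and the slice plus its two upper and two lower
neighbours are summed into one image (5 slices, 1 cm at 2-mm spacing).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["Volume", "SummedImage", "find_striatal_max_slice", "make_summed_image"]


@dataclass(frozen=True)
class Volume:
    """A 3D emission volume indexed ``(x, y, z)`` with ``z`` axial.

    Parameters
    ----------
    data : ndarray
        Nonnegative, finite 3D intensity grid.
    voxel_mm : tuple of float
        Voxel edge lengths in mm for each axis.
    """

    data: np.ndarray
    voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite values")
        if data.min() < 0:
            raise ValueError("volume contains negative intensities")
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel_mm must be 3 positive reals, got {self.voxel_mm}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_mm", tuple(float(v) for v in self.voxel_mm))

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class SummedImage:
    """A 2D image formed by summing consecutive axial slices.

    ``slice_range`` is the inclusive (low, high) pair of axial indices that
    were summed; ``center_slice`` is the striatal peak slice the range was
    built around.
    """

    data: np.ndarray
    center_slice: int
    slice_range: tuple[int, int]
    voxel_mm: tuple[float, float] = (2.0, 2.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValueError("summed image must be 2D")
        lo, hi = self.slice_range
        if not lo <= self.center_slice <= hi:
            raise ValueError("center_slice must lie inside slice_range")
        object.__setattr__(self, "data", data)

    @property
    def n_summed(self) -> int:
        return self.slice_range[1] - self.slice_range[0] + 1


def find_striatal_max_slice(volume: Volume, parotid_boundary: int) -> int:
    """Locate the axial slice with the hottest striatal signal.

    Scans slices strictly above ``parotid_boundary`` and returns the index
    whose per-slice maximum intensity is largest.  Ties are broken toward
    the lower (more inferior) index so the result is deterministic.

    Parameters
    ----------
    volume : Volume
        The emission volume.
    parotid_boundary : int
        Highest axial index still attributed to the parotid level; the
        search covers ``parotid_boundary + 1 .. n_slices - 1``.

    Returns
    -------
    int
        Axial index of the striatal peak slice.
    """
    nz = volume.n_slices
    if not 0 <= parotid_boundary < nz - 1:
        raise ValueError(
            f"parotid_boundary {parotid_boundary} leaves no slices to search "
            f"in a volume with {nz} axial slices"
        )
    sub = volume.data[:, :, parotid_boundary + 1 :]
    if not sub.any():
        raise ValueError("volume is zero above the parotid boundary")
    per_slice_max = sub.max(axis=(0, 1))
    # argmax returns the first (lowest) index on ties
    return int(np.argmax(per_slice_max)) + parotid_boundary + 1


def make_summed_image(volume: Volume, center_slice: int, half_width: int = 2) -> SummedImage:
    """Sum ``center_slice ± half_width`` axial slices into one 2D image.

    The range is clipped at the volume boundaries (with a warning) so the
    image is always defined; provenance indices are recorded on the result.
    """
    nz = volume.n_slices
    if not 0 <= center_slice < nz:
        raise ValueError(f"center_slice {center_slice} out of range [0, {nz})")
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    lo = center_slice - half_width
    hi = center_slice + half_width
    if lo < 0 or hi > nz - 1:
        lo_c, hi_c = max(lo, 0), min(hi, nz - 1)
        warnings.warn(
            f"summed-image range [{lo}, {hi}] clipped to [{lo_c}, {hi_c}] "
            f"at the volume boundary; {hi_c - lo_c + 1} slices summed",
            stacklevel=2,
        )
        lo, hi = lo_c, hi_c
    vx = volume.voxel_mm
    if abs(vx[2] - 2.0) > 1e-9 and half_width == 2:
        logger.warning(
            "slice spacing is %.3g mm, not 2 mm: the 5-slice summed image "
            "no longer spans 1 cm", vx[2],
        )
    data = volume.data[:, :, lo : hi + 1].sum(axis=2)
    return SummedImage(
        data=data,
        center_slice=int(center_slice),
        slice_range=(int(lo), int(hi)),
        voxel_mm=(vx[0], vx[1]),
    )
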