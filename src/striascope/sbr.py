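"""Striatum binding ratios (SBR) following the PPMI single-slice recipe.

SBR = (target-region count density / occipital reference density) - 1.
The count densities are read off a single image built by averaging the
eight hottest striatal slices around the striatal peak slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .summed import Volume, find_striatal_max_slice

__all__ = ["SbrResult", "average_hottest_slices", "compute_sbr", "compute_sbrs"]

_REGIONS = ("caudate_left", "caudate_right", "putamen_left", "putamen_right")


@dataclass(frozen=True)
class SbrResult:
    """Per-region and aggregated SBRs plus the reference density used."""

    sbr_caudate_left: float
    sbr_caudate_right: float
    sbr_putamen_left: float
    sbr_putamen_right: float
    sbr_caudate: float
    sbr_putamen: float
    reference_mean: float
    slice_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for name in ("sbr_caudate_left", "sbr_caudate_right",
                     "sbr_putamen_left", "sbr_putamen_right"):
            if getattr(self, name) <= -1.0:
                raise ValueError(f"{name} must exceed -1")


def average_hottest_slices(
    volume: Volume,
    parotid_boundary: int,
    n: int = 8,
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Average the ``n`` hottest striatal slices around the peak slice.

    The striatal peak slice is found above the parotid boundary; the window
    is then grown one slice at a time toward whichever neighbour has the
    higher per-slice maximum (ties toward the lower index) until it holds
    ``n`` contiguous slices.  Returns the voxelwise mean image and the
    selected axial indices.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    nz = volume.n_slices
    n_avail = nz - (parotid_boundary + 1)
    if n_avail < n:
        raise ValueError(
            f"only {n_avail} slices above the parotid boundary, need {n}"
        )
    peak = find_striatal_max_slice(volume, parotid_boundary)
    per_slice_max = volume.data.max(axis=(0, 1))
    lo = hi = peak
    while hi - lo + 1 < n:
        lo_next = lo - 1 if lo - 1 > parotid_boundary else None
        hi_next = hi + 1 if hi + 1 < nz else None
        if lo_next is None and hi_next is None:
            raise ValueError("window cannot grow: volume too short")
        if hi_next is None:
            lo = lo_next
        elif lo_next is None:
            hi = hi_next
        elif per_slice_max[lo_next] >= per_slice_max[hi_next]:
            lo = lo_next  # ties toward the lower (inferior) slice
        else:
            hi = hi_next
    indices = tuple(range(lo, hi + 1))
    mean_img = volume.data[:, :, lo : hi + 1].mean(axis=2)
    return mean_img, indices


def compute_sbr(target_mean: float, reference_mean: float) -> float:
    """SBR = target/reference - 1."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return float(target_mean) / float(reference_mean) - 1.0


def _region_mean(
    volume: Volume,
    avg_img: np.ndarray,
    mask: np.ndarray,
    indices: tuple[int, ...],
) -> float:
    """Count density of a region on the selected hottest slices.

    2D masks are applied to the averaged single-slice image.  3D masks are
    restricted to the selected slices and averaged voxelwise there, so a
    region whose axial footprint varies across slices is not diluted by
    out-of-region voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 2:
        if mask.shape != avg_img.shape:
            raise ValueError("2D mask shape does not match the volume plane")
        if not mask.any():
            raise ValueError("region mask is empty")
        return float(avg_img[mask].mean())
    if mask.ndim == 3:
        sub = mask[:, :, list(indices)]
        if not sub.any():
            raise ValueError("region mask is empty on the selected slices")
        return float(volume.data[:, :, list(indices)][sub].mean())
    raise ValueError("region masks must be 2D or 3D")


def _footprint(mask: np.ndarray, indices: tuple[int, ...]) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    return mask if mask.ndim == 2 else mask[:, :, list(indices)].any(axis=2)


def compute_sbrs(
    volume: Volume,
    region_masks: dict[str, np.ndarray],
    reference_mask: np.ndarray,
    aggregation: str = "mean",
    parotid_boundary: int = 0,
    n_slices: int = 8,
) -> SbrResult:
    """Compute the four regional SBRs and their left/right aggregates.

    ``region_masks`` must provide 2D or 3D masks for caudate_left/right and
    putamen_left/right; 3D masks are projected over the selected hottest
    slices.  ``aggregation`` of the left/right pair is ``"mean"`` or
    ``"worst"`` (the lower SBR, i.e. the more affected side).
    """
    if aggregation not in ("mean", "worst"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    missing = [r for r in _REGIONS if r not in region_masks]
    if missing:
        raise ValueError(f"missing region masks: {missing}")

    avg_img, indices = average_hottest_slices(volume, parotid_boundary, n=n_slices)

    reference_mean = _region_mean(volume, avg_img, reference_mask, indices)
    if reference_mean <= 0:
        raise ValueError("reference region has nonpositive mean count")

    ref_fp = _footprint(reference_mask, indices)
    sbr = {}
    for region in _REGIONS:
        if (_footprint(region_masks[region], indices) & ref_fp).any():
            raise ValueError(f"region mask {region} overlaps the reference region")
        sbr[region] = compute_sbr(
            _region_mean(volume, avg_img, region_masks[region], indices),
            reference_mean,
        )

    agg = (lambda a, b: (a + b) / 2.0) if aggregation == "mean" else min
    return SbrResult(
        sbr_caudate_left=sbr["caudate_left"],
        sbr_caudate_right=sbr["caudate_right"],
        sbr_putamen_left=sbr["putamen_left"],
        sbr_putamen_right=sbr["putamen_right"],
        sbr_caudate=agg(sbr["caudate_left"], sbr["caudate_right"]),
        sbr_putamen=agg(sbr["putamen_left"], sbr["putamen_right"]),
        reference_mean=reference_mean,
        slice_indices=indices,
    )
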