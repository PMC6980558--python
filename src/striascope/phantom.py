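"""Digital striatal phantom generator.

Produces SPECT-like 3D volumes with a known ground truth, emulating the
morphology that drives striatal shape analysis: in normal controls (NC) the
striatal tracer uptake forms a bilateral "comma" (caudate head plus an
elongated putamen at equal intensity), while in Parkinson's disease (PD)
putaminal uptake is lost first, leaving an "egg"- or "dot"-shaped,
caudate-dominant region.  Each phantom carries per-region truth masks and
the true striatum binding ratio implied by its construction, so the whole
feature pipeline can be validated as a parameter-recovery experiment.

A phantom is assembled in intensity units relative to the occipital
reference level: a brain ellipsoid of uniform nonspecific uptake (the
occipital reference region is a posterior sub-slab of it), bilateral
caudate and putamen compartments at ``uptake_contrast`` times the
reference (the putamen scaled by ``putamen_intensity_fraction``), and a
bright parotid-like pair of ellipsoids on a low axial slice so that slice
searches must actively skip them.  A Gaussian resolution blur (FWHM in mm)
is applied first, then Poisson-like count noise (sd = noise_scale * sqrt(I)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .summed import Volume

__all__ = [
    "SideGeometry",
    "StriatumParams",
    "PhantomSpec",
    "Phantom",
    "CohortParams",
    "generate_phantom",
    "generate_cohort",
    "save_phantom",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SideGeometry:
    """Geometry of one striatal side, in mm offsets from the grid centre.

    The caudate head is a roundish ellipsoid placed anterior-medially; the
    putamen is an elongated ellipsoid placed posterior-laterally and
    rotated in the axial plane so the union forms a comma.  ``mirror=-1``
    flips the x offsets and the rotation for the contralateral side.
    """

    caudate_center: tuple[float, float, float] = (13.0, 14.0, 0.0)
    caudate_radii: tuple[float, float, float] = (6.0, 9.0, 9.0)
    putamen_center: tuple[float, float, float] = (23.0, -4.0, 0.0)
    putamen_radii: tuple[float, float, float] = (6.5, 15.0, 8.0)
    putamen_rotation_deg: float = 20.0


@dataclass(frozen=True)
class StriatumParams:
    """Striatal geometry plus the putaminal intensity fraction.

    ``putamen_intensity_fraction`` is 1.0 for the NC comma (putamen as hot
    as the caudate) and low for PD (putaminal loss).  ``radius_scale``
    jitters overall striatal size per subject.
    """

    geometry: SideGeometry = field(default_factory=SideGeometry)
    putamen_intensity_fraction: float = 1.0
    radius_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.putamen_intensity_fraction <= 1.0:
            raise ValueError("putamen_intensity_fraction must be in [0, 1]")
        if self.radius_scale <= 0:
            raise ValueError("radius_scale must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Full specification of one synthetic subject.

    Parameters
    ----------
    group : {"NC", "PD"}
        Group label carried through to the feature table.
    grid_shape : tuple of int
        Volume shape ``(nx, ny, nz)``; default matches the 91x109x91
        grid of preprocessed PPMI SPECT.
    voxel_mm : float
        Isotropic voxel size in mm (default 2.0).
    striatum_params : StriatumParams
        Bilateral striatal geometry and putaminal fraction.
    uptake_contrast : float
        Striatum-to-reference intensity ratio; sets the true SBR
        (``contrast - 1`` in the caudate).
    occipital_level : float
        Reference-region (and nonspecific brain) intensity.
    parotid_level : float
        Intensity of the parotid-like hot pair; deliberately >= striatal
        intensity so naive whole-volume maxima land outside the brain.
    parotid_slice_index : int
        Axial index of the parotid centre, strictly below the striatum.
    fwhm_mm : float
        Gaussian resolution blur FWHM in mm (default 6.0).
    noise_scale : float
        Count-noise scale; Gaussian sd = noise_scale * sqrt(intensity).
    seed : int
        Seed for the noise stream; fixed seed gives bit-identical volumes.
    """

    group: str = "NC"
    grid_shape: tuple[int, int, int] = (91, 109, 91)
    voxel_mm: float = 2.0
    striatum_params: StriatumParams = field(default_factory=StriatumParams)
    uptake_contrast: float = 3.0
    occipital_level: float = 1.0
    parotid_level: float = 4.0
    parotid_slice_index: int = 15
    fwhm_mm: float = 6.0
    noise_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("NC", "PD"):
            raise ValueError(f"group must be 'NC' or 'PD', got {self.group!r}")
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ValueError(f"invalid grid_shape {self.grid_shape}")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        for name in ("uptake_contrast", "occipital_level", "parotid_level", "noise_scale", "fwhm_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.occipital_level <= 0:
            raise ValueError("occipital_level must be positive (reference region)")
        if not 0 <= self.parotid_slice_index < self.grid_shape[2]:
            raise ValueError("parotid_slice_index outside the grid")
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))

    @property
    def true_sbr(self) -> dict[str, float]:
        """Ground-truth SBR per region implied by the construction."""
        c = self.uptake_contrast
        f = self.striatum_params.putamen_intensity_fraction
        return {
            "caudate_left": c - 1.0,
            "caudate_right": c - 1.0,
            "putamen_left": c * f - 1.0,
            "putamen_right": c * f - 1.0,
        }


@dataclass(frozen=True)
class Phantom:
    """A generated phantom: volume, truth masks, true SBRs, and its spec."""

    volume: Volume
    truth_masks: dict[str, np.ndarray]
    true_sbr: dict[str, float]
    spec: PhantomSpec

    @property
    def striatal_z_range(self) -> tuple[int, int]:
        """Inclusive axial extent of the striatal truth masks."""
        zs = np.zeros(self.volume.n_slices, dtype=bool)
        for name, m in self.truth_masks.items():
            if name.startswith(("caudate", "putamen")):
                zs |= m.any(axis=(0, 1))
        idx = np.flatnonzero(zs)
        return int(idx[0]), int(idx[-1])

    def parotid_boundary(self, margin: int = 8) -> int:
        """Axial boundary for slice searches: parotid centre + margin."""
        return self.spec.parotid_slice_index + margin


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center_vox: np.ndarray,
    radii_vox: np.ndarray,
    rot_z_deg: float = 0.0,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Boolean ellipsoid evaluated only inside its bounding box.

    Returns the bounding-box slices and the local mask, keeping cohort
    generation cheap on the full 91^3-scale grid.
    """
    r_max = float(np.max(radii_vox)) + 1.0
    lo = np.maximum(np.floor(center_vox - r_max).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + r_max).astype(int) + 1, shape)
    if np.any(lo >= hi):
        raise ValueError("ellipsoid lies outside the grid")
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    ax = [np.arange(s.start, s.stop, dtype=float) for s in sl]
    th = np.deg2rad(rot_z_deg)
    dx = (ax[0] - center_vox[0])[:, None, None]
    dy = (ax[1] - center_vox[1])[None, :, None]
    dz = (ax[2] - center_vox[2])[None, None, :]
    # rotate in the axial (x, y) plane
    du = np.cos(th) * dx + np.sin(th) * dy
    dv = -np.sin(th) * dx + np.cos(th) * dy
    q = (du / radii_vox[0]) ** 2 + (dv / radii_vox[1]) ** 2 + (dz / radii_vox[2]) ** 2
    return sl, q <= 1.0


def _place(mask: np.ndarray, sl, local: np.ndarray) -> None:
    mask[sl] |= local


def _build_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    shape = spec.grid_shape
    vox = spec.voxel_mm
    center = np.array([(s - 1) / 2.0 for s in shape])
    geom = spec.striatum_params.geometry
    rs = spec.striatum_params.radius_scale

    masks = {
        name: np.zeros(shape, dtype=bool)
        for name in (
            "brain", "caudate_left", "caudate_right",
            "putamen_left", "putamen_right", "occipital", "parotid",
        )
    }

    # brain: large ellipsoid of nonspecific uptake, above the parotid level
    brain_radii = np.array([shape[0] * 0.42, shape[1] * 0.42, shape[2] * 0.34])
    brain_center = center + np.array([0.0, 0.0, shape[2] * 0.08])
    sl, m = _ellipsoid_mask(shape, brain_center, brain_radii)
    _place(masks["brain"], sl, m)

    for side, mirror in (("right", 1.0), ("left", -1.0)):
        for region, c_mm, r_mm, rot in (
            ("caudate", geom.caudate_center, geom.caudate_radii, 0.0),
            ("putamen", geom.putamen_center, geom.putamen_radii, geom.putamen_rotation_deg),
        ):
            c_vox = center + np.array([mirror * c_mm[0], c_mm[1], c_mm[2]]) / vox
            r_vox = rs * np.array(r_mm) / vox
            sl, m = _ellipsoid_mask(shape, c_vox, r_vox, mirror * rot)
            _place(masks[f"{region}_{side}"], sl, m)

    # caudate takes priority in any caudate/putamen overlap (disjoint truth)
    for side in ("left", "right"):
        masks[f"putamen_{side}"] &= ~(masks["caudate_left"] | masks["caudate_right"])

    striatum = (
        masks["caudate_left"] | masks["caudate_right"]
        | masks["putamen_left"] | masks["putamen_right"]
    )
    if not striatum.any() or (striatum & ~masks["brain"]).any():
        raise ValueError("grid too small to contain the configured striatal geometry")

    # occipital reference: posterior slab of the brain at striatal height,
    # well clear of the striatum
    occ = np.zeros(shape, dtype=bool)
    y_hi = int(center[1] - shape[1] * 0.30)
    z_striatum = striatum.any(axis=(0, 1))
    occ[:, :y_hi, :] = z_striatum[None, None, :]
    occ &= masks["brain"] & ~striatum
    if not occ.any():
        raise ValueError("grid too small for an occipital reference region")
    masks["occipital"] = occ

    # parotid-like hot pair below the brain
    z_lowest_striatum = int(np.flatnonzero(z_striatum)[0])
    if spec.parotid_slice_index >= z_lowest_striatum:
        raise ValueError(
            f"parotid_slice_index {spec.parotid_slice_index} is not strictly "
            f"below the striatum (lowest striatal slice {z_lowest_striatum})"
        )
    parotid_radii = np.array([10.0, 10.0, 8.0]) / vox
    for mirror in (1.0, -1.0):
        c_vox = np.array([
            center[0] + mirror * 28.0 / vox,
            center[1] + 6.0 / vox,
            float(spec.parotid_slice_index),
        ])
        sl, m = _ellipsoid_mask(shape, c_vox, parotid_radii)
        _place(masks["parotid"], sl, m)
    masks["parotid"] &= ~masks["brain"]
    return masks


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one phantom volume from its spec.

    The noiseless, unblurred compartment image is assembled first (so the
    truth SBRs are exact by construction), then blurred with the configured
    FWHM, then degraded with count noise.  Deterministic for a fixed seed.
    """
    masks = _build_masks(spec)
    occ = spec.occipital_level
    striatal = occ * spec.uptake_contrast
    putaminal = striatal * spec.striatum_params.putamen_intensity_fraction

    vol = np.zeros(spec.grid_shape, dtype=np.float64)
    vol[masks["brain"]] = occ
    vol[masks["caudate_left"] | masks["caudate_right"]] = striatal
    vol[masks["putamen_left"] | masks["putamen_right"]] = putaminal
    vol[masks["parotid"]] = spec.parotid_level

    if spec.fwhm_mm > 0:
        sigma_vox = spec.fwhm_mm * _FWHM_TO_SIGMA / spec.voxel_mm
        vol = gaussian_filter(vol, sigma=sigma_vox)
    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(size=vol.shape) * (spec.noise_scale * np.sqrt(vol))
    np.clip(vol, 0.0, None, out=vol)

    truth = {k: masks[k] for k in (
        "caudate_left", "caudate_right", "putamen_left", "putamen_right", "occipital",
    )}
    return Phantom(
        volume=Volume(vol, (spec.voxel_mm,) * 3),
        truth_masks=truth,
        true_sbr=spec.true_sbr,
        spec=spec,
    )


@dataclass(frozen=True)
class CohortParams:
    """Population distributions the cohort generator draws subjects from.

    Gaussian means/sds per group; putaminal fractions are clipped into
    [0.02, 1.0] and contrasts to >= 1.3 so no burst-striatum-like subject
    (near-total bilateral loss) is ever emitted.
    """

    nc_putamen_fraction: tuple[float, float] = (0.95, 0.03)
    pd_putamen_fraction: tuple[float, float] = (0.30, 0.10)
    nc_uptake_contrast: tuple[float, float] = (3.0, 0.25)
    pd_uptake_contrast: tuple[float, float] = (2.4, 0.25)
    radius_scale: tuple[float, float] = (1.0, 0.05)
    noise_scale: float = 0.1
    fwhm_mm: float = 6.0
    grid_shape: tuple[int, int, int] = (91, 109, 91)
    voxel_mm: float = 2.0

    MIN_CONTRAST = 1.3
    MIN_FRACTION = 0.02

    def __post_init__(self) -> None:
        for name in ("nc_putamen_fraction", "pd_putamen_fraction",
                     "nc_uptake_contrast", "pd_uptake_contrast", "radius_scale"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} spread must be nonnegative")
            if mean <= 0:
                raise ValueError(f"{name} mean must be positive")
        if self.nc_putamen_fraction[0] <= self.pd_putamen_fraction[0]:
            raise ValueError("NC putamen_intensity_fraction mean must exceed PD's")


def _draw_spec(group: str, params: CohortParams, rng: np.random.Generator,
               seed: int) -> PhantomSpec:
    if group == "NC":
        frac_ms, con_ms = params.nc_putamen_fraction, params.nc_uptake_contrast
    else:
        frac_ms, con_ms = params.pd_putamen_fraction, params.pd_uptake_contrast
    frac = float(np.clip(rng.normal(*frac_ms), params.MIN_FRACTION, 1.0))
    contrast = float(max(rng.normal(*con_ms), params.MIN_CONTRAST))
    rscale = float(np.clip(rng.normal(*params.radius_scale), 0.7, 1.3))
    return PhantomSpec(
        group=group,
        grid_shape=params.grid_shape,
        voxel_mm=params.voxel_mm,
        striatum_params=StriatumParams(
            putamen_intensity_fraction=frac, radius_scale=rscale,
        ),
        uptake_contrast=contrast,
        fwhm_mm=params.fwhm_mm,
        noise_scale=params.noise_scale,
        seed=seed,
    )


def generate_cohort(
    n_nc: int,
    n_pd: int,
    population_params: CohortParams | None = None,
    seed: int = 0,
    lazy: bool = False,
):
    """Draw a reproducible cohort of NC and PD phantoms.

    Per-subject specs are drawn from the population distributions using a
    child stream of ``seed`` (one spawn per subject), so the cohort is
    identical across calls with the same arguments.

    Parameters
    ----------
    n_nc, n_pd : int
        Group sizes (>= 1 each).
    population_params : CohortParams, optional
        Population distributions; defaults are the package's reference
        recovery-experiment conditions.
    seed : int
        Master seed; all randomness flows from it.
    lazy : bool
        If True, yield ``(spec, label)`` pairs and leave volume generation
        to the caller (memory-friendly for large cohorts).

    Returns
    -------
    list of (Phantom or PhantomSpec, str)
    """
    if n_nc < 1 or n_pd < 1:
        raise ValueError("n_nc and n_pd must both be >= 1")
    params = population_params or CohortParams()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_nc + n_pd)
    labels = ["NC"] * n_nc + ["PD"] * n_pd
    out = []
    for label, child in zip(labels, children):
        rng = np.random.default_rng(child)
        noise_seed = int(rng.integers(0, 2**31 - 1))
        spec = _draw_spec(label, params, rng, noise_seed)
        out.append((spec if lazy else generate_phantom(spec), label))
    return out


def save_phantom(phantom: Phantom, out_dir: str | Path, subject_id: str) -> dict[str, str]:
    """Write a phantom volume and its truth masks as NIfTI files.

    Returns a mapping of artefact name to file path.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(phantom.volume.voxel_mm) + [1.0])
    paths: dict[str, str] = {}

    img = nib.Nifti1Image(phantom.volume.data.astype(np.float32), affine)
    p = out_dir / f"{subject_id}.nii.gz"
    nib.save(img, p)
    paths["volume"] = str(p)
    for name, mask in phantom.truth_masks.items():
        m = nib.Nifti1Image(mask.astype(np.uint8), affine)
        mp = out_dir / f"{subject_id}_mask_{name}.nii.gz"
        nib.save(m, mp)
        paths[f"mask_{name}"] = str(mp)
    spec_path = out_dir / f"{subject_id}_spec.json"
    spec_path.write_text(json.dumps(asdict(phantom.spec), indent=2, sort_keys=True))
    paths["spec"] = str(spec_path)
    return paths
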