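"""Count-domain PET phantoms with habitus-dependent liver noise.

The phantom is a 3-D grid of independent Poisson counts.  The liver rate
is tied to the habitus/image-quality model: with amplitude ``a`` and
exponent ``d``, a patient of body mass ``m`` scanned at dose–time product
``DTP = activity × minutes-per-bed-position`` receives liver voxels

    counts ~ Poisson(λ),   λ = (a · m^(−d))² · DTP

so the expected per-voxel signal-to-noise ratio (mean/SD = √λ) equals
``a · m^(−d) · √DTP`` by construction.  A scalar calibration factor maps
counts to standardized uptake values (SUV) so that the liver SUVmean
matches a target biodistribution level.

Shorter acquisitions are emulated the way list-mode data are
retrospectively subsampled: every voxel's count is binomially thinned,
which maps Poisson(λ) marginals to Poisson(fλ) while preserving the
within-scan correlation structure of nested subsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

from .cohort import PatientRecord

__all__ = [
    "AcquisitionMeta",
    "LesionSpec",
    "PhantomGeometry",
    "CountVolume",
    "SuvVolume",
    "generate_phantom",
    "thin_counts",
    "counts_to_suv",
    "save_suv_nifti",
    "load_suv_nifti",
]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Administered activity (MBq) and acquisition time per bed (min)."""

    activity: float
    mbp: float

    def __post_init__(self) -> None:
        if self.activity <= 0:
            raise ValueError("activity must be > 0 MBq")
        if self.mbp <= 0:
            raise ValueError("mbp must be > 0 min")

    @property
    def dtp(self) -> float:
        """Dose–time product, MBq·min."""
        return self.activity * self.mbp


@dataclass(frozen=True)
class LesionSpec:
    """A spherical hot lesion: center (mm), diameter (mm), target SUVmean."""

    center: tuple[float, float, float]
    diameter: float
    suv_mean_target: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("lesion diameter must be > 0 mm")
        if self.suv_mean_target <= 0:
            raise ValueError("lesion SUV target must be > 0")


@dataclass(frozen=True)
class PhantomGeometry:
    """Torso/liver layout of the synthetic volume.

    World coordinates are millimetres; voxel ``(i, j, k)`` has its center
    at ``(i·vx, j·vy, k·vz)``.  The liver is an ellipsoid inside a larger
    torso ellipsoid; everything outside the torso is air (zero rate).
    """

    shape: tuple[int, int, int] = (100, 100, 60)
    voxel_size: tuple[float, float, float] = (4.1, 4.1, 3.0)
    liver_semiaxes: tuple[float, float, float] = (80.0, 60.0, 50.0)
    liver_offset: tuple[float, float, float] = (40.0, 0.0, 0.0)  # from grid center
    torso_semiaxes: tuple[float, float, float] = (190.0, 150.0, 500.0)
    background_suv: float = 1.0

    @property
    def grid_center(self) -> tuple[float, float, float]:
        return tuple(
            (n - 1) / 2.0 * v for n, v in zip(self.shape, self.voxel_size)
        )

    @property
    def liver_center(self) -> tuple[float, float, float]:
        return tuple(c + o for c, o in zip(self.grid_center, self.liver_offset))

    @property
    def liver_voi_center(self) -> tuple[float, float, float]:
        """Default center for the homogeneous right-lobe measurement VOI."""
        return self.liver_center

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.ogrid[
            0 : self.shape[0], 0 : self.shape[1], 0 : self.shape[2]
        ]  # type: ignore[return-value]

    def _ellipsoid(self, center, semiaxes) -> np.ndarray:
        ii, jj, kk = self.coordinate_grids()
        vx, vy, vz = self.voxel_size
        return (
            ((ii * vx - center[0]) / semiaxes[0]) ** 2
            + ((jj * vy - center[1]) / semiaxes[1]) ** 2
            + ((kk * vz - center[2]) / semiaxes[2]) ** 2
        ) <= 1.0

    def sphere_mask(self, center, diameter: float) -> np.ndarray:
        r = diameter / 2.0
        return self._ellipsoid(center, (r, r, r))

    def organ_masks(self, lesions: Sequence[LesionSpec] = ()) -> dict[str, np.ndarray]:
        """Mutually disjoint liver / lesion / background masks."""
        liver = self._ellipsoid(self.liver_center, self.liver_semiaxes)
        torso = self._ellipsoid(self.grid_center, self.torso_semiaxes)
        lesion = np.zeros(self.shape, dtype=bool)
        for spec in lesions:
            lesion |= self.sphere_mask(spec.center, spec.diameter)
        liver &= ~lesion
        background = torso & ~liver & ~lesion
        return {"liver": liver, "lesions": lesion, "background": background}


@dataclass
class CountVolume:
    """Raw Poisson counts with a count→SUV calibration factor."""

    grid: np.ndarray  # non-negative integers
    voxel_size: tuple[float, float, float]
    calibration: float  # SUV per count
    meta: AcquisitionMeta
    organ_masks: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class SuvVolume:
    """Voxel values in SUV units."""

    grid: np.ndarray
    voxel_size: tuple[float, float, float]
    meta: AcquisitionMeta
    organ_masks: dict[str, np.ndarray] = field(default_factory=dict)


def liver_rate(body_mass: float, model: tuple[float, float], dtp: float) -> float:
    """Expected liver counts per voxel: λ = (a·m^(−d))²·DTP."""
    a, d = model
    return (a * body_mass ** (-d)) ** 2 * dtp


def generate_phantom(
    patient: PatientRecord | float,
    meta: AcquisitionMeta,
    model: tuple[float, float] = (19.6, 0.95),
    liver_suv: float = 5.8,
    lesions: Sequence[LesionSpec] = (),
    seed: int | np.random.Generator = 0,
    geometry: PhantomGeometry | None = None,
) -> CountVolume:
    """Simulate one count-domain PET volume.

    Liver voxels are Poisson with rate ``(a·m^(−d))²·DTP``; the
    calibration is set to ``liver_suv / λ`` so the liver SUVmean is
    ``liver_suv`` in expectation.  Lesion and background rates are scaled
    to their SUV targets through the same calibration.  Deterministic for
    a fixed integer seed.
    """
    a, d = model
    if a <= 0:
        raise ValueError("model amplitude a must be > 0")
    if d < 0:
        raise ValueError("model exponent d must be >= 0")
    if liver_suv <= 0:
        raise ValueError("liver_suv must be > 0")
    geometry = geometry or PhantomGeometry()
    mass = patient.body_mass if isinstance(patient, PatientRecord) else float(patient)
    lam = liver_rate(mass, model, meta.dtp)
    if lam < 1.0:
        raise ValueError(
            f"liver rate λ={lam:.3g} < 1 count/voxel; the Poisson noise model "
            "breaks down — increase the dose-time product"
        )
    masks = geometry.organ_masks(lesions)
    rate = np.zeros(geometry.shape, dtype=float)
    rate[masks["background"]] = lam * geometry.background_suv / liver_suv
    rate[masks["liver"]] = lam
    for spec in lesions:
        rate[geometry.sphere_mask(spec.center, spec.diameter)] = (
            lam * spec.suv_mean_target / liver_suv
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = rng.poisson(rate)
    return CountVolume(
        grid=grid,
        voxel_size=geometry.voxel_size,
        calibration=liver_suv / lam,
        meta=meta,
        organ_masks=masks,
    )


def thin_counts(
    volume: CountVolume, fraction: float, seed: int | np.random.Generator = 0
) -> CountVolume:
    """Binomially thin counts to emulate a shorter list-mode acquisition.

    Each voxel count ``n`` is replaced by a Binomial(n, fraction) draw;
    acquisition time (and hence DTP) scales by ``fraction`` and the
    calibration by ``1/fraction`` so the expected SUV image is unchanged.
    ``fraction = 1`` returns the volume untouched.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if fraction == 1.0:
        return volume
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = rng.binomial(volume.grid, fraction)
    return CountVolume(
        grid=grid,
        voxel_size=volume.voxel_size,
        calibration=volume.calibration / fraction,
        meta=AcquisitionMeta(volume.meta.activity, volume.meta.mbp * fraction),
        organ_masks=volume.organ_masks,
    )


def counts_to_suv(volume: CountVolume) -> SuvVolume:
    """Apply the calibration factor, yielding an SUV volume."""
    if volume.calibration <= 0:
        raise ValueError("calibration must be > 0")
    return SuvVolume(
        grid=volume.grid * volume.calibration,
        voxel_size=volume.voxel_size,
        meta=volume.meta,
        organ_masks=volume.organ_masks,
    )


def _affine(voxel_size: Sequence[float]) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def save_suv_nifti(
    volume: SuvVolume, path: str | Path, seed: int | None = None
) -> None:
    """Write an SUV volume as NIfTI-1 (.nii.gz) with a JSON sidecar.

    Organ masks go to ``<stem>_mask_<name>.nii.gz`` as uint8; the sidecar
    records acquisition metadata and the mask file names.
    """
    path = Path(path)
    nib.save(
        nib.Nifti1Image(volume.grid.astype(np.float32), _affine(volume.voxel_size)),
        path,
    )
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    mask_files = {}
    for name, mask in volume.organ_masks.items():
        mask_path = path.with_name(f"{stem}_mask_{name}.nii.gz")
        nib.save(
            nib.Nifti1Image(mask.astype(np.uint8), _affine(volume.voxel_size)),
            mask_path,
        )
        mask_files[name] = mask_path.name
    sidecar = {
        "activity_mbq": volume.meta.activity,
        "mbp_min": volume.meta.mbp,
        "dtp": volume.meta.dtp,
        "seed": seed,
        "organ_mask_files": mask_files,
    }
    path.with_name(f"{stem}.json").write_text(json.dumps(sidecar, indent=2))


def load_suv_nifti(path: str | Path) -> SuvVolume:
    """Read an SUV volume and its sidecar/masks written by :func:`save_suv_nifti`."""
    path = Path(path)
    img = nib.load(path)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    sidecar = json.loads(path.with_name(f"{stem}.json").read_text())
    masks = {
        name: np.asarray(nib.load(path.with_name(fname)).dataobj).astype(bool)
        for name, fname in sidecar.get("organ_mask_files", {}).items()
    }
    return SuvVolume(
        grid=np.asarray(img.dataobj, dtype=float),
        voxel_size=voxel_size,  # type: ignore[arg-type]
        meta=AcquisitionMeta(sidecar["activity_mbq"], sidecar["mbp_min"]),
        organ_masks=masks,
    )
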