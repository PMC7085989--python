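"""Spherical VOIs and the image-quality / lesion-quantification measures.

The image-quality statistic is the liver signal-to-noise ratio: the
SUVmean inside a 3-cm spherical VOI in homogeneous liver divided by the
sample SD of the same voxels.  Normalizing by the square root of the
dose–time product (SNRnorm = SNR/√DTP) removes the dependence on
administered activity and scan time under Poisson statistics.

Lesion quantification follows the standard trio: SUVmax (hottest voxel in
the VOI), SUVpeak (hottest 1-cm³ spherical neighbourhood centered in the
VOI) and SUVmean from 50 %-of-SUVmax region growing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .phantom import AcquisitionMeta, CountVolume, SuvVolume

__all__ = [
    "VoiMask",
    "SnrResult",
    "SuvResult",
    "sphere_voi",
    "region_snr",
    "suv_metrics",
    "lesion_count_category",
]

#: Radius (mm) of a 1 cm³ sphere: (3/(4π))^(1/3) · 10.
PEAK_RADIUS_MM = (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0) * 10.0


@dataclass(frozen=True)
class VoiMask:
    """Boolean voxel mask of a spherical volume of interest."""

    mask: np.ndarray
    center: tuple[float, float, float]  # mm
    diameter: float  # mm

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SnrResult:
    """Liver-VOI statistics for one reconstruction."""

    suv_mean: float
    sd: float
    snr: float
    snr_norm: float  # (MBq·min)^(−1/2)
    meta: AcquisitionMeta


@dataclass(frozen=True)
class SuvResult:
    """Lesion SUV metrics for one VOI."""

    suv_max: float
    suv_peak: float
    suv_mean_50: float
    region_voxels: int
    kernel_cropped: bool = False


def sphere_voi(
    volume: CountVolume | SuvVolume,
    center: Sequence[float],
    diameter: float,
    liver_margin_mm: float = 10.0,
) -> VoiMask:
    """Rasterize a spherical VOI by voxel-center inclusion.

    A voxel belongs to the VOI iff its center lies within ``diameter/2``
    of ``center`` (world mm, voxel center at index·spacing).  A sphere
    extending past the grid raises; a degenerate sub-voxel sphere keeps
    the voxel nearest to the center.  If the volume carries a liver mask
    and any VOI voxel is closer than ``liver_margin_mm`` to the liver
    boundary, a warning is emitted (partial-volume hazard);
    ``liver_margin_mm <= 0`` disables the check (non-liver VOIs).
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0 mm")
    shape = volume.grid.shape
    spacing = np.asarray(volume.voxel_size, dtype=float)
    center = np.asarray(center, dtype=float)
    radius = diameter / 2.0
    extent = (np.asarray(shape) - 1) * spacing
    if np.any(center - radius < -spacing / 2) or np.any(
        center + radius > extent + spacing / 2
    ):
        raise ValueError(
            f"sphere (center {tuple(center)} mm, diameter {diameter} mm) "
            f"exceeds the grid extent {tuple(extent)} mm"
        )
    ii, jj, kk = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    dist2 = (
        (ii * spacing[0] - center[0]) ** 2
        + (jj * spacing[1] - center[1]) ** 2
        + (kk * spacing[2] - center[2]) ** 2
    )
    mask = dist2 <= radius**2
    if not mask.any():
        nearest = np.unravel_index(np.argmin(dist2), shape)
        mask[nearest] = True
    liver = volume.organ_masks.get("liver")
    if liver_margin_mm > 0 and liver is not None and liver.any():
        _warn_if_near_liver_edge(mask, liver, spacing, liver_margin_mm)
    return VoiMask(mask=mask, center=tuple(center), diameter=float(diameter))


def _warn_if_near_liver_edge(
    mask: np.ndarray, liver: np.ndarray, spacing: np.ndarray, margin_mm: float
) -> None:
    """Warn when any VOI voxel lies within ``margin_mm`` of the liver edge.

    The distance transform runs on the VOI bounding box padded by the
    margin; a boundary farther away than the pad cannot matter.
    """
    if (mask & ~liver).any():
        warnings.warn(
            "VOI extends outside the liver mask; edge effects likely",
            stacklevel=3,
        )
        return
    pad = np.ceil(margin_mm / spacing).astype(int) + 1
    idx = np.nonzero(mask)
    lo = [max(int(i.min()) - p, 0) for i, p in zip(idx, pad)]
    hi = [min(int(i.max()) + p + 1, n) for i, p, n in zip(idx, pad, mask.shape)]
    crop = tuple(slice(a, b) for a, b in zip(lo, hi))
    if liver[crop].all():  # no boundary within the padded box
        return
    dist = ndimage.distance_transform_edt(liver[crop], sampling=spacing)
    min_dist = float(dist[mask[crop]].min())
    if min_dist < margin_mm:
        warnings.warn(
            f"VOI approaches the liver boundary (min distance {min_dist:.1f} mm "
            f"< {margin_mm} mm); edge effects possible",
            stacklevel=3,
        )


def region_snr(
    suv_volume: SuvVolume,
    voi: VoiMask,
    meta: AcquisitionMeta | None = None,
) -> SnrResult:
    """Liver SUVmean, SD (n−1), SNR and SNRnorm inside a VOI."""
    values = suv_volume.grid[voi.mask]
    if values.size == 0:
        raise ValueError("VOI is empty")
    meta = meta or suv_volume.meta
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    # round-off from an exactly constant region still counts as SD = 0
    if sd <= 1e-12 * max(abs(mean), 1.0):
        raise ValueError("VOI is constant (SD = 0); SNR undefined")
    snr = mean / sd
    return SnrResult(
        suv_mean=mean,
        sd=sd,
        snr=snr,
        snr_norm=snr / np.sqrt(meta.dtp),
        meta=meta,
    )


def _peak_kernel(voxel_size: Sequence[float]) -> np.ndarray:
    """Boolean 1-cm³ sphere kernel rasterized by voxel-center inclusion."""
    spacing = np.asarray(voxel_size, dtype=float)
    half = np.floor(PEAK_RADIUS_MM / spacing).astype(int)
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij")
    return dx**2 + dy**2 + dz**2 <= PEAK_RADIUS_MM**2


def suv_metrics(suv_volume: SuvVolume, voi: VoiMask) -> SuvResult:
    """SUVmax, SUVpeak and 50 %-threshold region-growing SUVmean.

    SUVpeak scans every kernel position whose center voxel lies in the
    VOI and takes the highest kernel mean; kernels extending past the
    grid are cropped and the result flagged.  The 50 % region is the
    26-connected component of ``{SUV ≥ 0.5·SUVmax} ∩ VOI`` that contains
    the SUVmax voxel.
    """
    grid = suv_volume.grid.astype(float)
    if not voi.mask.any():
        raise ValueError("VOI is empty")
    in_voi = np.where(voi.mask, grid, -np.inf)
    seed = np.unravel_index(np.argmax(in_voi), grid.shape)
    suv_max = float(grid[seed])

    kernel = _peak_kernel(suv_volume.voxel_size)
    ksum = ndimage.correlate(grid, kernel.astype(float), mode="constant", cval=0.0)
    kcount = ndimage.correlate(
        np.ones_like(grid), kernel.astype(float), mode="constant", cval=0.0
    )
    kmean = ksum / kcount
    suv_peak = float(kmean[voi.mask].max())
    cropped = bool((kcount[voi.mask] < kernel.sum() - 0.5).any())

    candidates = (grid >= 0.5 * suv_max) & voi.mask
    labels, _ = ndimage.label(candidates, structure=np.ones((3, 3, 3), dtype=int))
    region = labels == labels[seed]
    return SuvResult(
        suv_max=suv_max,
        suv_peak=suv_peak,
        suv_mean_50=float(grid[region].mean()),
        region_voxels=int(region.sum()),
        kernel_cropped=cropped,
    )


#: Ordinal lesion-count bins: 0, 1, 2, 3–5, 6–10, >10 lesions.
_LESION_BIN_EDGES = (0, 1, 2, 5, 10)


def lesion_count_category(n_lesions: int) -> int:
    """Map a lesion count to its ordinal reporting category (0–5)."""
    n = int(n_lesions)
    if n != n_lesions:
        raise ValueError("n_lesions must be an integer")
    if n < 0:
        raise ValueError("n_lesions must be >= 0")
    for category, edge in enumerate(_LESION_BIN_EDGES):
        if n <= edge:
            return category
    return 5
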