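"""Volume data model, NIfTI I/O and spatial primitives.

All maps in a study live on one common lattice; a :class:`VolumeMap` is that
lattice plus its voxel geometry.  Out-of-brain voxels carry NaN as the
sentinel value.  World coordinates are derived from ``voxel_size_mm`` and
``origin`` only — no oblique affines, no resampling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeError(ValueError):
    """Malformed volume, geometry or parameter."""


@dataclass
class VolumeMap:
    """A 3-D lattice of real values with voxel geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values; NaN marks out-of-brain (sentinel) voxels.
    voxel_size_mm : tuple of 3 floats
        Strictly positive edge lengths of one voxel.
    origin : tuple of 3 floats
        World (mm) coordinates of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise VolumeError(
                f"expected a 3-D lattice, got {self.values.ndim}-D data"
            )
        if min(self.values.shape) < 1:
            raise VolumeError("every lattice dimension must be >= 1")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise VolumeError(f"voxel size must be 3 positive reals, got {self.voxel_size_mm}")
        self.origin = tuple(float(v) for v in self.origin)
        finite_or_nan = np.isfinite(self.values) | np.isnan(self.values)
        if not finite_or_nan.all():
            raise VolumeError("non-sentinel values must be finite (found +/-inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def brain_mask(self) -> np.ndarray:
        """Boolean mask of non-sentinel voxels."""
        return np.isfinite(self.values)

    def like(self, values: np.ndarray) -> "VolumeMap":
        """A new map with the same geometry and new values."""
        return VolumeMap(values, self.voxel_size_mm, self.origin)


@dataclass
class SphereOffsets:
    """Integer lattice offsets spanning a closed ball of ``radius_mm``.

    The zero offset (the sphere center) is always included, and the offset
    set is closed under sign flips along each axis.
    """

    radius_mm: float
    voxel_size_mm: tuple[float, float, float]
    offsets: np.ndarray = field(repr=False)  # (n, 3) int array

    def __len__(self) -> int:
        return len(self.offsets)


def _affine(voxel_size_mm, origin) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> VolumeMap:
    """Read one single 3-D NIfTI volume from ``path``.

    Raises
    ------
    IOError
        If the file is missing or not readable as NIfTI.
    VolumeError
        If the image is not 3-D.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    except VolumeError:
        raise
    except Exception as exc:  # nibabel raises a zoo of error types
        raise IOError(f"could not read volume {path!r}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeError(f"{path!r} holds a {data.ndim}-D image; expected a single 3-D volume")
    aff = img.affine
    voxel_size = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return VolumeMap(data, voxel_size, origin)


def write_volume(vmap: VolumeMap, path) -> str:
    """Write ``vmap`` to ``path`` as a NIfTI-1 file; returns the path."""
    img = nib.Nifti1Image(vmap.values, _affine(vmap.voxel_size_mm, vmap.origin))
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"could not write volume to {path!r}: {exc}") from exc
    return str(path)


def sphere_offsets(radius_mm: float, voxel_size_mm) -> SphereOffsets:
    """All integer lattice offsets within world distance ``radius_mm``.

    The ball is closed: offsets at exactly the radius are included.
    """
    voxel_size_mm = tuple(float(v) for v in voxel_size_mm)
    if any(v <= 0 for v in voxel_size_mm):
        raise VolumeError(f"voxel size must be positive, got {voxel_size_mm}")
    if radius_mm < 0:
        raise VolumeError("radius must be >= 0")
    bound = [int(np.floor(radius_mm / v)) for v in voxel_size_mm]
    offs = []
    for di, dj, dk in itertools.product(*(range(-b, b + 1) for b in bound)):
        d2 = (di * voxel_size_mm[0]) ** 2 + (dj * voxel_size_mm[1]) ** 2 + (dk * voxel_size_mm[2]) ** 2
        if d2 <= radius_mm ** 2 + 1e-9:
            offs.append((di, dj, dk))
    return SphereOffsets(radius_mm=float(radius_mm), voxel_size_mm=voxel_size_mm,
                         offsets=np.array(offs, dtype=np.int64))


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm) -> tuple[float, float, float]:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    factor = 2.0 * np.sqrt(2.0 * np.log(2.0))
    return tuple(fwhm_mm / factor / v for v in voxel_size_mm)


def smooth_volume(vmap: VolumeMap, fwhm_mm: float) -> VolumeMap:
    """Gaussian-smooth a map with the stated full-width-at-half-maximum.

    Anisotropic voxel sizes are honored per axis.  Sentinel (NaN) voxels are
    excluded from the convolution (normalized convolution over the finite
    support) and restored afterwards.  ``fwhm_mm == 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise VolumeError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return vmap.like(vmap.values.copy())
    sigma = fwhm_to_sigma_voxels(fwhm_mm, vmap.voxel_size_mm)
    mask = vmap.brain_mask
    if mask.all():
        out = ndimage.gaussian_filter(vmap.values, sigma=sigma, mode="reflect")
    else:
        filled = np.where(mask, vmap.values, 0.0)
        num = ndimage.gaussian_filter(filled, sigma=sigma, mode="reflect")
        den = ndimage.gaussian_filter(mask.astype(np.float64), sigma=sigma, mode="reflect")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(mask, num / den, np.nan)
    return vmap.like(out)
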