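"""Reading and writing 3D fluorescence stacks and masks with physical voxel spacing.

Volumes are stored as ``(z, y, x)`` arrays; the slice index is ``z``.  Voxel
spacing is always supplied by the caller in micrometres — TIFF resolution tags
are deliberately ignored (if present they may disagree with the acquisition
log, and the caller's value wins).
"""

from __future__ import annotations

import glob
import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

CHANNELS = ("NADH", "FAD", "RED", "FITC", "OTHER")

_SUPPORTED_DTYPES = (np.uint8, np.uint16, np.float32, np.float64)


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with per-axis voxel spacing in µm.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Non-negative intensities, nominally within the ``bit_depth`` range.
    spacing : tuple of float
        Voxel edge lengths ``(z, y, x)`` in µm; all strictly positive.
    channel : str
        One of ``NADH``, ``FAD``, ``RED``, ``FITC``, ``OTHER``.
    bit_depth : int
        Nominal intensity bit depth (default 16).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = "OTHER"
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")
        if self.voxels.size and float(np.min(self.voxels)) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def max_value(self) -> int:
        """Largest representable intensity, ``2**bit_depth - 1``."""
        return 2**self.bit_depth - 1

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        """Copy of this volume with new voxel data, metadata unchanged."""
        return replace(self, voxels=voxels)


@dataclass
class VesselMask:
    """A boolean 3D grid marking vascular (or airway) voxels."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    source_channel: str = "OTHER"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask voxels must be 3D, got ndim={self.voxels.ndim}")
        if self.voxels.dtype != bool:
            self.voxels = self.voxels.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(np.count_nonzero(self.voxels))


def _check_dtype(arr: np.ndarray, path: object) -> None:
    if not any(np.issubdtype(arr.dtype, d) for d in _SUPPORTED_DTYPES):
        raise ValueError(
            f"unsupported dtype {arr.dtype} in {path}; expected 8/16-bit unsigned or float"
        )


def read_stack(
    path: str | os.PathLike | Sequence[str | os.PathLike],
    spacing: tuple[float, float, float],
    channel: str = "OTHER",
    bit_depth: int = 16,
) -> ImageVolume:
    """Read a multi-page TIFF, a glob pattern of 2D slices, or a NIfTI file.

    Slices are stacked in file/page order along ``z``.  Boolean-encoded masks
    (8-bit ``{0, 255}``) are returned as-is; use :func:`read_mask` to recover
    the boolean grid.

    Parameters
    ----------
    path : path, glob pattern, or sequence of paths
    spacing : (z, y, x) voxel edge lengths in µm
    channel : channel label
    bit_depth : nominal bit depth of the data

    Raises
    ------
    FileNotFoundError
        If no file (or no slice of a pattern) exists.
    ValueError
        On inconsistent slice shapes or unsupported dtype.
    """
    if isinstance(path, (str, os.PathLike)):
        p = Path(path)
        if p.exists():
            if p.suffix in (".nii",) or str(p).endswith(".nii.gz"):
                return _read_nifti(p, spacing, channel, bit_depth)
            arr = tifffile.imread(str(p))
            _check_dtype(arr, p)
            if arr.ndim == 2:
                arr = arr[np.newaxis]
            if arr.ndim != 3:
                raise ValueError(f"expected 2D/3D TIFF data in {p}, got ndim={arr.ndim}")
            return ImageVolume(arr, spacing, channel, bit_depth)
        # treat as a glob pattern of 2D slices
        files = sorted(glob.glob(str(path)))
        if not files:
            raise FileNotFoundError(f"no slices found for {path!s}")
    else:
        files = [str(f) for f in path]
        if not files:
            raise FileNotFoundError("no slices found (empty file list)")

    slices = []
    for f in files:
        sl = tifffile.imread(f)
        _check_dtype(sl, f)
        if sl.ndim != 2:
            raise ValueError(f"slice file {f} is not 2D (ndim={sl.ndim})")
        if slices and sl.shape != slices[0].shape:
            raise ValueError(
                f"inconsistent slice shapes: {slices[0].shape} vs {sl.shape} in {f}"
            )
        if slices and sl.dtype != slices[0].dtype:
            raise ValueError(f"inconsistent slice dtypes in {f}")
        slices.append(sl)
    return ImageVolume(np.stack(slices, axis=0), spacing, channel, bit_depth)


def _read_nifti(p: Path, spacing, channel, bit_depth) -> ImageVolume:
    import nibabel as nib

    img = nib.load(str(p))
    arr = np.asarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"expected 3D NIfTI in {p}, got ndim={arr.ndim}")
    # NIfTI stores (x, y, z); transpose to (z, y, x)
    arr = np.transpose(arr, (2, 1, 0))
    _check_dtype(arr, p)
    return ImageVolume(arr, spacing, channel, bit_depth)


def write_stack(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as a multi-page TIFF (or NIfTI by extension).

    Integer volumes round-trip bit-exactly through :func:`read_stack`.

    Raises
    ------
    FileNotFoundError
        If the parent directory does not exist.
    """
    p = Path(path)
    if not p.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {p.parent}")
    if p.suffix == ".nii" or str(p).endswith(".nii.gz"):
        import nibabel as nib

        arr = np.transpose(volume.voxels, (2, 1, 0))
        affine = np.diag([volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0])
        nib.save(nib.Nifti1Image(arr, affine), str(p))
        return
    tifffile.imwrite(str(p), volume.voxels, photometric="minisblack")


def write_mask(mask: VesselMask, path: str | os.PathLike) -> None:
    """Write a boolean mask as 8-bit {0, 255} TIFF (viewer-friendly encoding)."""
    p = Path(path)
    if not p.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {p.parent}")
    tifffile.imwrite(str(p), mask.voxels.astype(np.uint8) * 255, photometric="minisblack")


def read_mask(
    path: str | os.PathLike,
    spacing: tuple[float, float, float],
    source_channel: str = "OTHER",
) -> VesselMask:
    """Read a binary mask stored as 8-bit {0, 255} (any nonzero counts as true)."""
    vol = read_stack(path, spacing, channel="OTHER", bit_depth=8)
    return VesselMask(vol.voxels > 0, spacing, source_channel)


def flat_field_correct(volume: ImageVolume, flat: "ImageVolume | np.ndarray") -> ImageVolume:
    """Divide out a flat-field illumination image, preserving the intensity range.

    The flat field is normalized to unit mean before division, so a constant
    flat changes no intensity ratios.  The output is rescaled so its maximum
    does not exceed the input bit range.

    Parameters
    ----------
    volume : ImageVolume
    flat : ImageVolume or ndarray
        2D per-slice field or full 3D field; shape must broadcast against
        each slice (2D) or the whole volume (3D).

    Raises
    ------
    ValueError
        If the flat field contains non-positive values.
    """
    f = flat.voxels if isinstance(flat, ImageVolume) else np.asarray(flat)
    f = f.astype(np.float64)
    if np.any(f <= 0):
        raise ValueError("flat field must be strictly positive everywhere")
    f = f / f.mean()
    corrected = volume.voxels.astype(np.float64) / f  # broadcasts 2D over z
    peak = corrected.max()
    if peak > volume.max_value:
        corrected *= volume.max_value / peak
    out = corrected
    if np.issubdtype(volume.voxels.dtype, np.integer):
        out = np.floor(corrected + 0.5).astype(volume.voxels.dtype)
    return volume.with_voxels(out)
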