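"""Reading, writing and downscaling of 3D volumes.

Supported on-disk formats are multi-page grayscale TIFF (pages are z slices,
stored ``(z, y, x)``) and NIfTI-1 (stored ``(x, y, z)``).  In memory every
volume is ``(x, y, z)``; the transpose happens here and only here.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .types import (
    BinaryMask,
    DimensionalityError,
    ImageVolume,
    LabelVolume,
    LobusegError,
    ParameterError,
    VolumeReadError,
)

__all__ = ["read_volume", "write_volume", "read_labels", "downscale"]

logger = logging.getLogger(__name__)

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def _read_array(path: os.PathLike | str) -> tuple[np.ndarray, tuple | None]:
    """Return ``(data_xyz, spacing_from_header_or_None)``."""
    path = Path(path)
    if not path.exists():
        raise VolumeReadError(f"no such file: {path}")
    if _is_nifti(path):
        try:
            img = nib.load(str(path))
            data = np.asarray(img.dataobj)
        except Exception as exc:  # nibabel raises a zoo of error types
            raise VolumeReadError(f"cannot read NIfTI file {path}: {exc}") from exc
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        spacing = zooms if len(zooms) == 3 and all(z > 0 for z in zooms) else None
        return data, spacing
    try:
        data = tifffile.imread(str(path))
    except Exception as exc:
        raise VolumeReadError(f"cannot read TIFF file {path}: {exc}") from exc
    if data.ndim == 2:
        raise DimensionalityError(
            f"{path} holds a single 2D page; a 3D multi-page stack is required"
        )
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected 3 dimensions, got {data.ndim}")
    # TIFF pages arrive (z, y, x); flip to the in-memory (x, y, z) order.
    return np.ascontiguousarray(data.transpose(2, 1, 0)), None


def read_volume(path, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    """Read a 3D volume from a multi-page TIFF or NIfTI file.

    ``spacing`` is the voxel size (dx, dy, dz) in micrometres.  A positive
    spacing found in a NIfTI header overrides the argument.
    """
    data, header_spacing = _read_array(path)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D volume, got {data.ndim}D")
    if header_spacing is not None and header_spacing != (1.0, 1.0, 1.0):
        spacing = header_spacing
    return ImageVolume(data=data, spacing=spacing)


def read_labels(path, spacing=(1.0, 1.0, 1.0)) -> LabelVolume:
    """Read an integer label volume (same formats as :func:`read_volume`)."""
    vol = read_volume(path, spacing)
    return LabelVolume(data=np.rint(vol.data).astype(np.int64), spacing=vol.spacing)


def write_volume(vol, path) -> None:
    """Write an :class:`ImageVolume`/:class:`LabelVolume`/:class:`BinaryMask`.

    Format follows the file suffix (``.tif``/``.tiff`` or ``.nii``/``.nii.gz``).
    Label volumes are stored as the narrowest unsigned integer type that holds
    the maximum label; masks as uint8.
    """
    path = Path(path)
    if not path.parent.exists():
        raise VolumeReadError(f"parent directory does not exist: {path.parent}")
    data = np.asarray(vol.data)
    if isinstance(vol, LabelVolume):
        data = data.astype(np.min_scalar_type(max(int(data.max(initial=0)), 1)))
        if data.dtype.itemsize < 1 or data.dtype.kind != "u":
            data = data.astype(np.uint32)
    elif isinstance(vol, BinaryMask):
        data = data.astype(np.uint8)
    try:
        if _is_nifti(path):
            affine = np.diag(list(vol.spacing) + [1.0])
            affine[:3, 3] = vol.origin
            img = nib.Nifti1Image(data, affine)
            img.header.set_zooms(vol.spacing)
            nib.save(img, str(path))
        else:
            tifffile.imwrite(
                str(path),
                np.ascontiguousarray(data.transpose(2, 1, 0)),
                photometric="minisblack",
            )
    except LobusegError:
        raise
    except Exception as exc:
        raise VolumeReadError(f"cannot write {path}: {exc}") from exc


def downscale(vol: ImageVolume, factor) -> ImageVolume:
    """Block-mean reduction of a volume by integer factors per axis.

    Output spacing is the input spacing multiplied by the factor; trailing
    partial blocks are dropped.  Block averaging (rather than subsampling)
    preserves the intensity statistics of thin septa.
    """
    factor = tuple(int(f) for f in np.atleast_1d(factor).ravel())
    if len(factor) == 1:
        factor = factor * 3
    if len(factor) != 3 or any(f <= 0 for f in factor):
        raise ParameterError(f"downscale factor must be 3 positive integers, got {factor}")
    shape = vol.shape
    if any(s < f for s, f in zip(shape, factor)):
        raise DimensionalityError(
            f"volume shape {shape} smaller than downscale factor {factor}"
        )
    nx, ny, nz = (s // f for s, f in zip(shape, factor))
    fx, fy, fz = factor
    cropped = vol.data[: nx * fx, : ny * fy, : nz * fz].astype(np.float64)
    blocks = cropped.reshape(nx, fx, ny, fy, nz, fz)
    out = blocks.mean(axis=(1, 3, 5))
    spacing = tuple(s * f for s, f in zip(vol.spacing, factor))
    # new voxel centers sit at the mean position of their source block
    origin = tuple(
        o + (f - 1) / 2.0 * s for o, s, f in zip(vol.origin, vol.spacing, factor)
    )
    return ImageVolume(data=out, spacing=spacing, origin=origin)
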