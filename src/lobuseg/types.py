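"""Volumetric containers with physical voxel spacing, and the package's error taxonomy.

All volumes are indexed ``data[i, j, k]`` along the (x, y, z) axes.  The
physical coordinate of the center of voxel ``(i, j, k)`` is
``origin + (i * dx, j * dy, k * dz)`` with ``spacing = (dx, dy, dz)`` in
micrometres.  Axial (z) sampling of cleared-tissue confocal stacks is
typically coarser than in-plane sampling, so spacing is anisotropic
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "LabelVolume",
    "LobusegError",
    "VolumeReadError",
    "DimensionalityError",
    "ParameterError",
    "DegenerateHistogramError",
    "EmptySLAError",
    "NoSeedError",
    "ConsistencyError",
    "MissingLabelError",
    "PlacementError",
]


class LobusegError(Exception):
    """Base class for all errors raised by lobuseg."""


class VolumeReadError(LobusegError):
    """A volume file could not be read or written."""


class DimensionalityError(LobusegError):
    """Input does not have the required shape/dimensionality."""


class ParameterError(LobusegError):
    """A parameter value is outside its valid domain."""


class DegenerateHistogramError(LobusegError):
    """Automatic thresholding failed because the intensity histogram is flat."""


class EmptySLAError(LobusegError):
    """Core/periphery separation produced an empty segmentable region."""


class NoSeedError(LobusegError):
    """No watershed seed survived thresholding and size filtering."""


class ConsistencyError(LobusegError):
    """Mutually inconsistent inputs (shapes, masks, seed placement...)."""


class MissingLabelError(LobusegError):
    """A requested label is absent from the label volume."""


class PlacementError(LobusegError):
    """The phantom generator could not place the requested geometry."""


def _as_triple(value, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(value).ravel())
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ParameterError(f"{name} must have 3 components, got {value!r}")
    return t


@dataclass
class _Volume:
    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D array, got {self.data.ndim} dimensions"
            )
        if min(self.data.shape) < 1:
            raise DimensionalityError("every dimension must have extent >= 1")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing components must be > 0, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def same_grid(self, other: "_Volume") -> bool:
        return self.shape == other.shape


@dataclass
class ImageVolume(_Volume):
    """3D scalar intensity field (arbitrary units) on an anisotropic grid."""

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.number):
            raise ParameterError(f"intensity data must be numeric, got {self.data.dtype}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ParameterError("intensities must be finite")


@dataclass
class BinaryMask(_Volume):
    """3D boolean field on the same grid as the volume it derives from."""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        super().__post_init__()

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelVolume(_Volume):
    """3D integer field; 0 is background, k > 0 identifies subunit k.

    Labels need not be consecutive (graph merging leaves gaps).
    """

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.bool_):
                self.data = self.data.astype(np.int32)
            else:
                as_int = self.data.astype(np.int64)
                if not np.array_equal(as_int, self.data):
                    raise ParameterError("labels must be integers")
                self.data = as_int
        super().__post_init__()
        if self.data.size and self.data.min() < 0:
            raise ParameterError("labels must be >= 0")

    def labels(self) -> np.ndarray:
        """Sorted array of positive labels present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]
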