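"""Core spatial containers: intensity volumes and binary masks on a voxel grid.

All imaging computation in the package operates on :class:`VolumeGrid`, a 3D
scalar intensity field with physical voxel spacing in micrometres.  The axis
convention follows the imaging setup: axis 0 is x (medio-lateral), axis 1 is y
(rostro-caudal), axis 2 is z (dorsal to ventral, the optical axis).  Confocal
stacks are acquired anisotropically (natively 1 x 1 x 2 um), so spacing is
carried explicitly and all physical quantities are computed from it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError

Spacing = tuple[float, float, float]

#: native confocal voxel spacing in micrometres (x, y, z)
NATIVE_SPACING: Spacing = (1.0, 1.0, 2.0)


@dataclass
class VolumeGrid:
    """A 3D scalar intensity field with physical voxel spacing.

    Parameters
    ----------
    data
        3D array of intensities.  Stored as float64 internally regardless of
        the on-disk bit depth.  All values must be finite and non-negative.
    spacing
        Voxel spacing ``(sx, sy, sz)`` in micrometres; strictly positive.
    """

    data: np.ndarray
    spacing: Spacing = NATIVE_SPACING

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError(f"volume must be 3D with each dim >= 1, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume intensities must be finite")
        if arr.size and arr.min() < 0:
            raise ValueError("volume intensities must be >= 0")
        self.data = arr
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        self.spacing = sp  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (um) spanned by voxel centres along each axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """A new volume on the same grid with different intensities."""
        return VolumeGrid(data, self.spacing)

    def congruent(self, other: "VolumeGrid | BinaryMask", rtol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing, rtol=rtol)

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to physical um coordinates."""
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def physical_to_index(self, pos: np.ndarray) -> np.ndarray:
        return np.asarray(pos, dtype=float) / np.asarray(self.spacing)


@dataclass
class BinaryMask:
    """A boolean field on the same kind of grid as :class:`VolumeGrid`.

    Used for brain masks, ROIs and thresholded expression footprints.
    """

    data: np.ndarray
    spacing: Spacing = NATIVE_SPACING

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError(f"mask must be 3D with each dim >= 1, got shape {arr.shape}")
        self.data = arr.astype(bool)
        sp = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.spacing = sp  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        """Number of true voxels."""
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in um^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def congruent(self, other: "VolumeGrid | BinaryMask", rtol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing, rtol=rtol)

    def union(self, other: "BinaryMask") -> "BinaryMask":
        require_congruent(self, other)
        return BinaryMask(self.data | other.data, self.spacing)

    def intersection(self, other: "BinaryMask") -> "BinaryMask":
        require_congruent(self, other)
        return BinaryMask(self.data & other.data, self.spacing)


def require_congruent(*grids: VolumeGrid | BinaryMask) -> None:
    """Raise :class:`GridMismatchError` unless all grids share shape and spacing."""
    first = grids[0]
    for g in grids[1:]:
        if not first.congruent(g):
            raise GridMismatchError(
                f"grids differ: shape {first.shape} spacing {first.spacing} vs "
                f"shape {g.shape} spacing {g.spacing}"
            )


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap coefficient 2|A∩B| / (|A|+|B|) between two masks."""
    aa = a.data if isinstance(a, BinaryMask) else np.asarray(a, bool)
    bb = b.data if isinstance(b, BinaryMask) else np.asarray(b, bool)
    denom = aa.sum() + bb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(aa, bb).sum() / denom
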