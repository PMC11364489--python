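"""Volumetric grids and structure sets in DICOM patient coordinates.

Everything in this package lives on a :class:`VolumeGrid`: a 3-D scalar
field (HU, Gy, or unitless weight) with explicit physical geometry in the
DICOM patient coordinate system (LPS, millimetres).  Conventions, used
consistently everywhere:

* voxel-center convention -- index ``(i, j, k)`` refers to the *center* of
  that voxel;
* 0-based indices, array axis order ``(x, y, z)``;
* world position of index ``(i, j, k)`` is
  ``origin + axes @ (spacing * (i, j, k))``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "StructureRole",
    "StructureSet",
    "resample_to",
]

#: Background fill values used by every resampler/reader in the package.
BACKGROUND_HU = -1000.0
BACKGROUND_DOSE = 0.0


class StructureRole(str, enum.Enum):
    """Clinical role of a delineated structure."""

    TARGET_PTV = "TARGET_PTV"
    TARGET_GTV = "TARGET_GTV"
    OAR = "OAR"
    RING = "RING"
    BODY = "BODY"


@dataclass
class VolumeGrid:
    """A 3-D scalar field with physical geometry.

    Parameters
    ----------
    values
        Scalar per voxel, shape ``(nx, ny, nz)``.  Units depend on context
        (HU for CT, Gy for dose, unitless for masks/weights).
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    spacing
        Voxel pitch (mm) along each grid axis; strictly positive.
    axes
        3x3 direction-cosine matrix whose *columns* are the world
        directions of the grid axes; orthonormal with determinant +1.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=1e-6):
            raise ValueError("axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("axes must be right-handed (determinant +1)")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def indices_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) indices ``(..., 3)`` to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return self.origin + (self.spacing * ijk) @ self.axes.T

    def world_to_indices(self, xyz: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`indices_to_world` (continuous indices)."""
        xyz = np.asarray(xyz, dtype=float)
        return ((xyz - self.origin) @ self.axes) / self.spacing

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape, dtype=float)
        ijk = np.stack(idx, axis=-1)
        return self.indices_to_world(ijk)

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.axes, other.axes, atol=tol)
        )

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        """A new grid with identical geometry and the given values."""
        return VolumeGrid(np.asarray(values), self.origin.copy(), self.spacing.copy(), self.axes.copy())

    def copy(self) -> "VolumeGrid":
        return self.with_values(self.values.copy())


@dataclass
class StructureSet:
    """Named binary masks co-registered to a reference grid."""

    grid: VolumeGrid
    masks: Dict[str, np.ndarray] = field(default_factory=dict)
    roles: Dict[str, StructureRole] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mask in self.masks.items():
            self._check(name, mask)

    def _check(self, name: str, mask: np.ndarray) -> None:
        if mask.dtype != bool:
            raise ValueError(f"mask {name!r} must be boolean, got {mask.dtype}")
        if mask.shape != self.grid.shape:
            raise ValueError(
                f"mask {name!r} shape {mask.shape} != grid shape {self.grid.shape}"
            )

    def add(self, name: str, mask: np.ndarray, role: StructureRole) -> None:
        mask = np.asarray(mask)
        self._check(name, mask)
        self.masks[name] = mask
        self.roles[name] = StructureRole(role)

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def names_with_role(self, role: StructureRole) -> list:
        return [n for n, r in self.roles.items() if r == role]

    @property
    def target(self) -> np.ndarray:
        """The planning target mask (PTV preferred, else GTV)."""
        for role in (StructureRole.TARGET_PTV, StructureRole.TARGET_GTV):
            names = self.names_with_role(role)
            if names:
                return self.masks[names[0]]
        raise KeyError("structure set has no target (PTV/GTV) structure")

    def has_target(self) -> bool:
        try:
            self.target
        except KeyError:
            return False
        return True


def resample_to(
    src: VolumeGrid,
    ref: VolumeGrid,
    mode: str = "linear",
    background: float = 0.0,
) -> VolumeGrid:
    """Resample ``src`` onto the geometry of ``ref``.

    ``mode`` is ``"linear"`` (trilinear; CT and dose) or ``"nearest"``
    (masks).  Out-of-bounds voxels are filled with ``background``
    (-1000 HU for CT, 0 for dose and masks, by this package's convention).
    This is a total function: any pair of grids is accepted.
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    if src.same_geometry(ref):
        return ref.with_values(src.values.copy())
    centers = ref.voxel_centers().reshape(-1, 3)
    idx = src.world_to_indices(centers)
    was_bool = src.values.dtype == bool
    vals = ndimage.map_coordinates(
        src.values.astype(float),
        idx.T,
        order=1 if mode == "linear" else 0,
        mode="constant",
        cval=float(background),
    ).reshape(ref.shape)
    if was_bool:
        vals = vals > 0.5
    return ref.with_values(vals)


def resample_mask_to(mask: np.ndarray, src_grid: VolumeGrid, ref: VolumeGrid) -> np.ndarray:
    """Nearest-neighbour resampling of a boolean mask between grids."""
    out = resample_to(src_grid.with_values(mask), ref, mode="nearest", background=0.0)
    return out.values.astype(bool)
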