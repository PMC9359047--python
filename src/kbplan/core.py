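"""Core voxel-grid containers shared by every stage of the pipeline.

All volumes live on axis-aligned voxel grids in DICOM patient coordinates
(LPS, millimetres).  Array axis order is (x, y, z): the world coordinate of
voxel index ``(i, j, k)`` is ``origin + index * spacing`` componentwise,
where ``origin`` is the position of the *center* of voxel ``(0, 0, 0)``.
Voxel membership everywhere in the package is decided at voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical structure vocabulary used throughout the package.
CANONICAL_STRUCTURES = (
    "PTV",
    "rectum",
    "bladder",
    "femoral_head_L",
    "femoral_head_R",
    "small_intestine",
    "spinal_cord",
)


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice in patient (LPS) coordinates.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels (M, N, L) along (x, y, z).
    spacing : tuple of float
        Voxel spacing in mm along each axis; all entries > 0.
    origin : tuple of float
        mm position of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("grid shape, spacing and origin must be length-3")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to mm coordinates."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Map mm coordinates to fractional voxel indices."""
        return (np.asarray(world) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def extent_mm(self) -> list[tuple[float, float]]:
        """Per-axis (low, high) mm bounds of the voxel-center lattice."""
        return [
            (self.origin[a], self.origin[a] + self.spacing[a] * (self.shape[a] - 1))
            for a in range(3)
        ]


@dataclass
class BinaryMask:
    """3D boolean occupancy of one structure on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.values.dtype != bool:
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be 0/1")
            self.values = self.values.astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cc

    def is_empty(self) -> bool:
        return not self.values.any()

    def bounding_box(self) -> tuple[tuple[int, int], ...] | None:
        """Per-axis half-open index bounds of the occupied region, or None."""
        if self.is_empty():
            return None
        bounds = []
        for axis in range(3):
            proj = self.values.any(axis=tuple(a for a in range(3) if a != axis))
            idx = np.flatnonzero(proj)
            bounds.append((int(idx[0]), int(idx[-1]) + 1))
        return tuple(bounds)

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.grid, self.values.copy())


@dataclass
class StructureSet:
    """Named structure masks of one patient, all on a single shared grid."""

    patient_id: str
    structures: dict[str, BinaryMask] = field(default_factory=dict)
    require_ptv: bool = True

    def __post_init__(self) -> None:
        grids = {m.grid for m in self.structures.values()}
        if len(grids) > 1:
            raise ValueError("all structures must share one VoxelGrid")
        unknown = set(self.structures) - set(CANONICAL_STRUCTURES)
        if unknown:
            raise ValueError(f"non-canonical structure names: {sorted(unknown)}")
        if self.require_ptv and "PTV" not in self.structures:
            raise ValueError(f"patient {self.patient_id!r}: PTV structure is required")

    @property
    def grid(self) -> VoxelGrid:
        return next(iter(self.structures.values())).grid

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    def __getitem__(self, name: str) -> BinaryMask:
        return self.structures[name]


@dataclass
class DoseGrid:
    """Absorbed dose in Gy on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.shape:
            raise ValueError(
                f"dose shape {self.dose.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.dose)):
            raise ValueError("dose must be finite everywhere")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")
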