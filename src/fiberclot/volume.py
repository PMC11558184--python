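"""Voxel-volume container shared by the phantom generator and the quantification pipeline.

Axis convention (fixed across the package): axis 0 is the chamber width x,
axis 1 the height y (the rod axis), axis 2 the flow direction z with the
inlet at index 0.  Voxels are isotropic; ``voxel_size`` is in micrometres and
``origin`` records, in mm, where the grid's (0, 0, 0) corner sits relative to
the chamber's inlet/bottom/left corner, so cropped volumes keep track of true
distances from the inlet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .geometry import ChamberSpec, FlowCondition

__all__ = ["VoxelVolume", "ClotSegmentation"]

AXIS_WIDTH, AXIS_HEIGHT, AXIS_FLOW = 0, 1, 2


@dataclass
class VoxelVolume:
    """Axis-aligned 3D scalar or binary grid with physical metadata."""

    grid: np.ndarray
    voxel_size: float  # um, isotropic
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got shape {self.grid.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical extent along (x, y, z) in mm."""
        return tuple(n * self.voxel_size_mm for n in self.grid.shape)  # type: ignore[return-value]

    @property
    def is_binary(self) -> bool:
        return self.grid.dtype == bool

    def binary_volume_mm3(self) -> float:
        """Total volume of True voxels, mm^3 (binary grids only)."""
        if not self.is_binary:
            raise TypeError("binary_volume_mm3 requires a boolean grid")
        return float(self.grid.sum()) * self.voxel_volume_mm3

    def same_geometry_as(self, other: "VoxelVolume") -> bool:
        return (
            self.grid.shape == other.grid.shape
            and self.voxel_size == other.voxel_size
            and np.allclose(self.origin, other.origin)
        )

    def with_grid(self, grid: np.ndarray) -> "VoxelVolume":
        """Copy of the metadata wrapping a new grid of identical shape."""
        if grid.shape != self.grid.shape:
            raise ValueError("replacement grid must have the same shape")
        return replace(self, grid=grid)

    def flow_coordinates_mm(self) -> np.ndarray:
        """Voxel-center z coordinates measured from the true inlet, mm."""
        nz = self.grid.shape[AXIS_FLOW]
        return self.origin[AXIS_FLOW] + (np.arange(nz) + 0.5) * self.voxel_size_mm


@dataclass
class ClotSegmentation:
    """Binary clot volume plus its experimental provenance.

    The clot mask is disjoint from the chamber solid (rods + walls) by
    construction (simulator) or by mask subtraction (image pipeline).
    ``growth_fraction`` optionally carries the simulator's per-step clot
    fraction of total chamber volume, used to couple clot growth to the
    resistance model.
    """

    clot: VoxelVolume
    spec: ChamberSpec
    condition: FlowCondition | None = None
    donor_id: Any = None
    replicate: int | None = None
    provenance: str | int | None = None
    growth_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.clot.is_binary:
            raise TypeError("clot volume must be a binary mask")

    @property
    def clot_volume_mm3(self) -> float:
        return self.clot.binary_volume_mm3()
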