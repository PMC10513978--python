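"""Voxel grid with a fixed patient-oriented axis convention.

Axes follow the convention used throughout the package:

* ``x`` — patient left (+) / right (−)
* ``y`` — anterior (+) / posterior (−)
* ``z`` — superior (+) / inferior (−)

Arrays are indexed ``[ix, iy, iz]`` (0-based) and world coordinates are in
millimetres, with the grid centred on the world origin.  Voxel cells are
half-open, so every world point inside the field of view maps to exactly one
voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoxelGrid", "DEFAULT_SPECT_GRID"]


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice: shape in voxels and isotropic-or-not spacing in mm."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(shape) != 3 or len(spacing) != 3:
            raise ValueError("VoxelGrid requires 3 shape and 3 spacing entries")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge length of the field of view along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    def centers(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along ``axis``, grid centred at 0."""
        n = self.shape[axis]
        s = self.spacing_mm[axis]
        return (np.arange(n) - (n - 1) / 2.0) * s

    def coordinate_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable centre-coordinate arrays (X, Y, Z) of shapes
        (nx,1,1), (1,ny,1), (1,1,nz)."""
        x = self.centers(0)[:, None, None]
        y = self.centers(1)[None, :, None]
        z = self.centers(2)[None, None, :]
        return x, y, z

    def affine(self) -> np.ndarray:
        """RAS+ affine for NIfTI export.

        Package axes are (Left+, Anterior+, Superior+); RAS flips the first
        axis.  Translation places the grid centre at the world origin.
        """
        sx, sy, sz = self.spacing_mm
        aff = np.diag([-sx, sy, sz, 1.0])
        for axis, sign_spacing in enumerate((-sx, sy, sz)):
            n = self.shape[axis]
            aff[axis, 3] = -sign_spacing * (n - 1) / 2.0
        return aff

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing_mm, other.spacing_mm
        )


#: Reconstructed-SPECT grid used by default: 128^3 voxels of 3.3 mm.
DEFAULT_SPECT_GRID = VoxelGrid(shape=(128, 128, 128), spacing_mm=(3.3, 3.3, 3.3))
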