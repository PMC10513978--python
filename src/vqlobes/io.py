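"""NIfTI-1 reading/writing for phantom and simulation volumes."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import VoxelGrid

__all__ = ["save_volume", "load_volume"]


def save_volume(volume: np.ndarray, grid: VoxelGrid, path: str | Path,
                labels: bool = False) -> Path:
    """Write a volume as NIfTI-1 (.nii or .nii.gz) with an RAS-consistent
    affine; label volumes as uint8, everything else as float32."""
    path = Path(path)
    dtype = np.uint8 if labels else np.float32
    img = nib.Nifti1Image(np.asarray(volume).astype(dtype), grid.affine())
    img.header.set_zooms(grid.spacing_mm)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    """Load a NIfTI volume and recover its grid from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, VoxelGrid(shape=tuple(data.shape), spacing_mm=zooms)
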