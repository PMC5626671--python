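"""Reading and writing voxel grids (NIfTI via nibabel, MetaImage via
SimpleITK), with mm spacing and origin preserved."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .phantoms import VoxelGrid

__all__ = ["save_volume", "load_volume"]


def save_volume(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a grid as .nii/.nii.gz or .mhd (+.raw), recording mm spacing
    and the corner origin."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag([*grid.voxel_size, 1.0])
        affine[:3, 3] = grid.origin + grid.voxel_size / 2.0  # centre of voxel 0
        nib.save(nib.Nifti1Image(np.asarray(grid.values, dtype=np.float32), affine), path)
        return path
    if path.suffix == ".mhd":
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(np.transpose(grid.values, (2, 1, 0)).astype(np.float32))
        )
        img.SetSpacing(tuple(float(s) for s in grid.voxel_size))
        img.SetOrigin(tuple(float(o + s / 2.0) for o, s in zip(grid.origin, grid.voxel_size)))
        sitk.WriteImage(img, str(path))
        return path
    raise ValueError(f"unsupported volume format: {path.name}")


def load_volume(path: str | Path) -> VoxelGrid:
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        affine = img.affine
        voxel_size = np.abs(np.diag(affine)[:3])
        center0 = affine[:3, 3]
        return VoxelGrid(
            np.asarray(img.dataobj, dtype=float), voxel_size,
            center0 - voxel_size / 2.0,
        )
    if path.suffix == ".mhd":
        img = sitk.ReadImage(str(path))
        values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0)).astype(float)
        voxel_size = np.asarray(img.GetSpacing(), dtype=float)
        center0 = np.asarray(img.GetOrigin(), dtype=float)
        return VoxelGrid(values, voxel_size, center0 - voxel_size / 2.0)
    raise ValueError(f"unsupported volume format: {path.name}")
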