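"""Analysis-space geometry and the subjects-by-voxels data container.

Source-based morphometry works on a fixed 3-D sampling grid (a brain-shaped
mask inside a rectangular voxel lattice with a voxel-to-world affine, as in
NIfTI images registered to a standard space).  Every stage of the pipeline
passes vectors of in-mask voxel values around; :class:`VolumeGrid` owns the
mapping between those flat vectors and 3-D volumes, and :class:`DataMatrix`
stacks one such vector per subject.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised for impossible or inconsistent configuration requests."""


@dataclasses.dataclass(frozen=True)
class VolumeGrid:
    """Geometry of the analysis space.

    Parameters
    ----------
    shape
        Voxels per axis (i, j, k); each entry must be >= 4.
    voxel_size
        Voxel edge length in mm per axis; all entries positive.
    affine
        4x4 voxel-index -> world-mm map (NIfTI convention).
    mask
        Boolean volume of analysed ("in-brain") voxels, same shape.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if len(shape) != 3 or any(s < 4 for s in shape):
            raise ConfigurationError(f"grid shape must be 3 axes of >= 4 voxels, got {shape}")
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ConfigurationError(f"voxel sizes must be positive, got {vs}")
        if self.affine.shape != (4, 4):
            raise ConfigurationError("affine must be 4x4")
        if self.mask.shape != shape:
            raise ConfigurationError(
                f"mask shape {self.mask.shape} does not match grid shape {shape}"
            )
        if not self.mask.any():
            raise ConfigurationError("mask must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels (columns of every DataMatrix on this grid)."""
        return int(self.mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place a flat in-mask vector back into a full 3-D volume."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise ConfigurationError(
                f"expected {self.n_voxels} in-mask values, got shape {values.shape}"
            )
        vol = np.full(self.shape, fill, dtype=float)
        vol[self.mask] = values
        return vol

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Flatten a 3-D volume to the in-mask voxel vector (C order)."""
        volume = np.asarray(volume, dtype=float)
        if volume.shape != self.shape:
            raise ConfigurationError(
                f"volume shape {volume.shape} does not match grid {self.shape}"
            )
        return volume[self.mask]

    def world_coordinates(self, ijk) -> np.ndarray:
        """World (mm) coordinate of one voxel index triple via the affine."""
        homog = np.append(np.asarray(ijk, dtype=float), 1.0)
        return (self.affine @ homog)[:3]


def default_grid(
    shape: tuple[int, int, int] = (24, 28, 24),
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    mask_axis_fraction: float = 0.46,
) -> VolumeGrid:
    """Desk-scale analysis grid with an ellipsoidal brain-like mask.

    The default 24x28x24 lattice at 3 mm with an ellipsoid covering ~46% of
    each semi-axis yields roughly 6-8k in-mask voxels — small enough for an
    ICA run in seconds while keeping genuine 3-D cluster morphology.  The
    affine centres the grid on the world origin so peak coordinates read
    like standard-space mm.
    """
    shape = tuple(int(s) for s in shape)
    vs = tuple(float(v) for v in voxel_size_mm)
    centre = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vs)
    affine[:3, 3] = -centre * np.asarray(vs)
    idx = np.indices(shape).astype(float)
    semi = np.asarray(shape) * mask_axis_fraction
    dist2 = sum(((idx[a] - centre[a]) / semi[a]) ** 2 for a in range(3))
    mask = dist2 <= 1.0
    return VolumeGrid(shape=shape, voxel_size=vs, affine=affine, mask=mask)


@dataclasses.dataclass
class DataMatrix:
    """Subjects-by-voxels gray-matter matrix over in-mask voxels.

    Row order matches the covariate table ``subjects`` (columns at least
    ``id``, ``age``, ``sex``, ``site``); columns are the grid's in-mask
    voxels in C order.
    """

    values: np.ndarray
    grid: VolumeGrid
    subjects: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("DataMatrix values must be 2-D (subjects x voxels)")
        if self.values.shape[1] != self.grid.n_voxels:
            raise ConfigurationError(
                f"matrix has {self.values.shape[1]} columns but mask has "
                f"{self.grid.n_voxels} voxels"
            )
        if len(self.subjects) != self.values.shape[0]:
            raise ConfigurationError(
                f"{self.values.shape[0]} rows but {len(self.subjects)} covariate rows"
            )
        if not np.isfinite(self.values).all():
            raise ConfigurationError("DataMatrix contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


def save_volume(grid: VolumeGrid, volume: np.ndarray, path: str | Path) -> Path:
    """Write one 3-D volume as NIfTI-1 using the grid's affine."""
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), grid.affine)
    img.header.set_zooms(grid.voxel_size)
    path = Path(path)
    nib.save(img, str(path))
    return path


def save_mask(grid: VolumeGrid, path: str | Path) -> Path:
    img = nib.Nifti1Image(grid.mask.astype(np.uint8), grid.affine)
    img.header.set_zooms(grid.voxel_size)
    path = Path(path)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def grid_from_nifti_mask(path: str | Path) -> VolumeGrid:
    """Reconstruct a VolumeGrid from a binary-mask NIfTI file."""
    img = nib.load(str(path))
    mask = np.asarray(img.get_fdata()) > 0.5
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(shape=mask.shape, voxel_size=zooms, affine=np.asarray(img.affine), mask=mask)
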