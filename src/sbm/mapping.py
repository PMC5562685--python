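"""Thresholded z-maps and 3-D cluster tables for spatial components.

Each source row is standardized over the in-mask voxels (z-scored),
embedded back into the 3-D grid, thresholded (default z >= 3, positive tail
— the covariance patterns of interest load positively), and decomposed into
connected clusters whose voxel counts, mm^3 sizes and world-coordinate
peaks are tabulated.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from .ica import Decomposition
from .volume import ConfigurationError, VolumeGrid

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclasses.dataclass
class ZMapSet:
    """Per-component z volumes on the grid (zeros outside the mask)."""

    zmaps: np.ndarray          # K x V in-mask z values
    grid: VolumeGrid

    @property
    def n_components(self) -> int:
        return self.zmaps.shape[0]

    def volume(self, k: int) -> np.ndarray:
        return self.grid.embed(self.zmaps[k])


@dataclasses.dataclass(frozen=True)
class ClusterRecord:
    """One suprathreshold connected cluster of a component's z-map."""

    component: int
    label: int
    n_voxels: int
    size_mm3: float
    peak_ijk: tuple[int, int, int]
    peak_xyz_mm: tuple[float, float, float]
    peak_z: float
    sign: int = 1


def zscore_sources(decomp: Decomposition, grid: VolumeGrid) -> ZMapSet:
    """Standardize every source row over in-mask voxels.

    Affine-invariant: a*s + b (a > 0) gives the identical z-map.  Raises if
    a source has zero variance, naming the component.
    """
    S = np.asarray(decomp.sources, dtype=float)
    if S.shape[1] != grid.n_voxels:
        raise ConfigurationError("sources are not defined on this grid's mask")
    sd = S.std(axis=1, ddof=0)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ConfigurationError(f"zero-variance source(s): components {bad.tolist()}")
    Z = (S - S.mean(axis=1, keepdims=True)) / sd[:, None]
    return ZMapSet(zmaps=Z, grid=grid)


def extract_clusters(
    zvolume: np.ndarray,
    grid: VolumeGrid,
    threshold: float = 3.0,
    connectivity: int = 26,
    min_voxels: int = 0,
    component: int = 0,
    tail: str = "positive",
) -> list[ClusterRecord]:
    """Connected suprathreshold clusters with sizes and world-space peaks.

    Clusters are connected components of ``{z >= threshold}`` (within the
    mask) under 6/18/26-connectivity; with ``tail="both"`` the set
    ``{z <= -threshold}`` is labelled separately and reported with
    ``sign=-1``.  Peak = in-cluster argmax of z, ties broken by smallest
    linear (C-order) index; its world coordinate comes from the grid
    affine.  Output sorted by size descending, then peak z descending;
    clusters below ``min_voxels`` are dropped.  An empty suprathreshold set
    yields an empty list.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ConfigurationError("connectivity must be 6, 18 or 26")
    if tail not in ("positive", "both"):
        raise ConfigurationError("tail must be 'positive' or 'both'")
    z = np.asarray(zvolume, dtype=float)
    if z.shape != grid.shape:
        raise ConfigurationError("z volume does not match grid shape")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    records: list[ClusterRecord] = []
    tails = [(1, z)] if tail == "positive" else [(1, z), (-1, -z)]
    for sign, zz in tails:
        supra = (zz >= threshold) & grid.mask
        labels, n_lab = ndimage.label(supra, structure=structure)
        flat_lab = labels.ravel()
        flat_z = zz.ravel()
        for lab in range(1, n_lab + 1):
            voxels = np.flatnonzero(flat_lab == lab)
            if voxels.size < max(min_voxels, 1):
                continue
            vals = flat_z[voxels]
            peak_flat = int(voxels[int(np.argmax(vals))])
            ijk = np.unravel_index(peak_flat, grid.shape)
            records.append(
                ClusterRecord(
                    component=component,
                    label=lab * sign,
                    n_voxels=int(voxels.size),
                    size_mm3=float(voxels.size * grid.voxel_volume_mm3),
                    peak_ijk=tuple(int(i) for i in ijk),
                    peak_xyz_mm=tuple(float(c) for c in grid.world_coordinates(ijk)),
                    peak_z=float(sign * zz[ijk]),
                    sign=sign,
                )
            )
    records.sort(key=lambda r: (-r.n_voxels, -abs(r.peak_z), r.label))
    return records


def cluster_table(
    zset: ZMapSet,
    threshold: float = 3.0,
    connectivity: int = 26,
    min_voxels: int = 0,
    tail: str = "positive",
) -> pd.DataFrame:
    """Tabulate clusters for every component of a ZMapSet."""
    rows = []
    for k in range(zset.n_components):
        for rec in extract_clusters(
            zset.volume(k), zset.grid, threshold=threshold,
            connectivity=connectivity, min_voxels=min_voxels,
            component=k, tail=tail,
        ):
            rows.append(
                {
                    "component": rec.component,
                    "peak_x_mm": rec.peak_xyz_mm[0],
                    "peak_y_mm": rec.peak_xyz_mm[1],
                    "peak_z_mm": rec.peak_xyz_mm[2],
                    "peak_z": rec.peak_z,
                    "size_mm3": rec.size_mm3,
                    "n_voxels": rec.n_voxels,
                    "sign": rec.sign,
                }
            )
    columns = ["component", "peak_x_mm", "peak_y_mm", "peak_z_mm",
               "peak_z", "size_mm3", "n_voxels", "sign"]
    return pd.DataFrame(rows, columns=columns)
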