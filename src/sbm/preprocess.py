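"""Spatial smoothing and voxelwise confound removal.

The pipeline smooths each subject's gray-matter volume with a Gaussian
kernel (stated as FWHM in mm, converted per-axis to voxel sigmas) and then
removes scanner-site and sex effects voxel by voxel with OLS, keeping the
residuals plus the per-voxel grand mean.  Residuals are invariant to the
choice of full-rank dummy coding, which is why the design uses intercept +
(L-1) reference-coded site indicators + one sex indicator even though the
sites could equally be coded with L indicators and no intercept.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import ConfigurationError, DataMatrix, VolumeGrid

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma (mm) for a kernel stated as full width at half maximum."""
    if fwhm_mm <= 0:
        raise ValueError(f"FWHM must be positive, got {fwhm_mm}")
    return float(fwhm_mm) * FWHM_TO_SIGMA


def smooth_volume(volume: np.ndarray, grid: VolumeGrid, fwhm_mm: float) -> np.ndarray:
    """Separable Gaussian smoothing with per-axis voxel sigmas.

    Anisotropic voxels are handled by dividing the mm sigma by each axis's
    voxel size.  A kernel narrower than half a voxel is a no-op (returned
    unchanged with a warning) — it would be below the sampling resolution.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape != grid.shape:
        raise ConfigurationError(
            f"volume shape {volume.shape} does not match grid {grid.shape}"
        )
    if fwhm_mm < min(grid.voxel_size) / 2.0:
        warnings.warn(
            f"FWHM {fwhm_mm} mm is below half a voxel; smoothing skipped",
            stacklevel=2,
        )
        return volume.copy()
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / v for v in grid.voxel_size]
    # reflect: constants pass through unchanged and interior mass is conserved
    return ndimage.gaussian_filter(volume, sigma=sigma_vox, mode="reflect")


def smooth_matrix(dm: DataMatrix, fwhm_mm: float) -> DataMatrix:
    """Smooth every subject's volume (embed -> filter -> re-extract)."""
    out = np.empty_like(dm.values)
    for i in range(dm.n_subjects):
        vol = dm.grid.embed(dm.values[i])
        out[i] = dm.grid.extract(smooth_volume(vol, dm.grid, fwhm_mm))
    return DataMatrix(values=out, grid=dm.grid, subjects=dm.subjects)


@dataclasses.dataclass
class ConfoundDesign:
    """Design matrix for nuisance removal: intercept, site dummies, sex dummy."""

    matrix: np.ndarray
    columns: tuple[str, ...]
    coding: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ConfigurationError(
                f"confound design is rank deficient; columns: {self.columns}"
            )

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def build_confound_design(cohort: pd.DataFrame, coding: str = "reference") -> ConfoundDesign:
    """Intercept + (L-1) site indicators + 1 sex indicator.

    Site levels observed in the cohort are sorted; the first is the
    reference.  Levels with zero subjects are simply absent.  If fewer than
    two site levels are present the site columns are dropped with a warning;
    likewise for sex.  ``coding="sum"`` uses sum-to-zero site contrasts
    instead — residuals are identical for any full-rank coding (tested).
    """
    n = len(cohort)
    cols = [np.ones(n)]
    names = ["intercept"]
    site_levels = sorted(cohort["site"].unique())
    if len(site_levels) < 2:
        warnings.warn("only one site level present; site columns dropped", stacklevel=2)
    elif coding == "reference":
        for lvl in site_levels[1:]:
            cols.append((cohort["site"] == lvl).to_numpy(dtype=float))
            names.append(f"site[{lvl}]")
    elif coding == "sum":
        ref = site_levels[-1]
        for lvl in site_levels[:-1]:
            col = (cohort["site"] == lvl).to_numpy(dtype=float)
            col = col - (cohort["site"] == ref).to_numpy(dtype=float)
            cols.append(col)
            names.append(f"site.sum[{lvl}]")
    else:
        raise ConfigurationError(f"unknown coding {coding!r}")
    sex_levels = sorted(cohort["sex"].unique())
    if len(sex_levels) < 2:
        warnings.warn("only one sex level present; sex column dropped", stacklevel=2)
    else:
        cols.append((cohort["sex"] == sex_levels[-1]).to_numpy(dtype=float))
        names.append(f"sex[{sex_levels[-1]}]")
    return ConfoundDesign(
        matrix=np.column_stack(cols), columns=tuple(names), coding=coding
    )


def residualize(dm: DataMatrix, design: ConfoundDesign) -> DataMatrix:
    """Per-voxel OLS residuals on the confound design, grand mean re-added.

    The residual component is orthogonal to every design column; adding the
    per-voxel mean back keeps the matrix on a gray-matter-like positive
    scale (the decomposition centres internally, so this is inconsequential
    to the ICA result).
    """
    D = design.matrix
    if D.shape[0] != dm.n_subjects:
        raise ConfigurationError(
            f"design has {D.shape[0]} rows but matrix has {dm.n_subjects} subjects"
        )
    beta, *_ = np.linalg.lstsq(D, dm.values, rcond=None)
    resid = dm.values - D @ beta
    out = resid + dm.values.mean(axis=0, keepdims=True)
    return DataMatrix(values=out, grid=dm.grid, subjects=dm.subjects)


def confound_orthogonality(dm: DataMatrix, design: ConfoundDesign) -> float:
    """Max |<residual column, design column>| / (norms product) after centring.

    Used by the pipeline's invariant checks: residualized data minus its
    per-voxel mean must be orthogonal to every design column.
    """
    centred = dm.values - dm.values.mean(axis=0, keepdims=True)
    D = design.matrix - design.matrix.mean(axis=0, keepdims=True)
    # exclude the (now zero) intercept column
    keep = np.linalg.norm(D, axis=0) > 1e-12
    if not keep.any():
        return 0.0
    D = D[:, keep]
    inner = np.abs(D.T @ centred)
    scale = np.linalg.norm(D, axis=0)[:, None] * np.maximum(
        np.linalg.norm(centred, axis=0)[None, :], 1e-30
    )
    return float((inner / scale).max())


def save_datamatrix(dm: DataMatrix, path: str | Path, meta: dict | None = None) -> Path:
    """Write the adjusted matrix (.npz) plus a JSON sidecar with provenance."""
    path = Path(path)
    np.savez_compressed(path, values=dm.values, mask=dm.grid.mask,
                        affine=dm.grid.affine, voxel_size=dm.grid.voxel_size)
    sidecar = {
        "mask_sha256": hashlib.sha256(dm.grid.mask.tobytes()).hexdigest(),
        "n_subjects": dm.n_subjects,
        "n_voxels": dm.grid.n_voxels,
    }
    sidecar.update(meta or {})
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return path
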