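"""Synthetic gray-matter cohorts with known covariance networks.

Generates everything the real study measured but with ground truth attached:
K sparse spatial sources (sums of smooth Gaussian blobs, optionally mirrored
across the midline to mimic bilateral networks), per-subject loadings that
follow linear or quadratic functions of age plus Gaussian noise, additive
scanner-site and sex offset maps, voxelwise residual noise, and a positive
baseline so voxel values look gray-matter-like.  The defaults encode the
study conditions used throughout the test suite: an adult-lifespan cohort
whose age/sex/site distribution mirrors the published sample (n=536 across
seven age bins, three scanner sites), three linearly declining networks and
one inverted-U quadratic network.

Sources are deliberately sparse (blobs on a zero background), hence
super-Gaussian — the distributional regime the non-extended infomax
contrast assumes.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .volume import ConfigurationError, DataMatrix, VolumeGrid, save_mask, save_volume

#: Age-bin table of the emulated adult-lifespan cohort: ((low, high), count).
DEFAULT_AGE_BINS: tuple[tuple[tuple[float, float], int], ...] = (
    ((20.0, 29.0), 93),
    ((30.0, 39.0), 106),
    ((40.0, 49.0), 86),
    ((50.0, 59.0), 88),
    ((60.0, 69.0), 116),
    ((70.0, 79.0), 41),
    ((80.0, 86.0), 6),
)
#: Scanner-site sampling probabilities (three sites, 289/179/68 of 536).
DEFAULT_SITE_PROBS: tuple[float, float, float] = (289 / 536, 179 / 536, 68 / 536)
#: Fraction of female subjects (273 of 536).
DEFAULT_SEX_RATIO: float = 273 / 536

SITE_LEVELS = ("site1", "site2", "site3")
SEX_LEVELS = ("F", "M")


@dataclasses.dataclass(frozen=True)
class LoadingSpec:
    """Deterministic age trajectory of one component's subject loadings.

    ``coefficients`` are (intercept, age[, age^2]) in loading units per
    year^k; ``order`` must match their length minus one.  ``noise_sd`` is the
    SD of i.i.d. Gaussian loading noise added per subject.
    """

    order: int
    coefficients: tuple[float, ...]
    noise_sd: float

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ConfigurationError(f"loading order must be 1 or 2, got {self.order}")
        if len(self.coefficients) != self.order + 1:
            raise ConfigurationError(
                f"order {self.order} needs {self.order + 1} coefficients, "
                f"got {len(self.coefficients)}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    def evaluate(self, ages: np.ndarray) -> np.ndarray:
        """Noise-free loading at each age (polynomial in raw years)."""
        ages = np.asarray(ages, dtype=float)
        out = np.zeros_like(ages)
        for k, c in enumerate(self.coefficients):
            out += c * ages**k
        return out

    def snr(self, ages: np.ndarray) -> float:
        """Loading signal-to-noise: SD of the age trend over SD of the noise."""
        if self.noise_sd == 0:
            return np.inf
        return float(np.std(self.evaluate(ages))) / self.noise_sd


#: Study-condition loading trajectories: three linear declines, one
#: inverted-U quadratic with vertex near age 50.  Loading SNR over the
#: default age distribution is ~3.6-5.8 (>= 3 for every component).
DEFAULT_LOADING_SPECS: tuple[LoadingSpec, ...] = (
    LoadingSpec(order=1, coefficients=(1.6, -0.012), noise_sd=0.04),
    LoadingSpec(order=1, coefficients=(1.5, -0.010), noise_sd=0.04),
    LoadingSpec(order=1, coefficients=(1.7, -0.014), noise_sd=0.04),
    LoadingSpec(order=2, coefficients=(0.5, 0.040, -0.00040), noise_sd=0.03),
)


@dataclasses.dataclass
class GroundTruth:
    """Complete generative description of one synthetic cohort.

    ``sources`` are K unit-variance zero-mean maps over the mask;
    ``site_effects`` maps site label -> in-mask offset vector; ``seed``
    fully determines every sampled quantity downstream.
    """

    grid: VolumeGrid
    sources: np.ndarray
    loading_specs: tuple[LoadingSpec, ...]
    site_effects: dict[str, np.ndarray]
    sex_effect: np.ndarray
    residual_noise_sd: float
    baseline: float
    seed: int

    def __post_init__(self) -> None:
        self.sources = np.asarray(self.sources, dtype=float)
        if self.sources.ndim != 2 or self.sources.shape[0] < 2:
            raise ConfigurationError("ground truth needs K >= 2 sources")
        if self.sources.shape[1] != self.grid.n_voxels:
            raise ConfigurationError("sources not defined on the grid's mask")
        if len(self.loading_specs) != self.sources.shape[0]:
            raise ConfigurationError("one LoadingSpec per source required")

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    def loadings(self, ages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """n x K loading matrix: age trend plus Gaussian loading noise."""
        ages = np.asarray(ages, dtype=float)
        cols = []
        for spec in self.loading_specs:
            w = spec.evaluate(ages)
            if spec.noise_sd > 0:
                w = w + rng.normal(0.0, spec.noise_sd, size=ages.shape)
            cols.append(w)
        return np.column_stack(cols)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ConfigurationError("cannot standardize a constant map")
    return (v - v.mean()) / sd


def make_sources(
    grid: VolumeGrid,
    K: int,
    blob_count_range: tuple[int, int] = (1, 4),
    seed: int = 0,
    radius_range_mm: tuple[float, float] = (6.0, 12.0),
    mirror_prob: float = 0.5,
    max_corr: float = 0.3,
    max_tries: int = 200,
) -> np.ndarray:
    """Sample K sparse spatial sources with low pairwise correlation.

    Each source is a sum of 1-4 smooth 3-D Gaussian blobs centred at random
    in-mask voxels, optionally mirrored across the first-axis midline
    (bilaterality), then standardized to zero mean / unit variance over the
    mask.  A blob's ``radius`` is its visible half-extent in mm (the
    Gaussian profile's sigma is radius/2), so default 6-12 mm radii produce
    clusters on the scale of real gray-matter network nodes — the volumes
    come out at acquisition-plus-smoothing resolution, i.e. already smooth.
    Blob centres are resampled until every pairwise correlation with
    previously accepted sources is below ``max_corr``.
    """
    if K < 2:
        raise ConfigurationError("K must be >= 2")
    lo, hi = blob_count_range
    if not (1 <= lo <= hi):
        raise ConfigurationError(f"bad blob_count_range {blob_count_range}")
    if radius_range_mm[1] * 2 >= min(grid.extent_mm):
        raise ConfigurationError(
            f"blob radius up to {radius_range_mm[1]} mm does not fit inside "
            f"grid extent {grid.extent_mm} mm"
        )
    rng = np.random.default_rng(seed)
    idx = np.indices(grid.shape).astype(float)
    mask_coords = np.argwhere(grid.mask)
    voxel = np.asarray(grid.voxel_size)

    sources: list[np.ndarray] = []
    for _ in range(K):
        for attempt in range(max_tries):
            n_blobs = int(rng.integers(lo, hi + 1))
            vol = np.zeros(grid.shape)
            for _b in range(n_blobs):
                centre = mask_coords[rng.integers(len(mask_coords))]
                radius = rng.uniform(*radius_range_mm)
                sigma_vox = (radius / 2.0) / voxel
                amp = rng.uniform(0.5, 1.0)
                d2 = sum(
                    ((idx[a] - centre[a]) / sigma_vox[a]) ** 2 for a in range(3)
                )
                blob = amp * np.exp(-0.5 * d2)
                vol += blob
                if rng.random() < mirror_prob:
                    vol += blob[::-1, :, :]
            cand = _standardize(grid.extract(vol))
            if all(abs(float(cand @ s) / grid.n_voxels) < max_corr for s in sources):
                sources.append(cand)
                break
        else:
            raise ConfigurationError(
                f"could not place source {len(sources)} with pairwise "
                f"|correlation| < {max_corr} in {max_tries} tries"
            )
    return np.vstack(sources)


def sample_cohort(
    age_bins=DEFAULT_AGE_BINS,
    n: int | None = None,
    sex_ratio: float = DEFAULT_SEX_RATIO,
    site_probs: tuple[float, float, float] = DEFAULT_SITE_PROBS,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a covariate table (id, age, sex, site).

    Ages are uniform within each ``(low, high)`` bin with the stated count;
    sex is Bernoulli(``sex_ratio`` female) and site categorical with
    ``site_probs``.  If ``n`` is given it must equal the bin-count total.
    """
    counts = [int(c) for (_rng_, c) in age_bins]
    total = sum(counts)
    if n is not None and n != total:
        raise ConfigurationError(f"bin counts sum to {total}, not n={n}")
    probs = np.asarray(site_probs, dtype=float)
    if len(probs) != 3 or abs(probs.sum() - 1.0) > 1e-8:
        raise ConfigurationError("site_probs must be 3 fractions summing to 1")
    rng = np.random.default_rng(seed)
    ages = np.concatenate(
        [rng.uniform(lo, hi, size=c) if hi > lo else np.full(c, float(lo))
         for (lo, hi), c in age_bins]
    )
    sex = np.where(rng.random(total) < sex_ratio, "F", "M")
    site = rng.choice(SITE_LEVELS, size=total, p=probs)
    return pd.DataFrame(
        {
            "id": [f"sub-{i + 1:04d}" for i in range(total)],
            "age": ages,
            "sex": sex,
            "site": site,
        }
    )


def scaled_age_bins(n: int, age_bins=DEFAULT_AGE_BINS):
    """Rescale the default bin counts to total ``n`` (largest remainder)."""
    if n < 10:
        raise ConfigurationError("need n >= 10 for any analysis run")
    counts = np.asarray([c for _r, c in age_bins], dtype=float)
    exact = counts * n / counts.sum()
    floor = np.floor(exact).astype(int)
    short = n - floor.sum()
    order = np.argsort(-(exact - floor))
    floor[order[:short]] += 1
    return tuple(((lo, hi), int(c)) for ((lo, hi), _), c in zip(age_bins, floor))


def make_ground_truth(
    grid: VolumeGrid,
    K: int = 4,
    seed: int = 0,
    loading_specs: tuple[LoadingSpec, ...] | None = None,
    site_effect_sd: float = 0.1,
    sex_effect_sd: float = 0.1,
    residual_noise_sd: float = 0.2,
    baseline: float = 3.0,
    blob_count_range: tuple[int, int] = (1, 4),
) -> GroundTruth:
    """Build a GroundTruth with sampled sources and confound maps.

    Confound maps are spatially smooth random fields (white noise smoothed
    with a 2-voxel Gaussian, standardized, scaled by the stated SD), one per
    scanner site plus one sex-offset map.
    """
    if loading_specs is None:
        if K == len(DEFAULT_LOADING_SPECS):
            loading_specs = DEFAULT_LOADING_SPECS
        else:
            loading_specs = tuple(
                LoadingSpec(order=1, coefficients=(1.5, -0.010), noise_sd=0.04)
                for _ in range(K)
            )
    ss = np.random.SeedSequence([int(seed), 0x5B3])
    s_src, s_conf = ss.spawn(2)
    sources = make_sources(
        grid, K, blob_count_range=blob_count_range,
        seed=s_src.generate_state(1)[0] % (2**31),
    )
    rng = np.random.default_rng(s_conf)

    def smooth_field(sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros(grid.n_voxels)
        noise = rng.standard_normal(grid.shape)
        sm = ndimage.gaussian_filter(noise, sigma=2.0)
        return sd * _standardize(grid.extract(sm))

    site_effects = {lvl: smooth_field(site_effect_sd) for lvl in SITE_LEVELS}
    sex_effect = smooth_field(sex_effect_sd)
    return GroundTruth(
        grid=grid,
        sources=sources,
        loading_specs=tuple(loading_specs),
        site_effects=site_effects,
        sex_effect=sex_effect,
        residual_noise_sd=residual_noise_sd,
        baseline=baseline,
        seed=int(seed),
    )


def synthesize(gt: GroundTruth, cohort: pd.DataFrame, grid: VolumeGrid | None = None) -> DataMatrix:
    """Mix sources, confounds and noise into a subjects-by-voxels matrix.

    Subject i's in-mask row is ``sum_k w_ik s_k + site_offset(site_i) +
    sex_i * sex_effect + eps + baseline`` with ``w_ik`` the LoadingSpec
    evaluated at age_i plus loading noise and ``eps`` i.i.d. Gaussian of SD
    ``residual_noise_sd``.  Fully determined by ``gt.seed`` and the cohort.
    """
    if grid is None:
        grid = gt.grid
    if grid is not gt.grid and grid.n_voxels != gt.grid.n_voxels:
        raise ConfigurationError("cohort grid does not match ground-truth grid")
    ss = np.random.SeedSequence([int(gt.seed), 0xDA7A])
    s_load, s_noise = ss.spawn(2)
    ages = cohort["age"].to_numpy(dtype=float)
    W = gt.loadings(ages, np.random.default_rng(s_load))
    X = W @ gt.sources
    for lvl, off in gt.site_effects.items():
        rows = (cohort["site"] == lvl).to_numpy()
        if rows.any():
            X[rows] += off
    sex_ind = (cohort["sex"] == "M").to_numpy(dtype=float)
    X += np.outer(sex_ind, gt.sex_effect)
    if gt.residual_noise_sd > 0:
        X += np.random.default_rng(s_noise).normal(
            0.0, gt.residual_noise_sd, size=X.shape
        )
    X += gt.baseline
    return DataMatrix(values=X, grid=grid, subjects=cohort.reset_index(drop=True))


def export_cohort(
    dm: DataMatrix, gt: GroundTruth, outdir: str | Path
) -> Path:
    """Write one NIfTI per subject, the mask, covariates TSV and truth YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_mask(dm.grid, outdir / "mask.nii.gz")
    for i, sid in enumerate(dm.subjects["id"]):
        save_volume(dm.grid, dm.grid.embed(dm.values[i]), outdir / f"{sid}_gm.nii.gz")
    dm.subjects.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    spec = {
        "seed": gt.seed,
        "n_components": gt.n_components,
        "residual_noise_sd": gt.residual_noise_sd,
        "baseline": gt.baseline,
        "loading_specs": [
            {
                "order": s.order,
                "coefficients": list(s.coefficients),
                "noise_sd": s.noise_sd,
            }
            for s in gt.loading_specs
        ],
    }
    with open(outdir / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)
    return outdir
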