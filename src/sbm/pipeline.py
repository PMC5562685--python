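"""End-to-end orchestration: simulate/load -> smooth -> residualize ->
decompose -> map -> trajectories -> reports.

A run is driven by a :class:`RunConfig` whose defaults are the study
settings (K = 20 components, 8 mm FWHM smoothing, z-map threshold 3,
polynomial orders 1-3, alpha 0.05 Bonferroni-corrected over m = K tests,
age-subset re-analyses at upper bounds 80/70/60).  The single master seed
is expanded into independent per-stage seeds through a deterministic
``SeedSequence`` spawn, so a rerun with the same config reproduces every
numeric output bitwise.  Structural invariants (z-map standardization,
residual/confound orthogonality, the decomposition's reconstruction
identity, cluster mass conservation and threshold monotonicity, and the
t^2 = R^2 (n-2)/(1-R^2) identity on linear fits) are checked on every run
and recorded in the manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ica, mapping, preprocess, synthetic, trajectories
from .volume import ConfigurationError, DataMatrix, VolumeGrid, default_grid, grid_from_nifti_mask, load_volume, save_volume

__version__ = "0.1.0"


@dataclasses.dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults mirror the study settings."""

    mode: str = "synthetic"
    n_components: int = 20
    fwhm_mm: float = 8.0
    z_threshold: float = 3.0
    orders: tuple[int, ...] = (1, 2, 3)
    alpha: float = 0.05
    m: int | None = None              # Bonferroni test count; None -> n_components
    age_subsets: tuple[float, ...] = (80.0, 70.0, 60.0)
    connectivity: int = 26
    min_voxels: int = 0
    tail: str = "positive"
    seed: int = 0
    outdir: str = "sbm_run"
    smooth_inputs: bool = True        # real mode may supply pre-smoothed maps
    # synthetic-mode generator settings
    n_subjects: int = 536
    k_true: int = 4
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    # real-mode inputs
    volumes_dir: str | None = None
    mask_path: str | None = None
    covariates_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ConfigurationError("mode must be 'synthetic' or 'real'")
        self.orders = tuple(int(o) for o in self.orders)
        self.age_subsets = tuple(float(b) for b in self.age_subsets)
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def bonferroni_m(self) -> int:
        return self.m if self.m is not None else self.n_components

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["orders"] = list(self.orders)
        d["age_subsets"] = list(self.age_subsets)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path


def _stage_seeds(master: int, n: int = 6) -> list[int]:
    """Deterministic per-stage seeds (< 2^31) from the master seed."""
    ss = np.random.SeedSequence(int(master))
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_real_inputs(cfg: RunConfig) -> DataMatrix:
    if not (cfg.volumes_dir and cfg.mask_path and cfg.covariates_path):
        raise ConfigurationError(
            "real mode needs volumes_dir, mask_path and covariates_path"
        )
    grid = grid_from_nifti_mask(cfg.mask_path)
    cov = pd.read_csv(cfg.covariates_path, sep="\t")
    missing = [c for c in ("id", "age", "sex", "site") if c not in cov.columns]
    if missing:
        raise ConfigurationError(f"covariate table lacks columns: {missing}")
    vol_dir = Path(cfg.volumes_dir)
    rows, absent = [], []
    for sid in cov["id"]:
        hits = sorted(vol_dir.glob(f"{sid}*.nii*"))
        if not hits:
            absent.append(str(sid))
            continue
        rows.append(grid.extract(load_volume(hits[0])))
    if absent:
        raise ConfigurationError(f"no volume found for subjects: {absent}")
    return DataMatrix(values=np.vstack(rows), grid=grid, subjects=cov)


def check_invariants(
    decomp: ica.Decomposition,
    dm_resid: DataMatrix,
    design: preprocess.ConfoundDesign,
    zset: mapping.ZMapSet,
    clusters: pd.DataFrame,
    fits: list[trajectories.TrajectoryFit],
    z_threshold: float,
    connectivity: int,
) -> dict:
    """Structural invariants asserted on every pipeline run."""
    grid = zset.grid
    checks: dict[str, dict] = {}

    zmean = float(np.abs(zset.zmaps.mean(axis=1)).max())
    zsd = float(np.abs(zset.zmaps.std(axis=1, ddof=0) - 1).max())
    checks["zmaps_standardized"] = {"ok": zmean < 1e-8 and zsd < 1e-8,
                                    "max_abs_mean": zmean, "max_sd_dev": zsd}

    ortho = preprocess.confound_orthogonality(dm_resid, design)
    checks["residual_orthogonality"] = {"ok": ortho < 1e-8, "max_rel_inner": ortho}

    rerr = ica.reconstruction_error(decomp, dm_resid)
    checks["reconstruction_identity"] = {"ok": rerr < 1e-6, "relative_error": rerr}

    mass_ok = True
    mono_ok = True
    for k in range(zset.n_components):
        vol = zset.volume(k)
        supra = int(((vol >= z_threshold) & grid.mask).sum())
        tabulated = int(clusters.loc[
            (clusters["component"] == k) & (clusters["sign"] == 1), "n_voxels"
        ].sum())
        mass_ok &= supra == tabulated
        higher = int(((vol >= z_threshold + 0.5) & grid.mask).sum())
        mono_ok &= higher <= supra
    checks["cluster_mass_conservation"] = {"ok": bool(mass_ok)}
    checks["threshold_monotonicity"] = {"ok": bool(mono_ok)}

    worst = 0.0
    for tf in fits:
        lin = tf.fits.get(1)
        if lin is None or lin.r2 >= 1.0:
            continue
        t_direct = lin.beta_high / lin.se_high
        t_ident = trajectories.t_from_r2(lin.r2, lin.n)
        denom = max(abs(t_ident), 1e-12)
        worst = max(worst, abs(abs(t_direct) - t_ident) / denom)
    checks["linear_t_r2_identity"] = {"ok": worst < 1e-8, "max_rel_dev": worst}

    checks["all_ok"] = all(v["ok"] for k, v in checks.items() if k != "all_ok")
    return checks


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write all reports under the run directory.

    Returns the run directory.  Raises if a structural invariant fails;
    non-converged ICA completes with a warning recorded in the manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    warnings_log: list[str] = []

    if config.mode == "synthetic":
        grid = default_grid(config.grid_shape, config.voxel_size_mm)
        gt = synthetic.make_ground_truth(grid, K=config.k_true, seed=seeds[0])
        cohort = synthetic.sample_cohort(
            synthetic.scaled_age_bins(config.n_subjects), seed=seeds[1]
        )
        dm = synthetic.synthesize(gt, cohort)
    else:
        gt = None
        dm = _load_real_inputs(config)
        grid = dm.grid
        cohort = dm.subjects

    if config.smooth_inputs:
        dm = preprocess.smooth_matrix(dm, config.fwhm_mm)
    design = preprocess.build_confound_design(cohort)
    dm_adj = preprocess.residualize(dm, design)

    decomp = ica.decompose(dm_adj, K=config.n_components, seed=seeds[2])
    if decomp.convergence is not None and not decomp.convergence.converged:
        warnings_log.append(
            f"ICA did not converge (final update {decomp.convergence.final_update:.2e})"
        )

    zset = mapping.zscore_sources(decomp, grid)
    clusters = mapping.cluster_table(
        zset, threshold=config.z_threshold, connectivity=config.connectivity,
        min_voxels=config.min_voxels, tail=config.tail,
    )

    ages = cohort["age"].to_numpy(dtype=float)
    fits = [
        trajectories.fit_component(
            decomp.mixing[:, k], ages, orders=config.orders,
            alpha=config.alpha, m=config.bonferroni_m, component=k,
        )
        for k in range(decomp.n_components)
    ]
    table = trajectories.trajectory_table(fits)
    sens = trajectories.age_subset_analysis(
        decomp.mixing, cohort, upper_bounds=config.age_subsets,
        orders=config.orders, alpha=config.alpha, m=config.bonferroni_m,
    )

    invariants = check_invariants(
        decomp, dm_adj, design, zset, clusters, fits,
        config.z_threshold, config.connectivity,
    )

    # ---- outputs -------------------------------------------------------
    config.to_yaml(outdir / "config.yaml")
    mix = pd.DataFrame(
        decomp.mixing,
        columns=[f"IC{k + 1}" for k in range(decomp.n_components)],
    )
    mix.insert(0, "id", cohort["id"].to_numpy())
    mix.to_csv(outdir / "mixing.tsv", sep="\t", index=False)
    clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    table.to_csv(outdir / "trajectories.tsv", sep="\t", index=False)
    sens.to_csv(outdir / "sensitivity.tsv", sep="\t", index=False)
    for k in range(zset.n_components):
        save_volume(grid, zset.volume(k), outdir / f"zmap_IC{k + 1}.nii.gz")
    conv = decomp.convergence
    with open(outdir / "convergence.json", "w") as fh:
        json.dump(
            {
                "iterations": conv.iterations if conv else None,
                "final_update": conv.final_update if conv else None,
                "converged": conv.converged if conv else None,
                "n_anneals": conv.n_anneals if conv else None,
                "retained_variance": decomp.reduction.retained_variance,
            },
            fh, indent=2,
        )
    if gt is not None:
        rep = ica.match_components(
            decomp, gt,
            true_loadings=gt.loadings(ages, np.random.default_rng(0))
            if decomp.n_components >= gt.n_components else None,
        )
        with open(outdir / "recovery.json", "w") as fh:
            json.dump(
                {
                    "permutation": rep.permutation.tolist(),
                    "signs": rep.signs.tolist(),
                    "spatial_correlation": rep.spatial_correlation.tolist(),
                    "mean_spatial_correlation": rep.mean_spatial_correlation,
                    "amari": rep.amari,
                },
                fh, indent=2,
            )

    outputs = sorted(
        p for p in outdir.iterdir()
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "software_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_sha256": _sha256(outdir / "config.yaml"),
        "warnings": warnings_log,
        "invariants": invariants,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    if not invariants["all_ok"]:
        failed = [k for k, v in invariants.items() if k != "all_ok" and not v["ok"]]
        raise RuntimeError(f"structural invariant(s) failed: {failed}")
    return outdir


def validate_report(
    table: pd.DataFrame | str | Path,
    n_subjects: int | None = None,
    t_tol: float = 0.03,
    p_rel_tol: float = 0.10,
    ci_round_rel: float = 0.01,
) -> pd.DataFrame:
    """Audit a trajectory report's internal statistical identities.

    For every linear row checks (a) |t| against sqrt(R^2 (n-2)/(1-R^2))
    within ``t_tol`` (covering two-decimal table rounding), (b) t against
    beta/SE with SE reconstructed from the 95% CI within
    ``t_tol + ci_round_rel * |t|`` — CI bounds printed to three significant
    figures perturb the reconstructed SE by up to ~1% relative, which
    scales with |t| — and (c) p against the two-sided t survival function
    within ``p_rel_tol`` relative.  Rows that cannot be parsed are reported with
    ``status='malformed'`` and skipped.  Expects columns ``r2, beta_high,
    ci_low, ci_high, t, p`` plus either ``df`` or an ``n_subjects``
    argument; a ``selected_order`` column restricts checks to linear rows.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    results = []
    for idx, row in table.iterrows():
        rec = {"row": idx, "status": "ok", "t_r2_ok": None, "t_ci_ok": None,
               "p_ok": None}
        try:
            order = int(row["selected_order"]) if "selected_order" in row else 1
            if order != 1:
                rec["status"] = "skipped_nonlinear"
                results.append(rec)
                continue
            r2 = float(row["r2"])
            beta = float(row["beta_high"])
            lo, hi = float(row["ci_low"]), float(row["ci_high"])
            t_printed = float(row["t"])
            p_printed = float(row["p"])
            if "df" in row and np.isfinite(row["df"]):
                df = int(row["df"])
                n = df + 2
            elif n_subjects is not None:
                n = int(n_subjects)
                df = n - 2
            else:
                raise KeyError("df")
            t_r2 = trajectories.t_from_r2(r2, n)
            rec["t_from_r2"] = t_r2
            rec["t_r2_ok"] = bool(abs(abs(t_printed) - t_r2) <= t_tol)
            t_ci = trajectories.t_from_beta_ci(beta, lo, hi, df)
            rec["t_from_ci"] = t_ci
            ci_tol = t_tol + ci_round_rel * abs(t_printed)
            rec["t_ci_ok"] = bool(abs(t_printed - t_ci) <= ci_tol)
            p_check = trajectories.two_sided_p(t_printed, df)
            rec["p_from_t"] = p_check
            rec["p_ok"] = bool(
                abs(p_check - p_printed) <= p_rel_tol * max(p_printed, 1e-300)
            )
        except (KeyError, TypeError, ValueError) as exc:
            rec["status"] = "malformed"
            rec["error"] = str(exc)
        results.append(rec)
    out = pd.DataFrame(
        results,
        columns=["row", "status", "t_r2_ok", "t_ci_ok", "p_ok",
                 "t_from_r2", "t_from_ci", "p_from_t", "error"],
    )
    checked = out[out["status"] == "ok"]
    out.attrs["all_consistent"] = bool(
        checked[["t_r2_ok", "t_ci_ok", "p_ok"]].all().all()
    ) if len(checked) else True
    out.attrs["n_checked"] = int(len(checked))
    return out
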