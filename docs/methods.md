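# Methods

## The model

Source-based morphometry treats the stacked gray-matter maps of a cohort as
a linear mixture.  With `X` the n_subjects × n_voxels matrix of in-mask
gray-matter values, the decomposition

    X ≈ A S

yields `S` (K × n_voxels), whose rows are spatially independent covariance
networks, and `A` (n_subjects × K), whose columns score how strongly each
subject expresses each network.  The age trajectory of a network is the
regression of its column of `A` on age.

The pipeline stages are: Gaussian smoothing (8 mm FWHM default, per-axis
voxel sigmas `σ = FWHM/(2√(2 ln 2)) / voxel_size`); voxelwise OLS removal
of scanner-site and sex effects; PCA whitening to K components; infomax
unmixing; z-scored source maps thresholded at Z = 3 with 26-connected
cluster tables; and per-component polynomial (order 1–3) age fits with BIC
selection and Bonferroni-corrected t-tests of the highest-order
coefficient.

## Confound removal

Three scanner sites and sex are removed per voxel by OLS on an intercept +
(L−1) reference-coded site indicators + one sex indicator.  Coding L site
indicators alongside an intercept would be rank-deficient; since only the
residuals propagate downstream and residuals are invariant to the choice of
full-rank coding (verified against sum coding to 1e-10), the
parameterization is immaterial.  The per-voxel grand mean is added back so
the matrix keeps a gray-matter-like positive scale; the decomposition
centres internally, so this choice cannot affect the networks.

## Centering and whitening

The matrix is **doubly centred** (per voxel across subjects, then per
subject across voxels) before the SVD-based projection to K principal axes
with unit covariance.  Double centering makes two contracts exact rather
than approximate: every estimated source row has zero mean over mask
voxels, and `mixing @ sources` reconstructs the centred, K-rank-reduced
data to machine precision.  The subject-mean component it removes is a
global-volume offset that the site/sex residualization and the baseline
already account for.

## Infomax

Unmixing uses batch natural-gradient infomax with the logistic
nonlinearity (`ΔW = lr (I + (1 − 2 g(U)) Uᵀ/p) W`, `g(u) = 1/(1+e^{−u})`,
`U = W Y`), the maximum-likelihood contrast for super-Gaussian sources —
appropriate because gray-matter networks are sparse maps (blobs on a
near-zero background).  Defaults: seeded random orthonormal start,
`lr0 = 0.1/ln(K+1)`, annealing by ×0.9 whenever the angle between
successive updates exceeds 60°, stop at relative update norm < 1e-6 or
2000 iterations.  The rate constant and iteration cap were chosen so that
desk-scale problems (K ≤ 20, ~6600 voxels) reach the tolerance; a
non-convergent run returns its current unmixing with a warning flag rather
than raising.  Two i.i.d. Gaussian sources are the documented
unidentifiable case: any rotation whitens, and the algorithm may return an
arbitrary rotation.

Canonical form: source rows are rescaled to unit variance (scale moves
into the mixing columns), each component is sign-flipped so its source
skewness is ≥ 0, and components are ordered by descending explained
variance.  K = 20 is the pipeline default, matching the published
analysis; the recovery experiments extract K = 4 to match their generating
truth.

Estimated source rows are mutually uncorrelated (within ~1e-2) when the
generating sources are independent and the spatial sample is large; on
spatially overlapping blob sources the maximum-likelihood unmixing tracks
part of the true dependence, and residual correlations of a few percent
are expected, not an error.

## Network maps and clusters

Each source row is z-scored over in-mask voxels and embedded in the 3-D
grid.  Clusters are connected components of `{z ≥ 3}` (positive tail by
default — the reported covariance patterns load positively; a two-tailed
mode labels `{z ≤ −3}` separately) under 26-connectivity, with voxel
counts, mm³ sizes (count × voxel volume), and affine-mapped world-mm peak
coordinates; peak ties break to the smallest linear index for determinism.
The minimum cluster size defaults to 0 (single voxels are reported).

## Trajectory statistics

Fits use OLS on powers of mean-centred age for conditioning; coefficients
are reported in the raw-age basis, and the highest-order coefficient and
its SE are identical in both bases.  BIC is `n ln(RSS/n) + (order+1) ln n`
(error variance omitted from the parameter count — it would add the same
`ln n` to every order and cannot change rankings); RSS = 0 maps to −∞ and
ties break to the lower order.  The selected model's highest-order
coefficient is tested two-sided with `df = n − (order+1)`; p-values go
through the regularized incomplete-beta survival function, so magnitudes
like 1e-77 are exact in double precision.  Bonferroni uses m = the number
of extracted components (20 by default, giving the 0.05/20 = 2.5e-3
per-test bound).  Age-subset re-analyses (upper bounds 80/70/60 years by
default) keep the full-cohort weights and restrict subjects only.

Printed-table auditing utilities invert the linear-fit identities:
`|t| = √(R² (n−2)/(1−R²))` and `SE = (CI_hi − CI_lo)/(2 t_{0.975,df})`.
When auditing a table printed at finite precision, the CI route's
tolerance grows with |t| (3-significant-figure CI bounds perturb the
reconstructed SE by ~1% relative).

**Post-selection inflation.**  The composite procedure — select the order
by BIC, then test the highest-order coefficient at α/m — does not control
family-wise error at α: conditioning on BIC preferring a higher order
implies that coefficient's t is already large.  The null-calibration
simulation (n = 536, m = 20, 1000 families) measures FWER ≈ 0.09 for the
composite versus ≈ 0.04–0.05 for the Bonferroni procedure proper (the
age-effect test per component without selection conditioning).  Both
numbers are recomputed by `analysis/05_null_calibration.py` and the test
suite; users interpreting the composite procedure's significance flags
should be aware of the inflation.

## Synthetic cohorts

The generator emulates the statistical structure of an adult-lifespan
gray-matter study: a 24×28×24 grid at 3 mm with an ellipsoidal mask
(~6600 voxels); K covariant sources, each a sum of 1–4 Gaussian blobs
(radius = visible half-extent, 6–12 mm; sigma = radius/2) optionally
mirrored across the midline for bilaterality, standardized over the mask,
and resampled until all pairwise correlations are < 0.3; subject loadings
following linear or quadratic polynomials of age plus Gaussian noise;
smooth random site and sex offset maps (SD 0.1); i.i.d. voxel noise; and a
positive baseline (3.0) for a gray-matter-like scale.  The default cohort
reproduces the published sample's age-bin counts (93/106/86/88/116/41/6,
total 536), site mix (289/179/68) and sex ratio (273 F / 263 M); arbitrary
totals use largest-remainder rescaling of the bins.

Default trajectories: three linear declines (slopes −0.012, −0.010,
−0.014 per year; noise SD 0.04) and one inverted-U quadratic (vertex near
age 50, curvature −4e-4 per year²; noise SD 0.03), giving loading SNRs
(trend SD / noise SD) of ~3.4–5.8 over the default age distribution.  The
source literature reports no voxel-scale effect sizes, so the noise scales
are calibrated to make recovery feasible rather than to match any real
acquisition: voxel noise SD 0.2 leaves per-voxel signal well below noise
while PCA across ~6600 voxels recovers the subspace reliably.

Because the blobs are generated directly at post-smoothing spatial scale,
the recovery experiments feed them through the pre-smoothed-inputs path
(no second smoothing pass).  Re-smoothing already-smooth volumes costs
roughly a factor 20 in effective spatial samples and measurably inflates
ICA cross-talk between components (BIC order-selection accuracy drops from
~95% to ~78% in the default experiment); the full pipeline nevertheless
smooths by default, since real inputs arrive at acquisition resolution.

**What the generator does not emulate** — anatomy (no template, no tissue
priors), spatially structured noise, scanner-specific voxel-scale
artefacts beyond additive offset maps, non-polynomial trajectories, and
subject motion/registration error.  Passing recovery tests therefore shows
the estimator chain is correct under its own model, not that real
gray-matter networks are recovered with these accuracies.

## Problem sizes and determinism

Test-suite experiments use n = 150–200 subjects, K = 4, and 5–20 seeds;
the null calibration uses 1000 simulated families at n = 536.  Every
random quantity descends from an explicit seed (the pipeline expands its
master seed into per-stage seeds via `numpy.random.SeedSequence.spawn`),
and identical configurations reproduce all numeric outputs bitwise.

## Known limitations

- Non-extended infomax only: sub-Gaussian sources (e.g. uniform) are
  outside the contrast's assumptions and are not separated reliably.
- No ICASSO-style stability resampling and no estimation of the component
  number; K is fixed by configuration.
- Cluster tables carry coordinates only; anatomical labelling is the
  user's concern (an optional lookup table can be joined downstream).
- The composite select-then-test significance flags inherit the
  post-selection inflation described above.
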