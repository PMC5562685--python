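"""PCA whitening + non-extended infomax ICA for spatial decomposition.

The adjusted subjects-by-voxels matrix is doubly centred (per voxel across
subjects and per subject across voxels), reduced to K principal axes with
unit covariance, and unmixed by batch natural-gradient infomax with the
logistic nonlinearity — the maximum-likelihood contrast for super-Gaussian
sources, which the sparse gray-matter networks are.  The decomposition is
returned in a canonical form: source rows unit-variance with non-negative
skewness, components ordered by descending explained variance, and the
mixing matrix expressed in original subject space so that
``mixing @ sources`` reconstructs the centred, K-rank-reduced data exactly.

Double centring makes two contracts hold simultaneously and exactly: every
source row has zero mean over mask voxels, and the reconstruction identity
above is algebraic rather than approximate.
"""
from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import optimize, special, stats

from .volume import ConfigurationError, DataMatrix


@dataclasses.dataclass
class Reduction:
    """Whitening/de-whitening operators and retained-variance bookkeeping."""

    row_mean: np.ndarray      # per-voxel mean across subjects (V,)
    col_mean: np.ndarray      # per-subject mean across voxels, after row centring (n,)
    grand_scale: int          # number of voxels used for the unit-covariance scaling
    whiten: np.ndarray        # K x n: whitened = whiten @ centred
    dewhiten: np.ndarray      # n x K: centred_reduced = dewhiten @ whitened
    singular_values: np.ndarray
    retained_variance: float
    rank: int

    def centre(self, X: np.ndarray) -> np.ndarray:
        Xc = X - self.row_mean[None, :]
        return Xc - self.col_mean[:, None]

    def whitened(self, X: np.ndarray) -> np.ndarray:
        return self.whiten @ self.centre(X)


@dataclasses.dataclass
class ConvergenceInfo:
    iterations: int
    final_update: float
    converged: bool
    learning_rate_trace: list[float]
    n_anneals: int


@dataclasses.dataclass
class Decomposition:
    """Mixing (subject weights) and sources (spatial components) of one run."""

    mixing: np.ndarray        # n_subjects x K
    sources: np.ndarray       # K x n_voxels, zero mean / unit variance rows
    reduction: Reduction
    convergence: ConvergenceInfo | None
    seed: int
    explained_variance: np.ndarray  # per component, descending

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]


def _as_array(X) -> np.ndarray:
    if isinstance(X, DataMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def center_and_whiten(X, K: int, rank_tol: float = 1e-9):
    """Double-centre the data and project to K unit-variance principal axes.

    Returns ``(Y, reduction)`` with ``Y`` of shape K x n_voxels satisfying
    ``Y @ Y.T / n_voxels = I``.  Raises if K exceeds the numerical rank of
    the centred matrix (reported in the message).
    """
    X = _as_array(X)
    n, p = X.shape
    if K > min(n - 1, p):
        raise ConfigurationError(f"K={K} exceeds min(n_subjects-1, n_voxels)")
    row_mean = X.mean(axis=0)
    Xc = X - row_mean[None, :]
    col_mean = Xc.mean(axis=1)
    Xc = Xc - col_mean[:, None]
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > rank_tol * S[0]).sum()) if S[0] > 0 else 0
    if K > rank:
        raise ConfigurationError(
            f"K={K} exceeds the numerical rank {rank} of the centred data"
        )
    sqrt_p = math.sqrt(p)
    whiten = (sqrt_p / S[:K])[:, None] * U[:, :K].T          # K x n
    dewhiten = U[:, :K] * (S[:K] / sqrt_p)[None, :]           # n x K
    Y = whiten @ Xc
    total = float((S**2).sum())
    red = Reduction(
        row_mean=row_mean,
        col_mean=col_mean,
        grand_scale=p,
        whiten=whiten,
        dewhiten=dewhiten,
        singular_values=S,
        retained_variance=float((S[:K] ** 2).sum() / total) if total > 0 else 0.0,
        rank=rank,
    )
    return Y, red


def infomax(
    Y: np.ndarray,
    lr0: float | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
    anneal: float = 0.9,
    anneal_angle_deg: float = 60.0,
) -> tuple[np.ndarray, ConvergenceInfo]:
    """Batch natural-gradient infomax with the logistic nonlinearity.

    Iterates ``dW = lr * (I + (1 - 2*g(U)) @ U.T / p) @ W`` with
    ``g(u) = 1/(1+exp(-u))`` and ``U = W @ Y`` on the whitened data, from a
    seeded random orthonormal start.  The learning rate is annealed (times
    ``anneal``) whenever the angle between successive updates exceeds 60
    degrees; iteration stops when ``||dW||/||W|| < tol``.  Non-convergence
    at ``max_iter`` returns the current W with a warning flag, not an error.
    """
    Y = np.asarray(Y, dtype=float)
    K, p = Y.shape
    rng = np.random.default_rng(seed)
    W, _ = np.linalg.qr(rng.standard_normal((K, K)))
    lr = lr0 if lr0 is not None else 0.1 / math.log(K + 1.0)
    eye = np.eye(K)
    cos_limit = math.cos(math.radians(anneal_angle_deg))
    lr_trace = [lr]
    n_anneals = 0
    prev_dW = None
    rel = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        U = W @ Y
        G = special.expit(U)
        grad = (eye + (1.0 - 2.0 * G) @ U.T / p) @ W
        dW = lr * grad
        if prev_dW is not None:
            num = float(np.sum(dW * prev_dW))
            den = float(np.linalg.norm(dW) * np.linalg.norm(prev_dW))
            if den > 0 and num / den < cos_limit:
                lr *= anneal
                n_anneals += 1
                lr_trace.append(lr)
                dW = lr * grad
        W = W + dW
        prev_dW = dW
        rel = float(np.linalg.norm(dW) / np.linalg.norm(W))
        if rel < tol:
            break
    converged = rel < tol
    if not converged:
        warnings.warn(
            f"infomax did not converge in {max_iter} iterations "
            f"(relative update {rel:.2e})",
            stacklevel=2,
        )
    info = ConvergenceInfo(
        iterations=it,
        final_update=rel,
        converged=converged,
        learning_rate_trace=lr_trace,
        n_anneals=n_anneals,
    )
    return W, info


def compose_decomposition(
    X, reduction: Reduction, W: np.ndarray,
    convergence: ConvergenceInfo | None = None, seed: int = 0,
) -> Decomposition:
    """Assemble the canonical Decomposition from the unmixing matrix.

    Sources are rescaled to unit variance per row (the scale moves into the
    mixing columns), sign-flipped so each source's skewness is >= 0, and
    ordered by descending explained variance (squared norm of the mixing
    column, sources being unit variance).
    """
    X = _as_array(X)
    Y = reduction.whitened(X)
    S = W @ Y
    A = reduction.dewhiten @ np.linalg.inv(W)     # n x K, mixing for raw S
    sd = S.std(axis=1, ddof=0)
    if np.any(sd == 0):
        raise ConfigurationError("degenerate (constant) source encountered")
    S = S / sd[:, None]
    A = A * sd[None, :]
    skew = stats.skew(S, axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    S = S * flip[:, None]
    A = A * flip[None, :]
    ev = (A**2).sum(axis=0)
    order = np.argsort(-ev)
    return Decomposition(
        mixing=A[:, order],
        sources=S[order],
        reduction=reduction,
        convergence=convergence,
        seed=seed,
        explained_variance=ev[order],
    )


def decompose(X, K: int, seed: int = 0, **infomax_kwargs) -> Decomposition:
    """center_and_whiten -> infomax -> compose, in one call."""
    Y, red = center_and_whiten(X, K)
    W, info = infomax(Y, seed=seed, **infomax_kwargs)
    return compose_decomposition(X, red, W, convergence=info, seed=seed)


def reconstruction_error(decomp: Decomposition, X) -> float:
    """Relative error of mixing @ sources vs the centred reduced data."""
    X = _as_array(X)
    red = decomp.reduction
    target = red.dewhiten @ red.whitened(X)
    recon = decomp.mixing @ decomp.sources
    denom = np.linalg.norm(target)
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(recon - target) / denom)


def amari_index(P: np.ndarray) -> float:
    """Normalized Amari performance index in [0, 1].

    Zero iff ``P`` is a scaled permutation; 1 for the maximally mixed case
    (all entries equal).  The row and column sums of ``|P|/rowmax`` and
    ``|P|/colmax`` are averaged and normalized by ``2 K (K-1)``.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ConfigurationError("Amari index needs a square matrix")
    A = np.abs(P)
    if np.any(A.max(axis=1) == 0) or np.any(A.max(axis=0) == 0):
        raise ConfigurationError("Amari index undefined for zero rows/columns")
    K = A.shape[0]
    if K == 1:
        return 0.0
    rows = (A / A.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (A / A.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * K * (K - 1)))


@dataclasses.dataclass
class RecoveryReport:
    """How well an estimated decomposition matches a known ground truth."""

    permutation: np.ndarray        # est index -> true index
    signs: np.ndarray              # sign of the matched spatial correlation
    spatial_correlation: np.ndarray  # absolute values, per matched pair
    loading_correlation: np.ndarray  # absolute values, per matched pair
    amari: float | None
    unmatched_estimated: tuple[int, ...]
    unmatched_true: tuple[int, ...]

    @property
    def mean_spatial_correlation(self) -> float:
        return float(self.spatial_correlation.mean())


def _corr_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of A and every row of B."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    Ac /= np.linalg.norm(Ac, axis=1, keepdims=True)
    Bc /= np.linalg.norm(Bc, axis=1, keepdims=True)
    return Ac @ Bc.T


def match_components(est: Decomposition, truth, true_loadings: np.ndarray | None = None) -> RecoveryReport:
    """Optimally pair estimated and true components by |spatial correlation|.

    Uses the Hungarian assignment maximizing total absolute correlation (not
    greedy matching).  ``truth`` may be a GroundTruth or a K x V source
    array.  With unequal component counts the min(K_est, K_true) best pairs
    are matched and the rest flagged unmatched.
    """
    true_sources = np.asarray(getattr(truth, "sources", truth), dtype=float)
    C = _corr_rows(est.sources, true_sources)
    rows, cols = optimize.linear_sum_assignment(-np.abs(C))
    signs = np.sign(C[rows, cols])
    spatial = np.abs(C[rows, cols])
    if true_loadings is not None:
        L = np.asarray(true_loadings, dtype=float)
        lc = np.empty(len(rows))
        for i, (r, c) in enumerate(zip(rows, cols)):
            lc[i] = abs(np.corrcoef(est.mixing[:, r], L[:, c])[0, 1])
    else:
        lc = np.full(len(rows), np.nan)
    amari = None
    if est.sources.shape[0] == true_sources.shape[0]:
        amari = amari_index(C)
    k_est, k_true = est.sources.shape[0], true_sources.shape[0]
    return RecoveryReport(
        permutation=cols,
        signs=signs,
        spatial_correlation=spatial,
        loading_correlation=lc,
        amari=amari,
        unmatched_estimated=tuple(sorted(set(range(k_est)) - set(rows))),
        unmatched_true=tuple(sorted(set(range(k_true)) - set(cols))),
    )


def rotation_kurtosis_oracle(Y: np.ndarray, step_deg: float = 0.1) -> np.ndarray:
    """Exhaustive 2-D unmixing oracle: the rotation maximizing |kurtosis|.

    For K=2 whitened data the unmixing matrix is a rotation up to
    permutation/sign; this scans theta in [0, pi) in ``step_deg`` steps and
    returns the rotation whose outputs maximize the summed absolute excess
    kurtosis.  Used as an independent check on infomax, never as the
    implementation.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] != 2:
        raise ConfigurationError("the rotation oracle is defined for K=2 only")
    thetas = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    best, best_val = None, -np.inf
    for th in thetas:
        c, s = math.cos(th), math.sin(th)
        R = np.array([[c, s], [-s, c]])
        U = R @ Y
        val = float(np.abs(stats.kurtosis(U, axis=1, fisher=True)).sum())
        if val > best_val:
            best_val, best = val, R
    return best
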