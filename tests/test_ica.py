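import itertools

import numpy as np
import pytest
from scipy import stats

from sbm import ica, preprocess, synthetic
from sbm.ica import (
    amari_index,
    center_and_whiten,
    compose_decomposition,
    decompose,
    infomax,
    match_components,
    reconstruction_error,
    rotation_kurtosis_oracle,
)
from sbm.volume import ConfigurationError


def _whiten2(X):
    Xc = X - X.mean(axis=1, keepdims=True)
    C = Xc @ Xc.T / X.shape[1]
    d, E = np.linalg.eigh(C)
    wh = E @ np.diag(d**-0.5) @ E.T
    return wh @ Xc, wh


class TestCenterAndWhiten:
    def test_whitened_covariance_identity(self, synthetic_run):
        _gt, _cohort, dm = synthetic_run
        Y, red = center_and_whiten(dm, K=4)
        cov = Y @ Y.T / Y.shape[1]
        np.testing.assert_allclose(cov, np.eye(4), atol=1e-8)

    def test_noise_free_retained_variance(self, grid):
        gt = synthetic.make_ground_truth(grid, K=4, seed=1, residual_noise_sd=0.0,
                                         site_effect_sd=0.0, sex_effect_sd=0.0)
        cohort = synthetic.sample_cohort(synthetic.scaled_age_bins(60), seed=2)
        dm = synthetic.synthesize(gt, cohort)
        _Y, red = center_and_whiten(dm, K=4)
        assert red.retained_variance > 0.999

    def test_k_beyond_rank_reports_rank(self, grid):
        gt = synthetic.make_ground_truth(grid, K=4, seed=3, residual_noise_sd=0.0,
                                         site_effect_sd=0.0, sex_effect_sd=0.0)
        cohort = synthetic.sample_cohort(synthetic.scaled_age_bins(30), seed=4)
        dm = synthetic.synthesize(gt, cohort)
        with pytest.raises(ConfigurationError, match="rank"):
            center_and_whiten(dm, K=10)

    def test_rank_one_whitened_is_standardized_loading(self, small_grid):
        rng = np.random.default_rng(5)
        w = rng.standard_normal(20)
        s = rng.standard_normal(small_grid.n_voxels)
        X = np.outer(w, s) + 7.0
        Y, red = center_and_whiten(X, K=1)
        wc = w - w.mean()
        # the single mixing column must align (+-) with the centred loading
        dec = compose_decomposition(X, red, np.ones((1, 1)))
        corr = np.corrcoef(dec.mixing[:, 0], wc)[0, 1]
        assert abs(corr) > 1 - 1e-10


class TestInfomax:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        S = rng.laplace(size=(2, 2000))
        Y, _ = _whiten2(S)
        W1, _ = infomax(Y, seed=3)
        W2, _ = infomax(Y, seed=3)
        np.testing.assert_array_equal(W1, W2)

    @pytest.mark.parametrize("seed", range(5))
    def test_separates_super_gaussian_pair(self, seed):
        """Laplace sources mixed by identity: unmixing ~ scaled permutation."""
        rng = np.random.default_rng(200 + seed)
        S = rng.laplace(size=(2, 5000))
        Y, wh = _whiten2(S)
        W, info = infomax(Y, seed=seed)
        assert amari_index(W @ wh) < 0.05

    def test_gaussian_pair_unidentifiable_but_returns(self):
        """Two i.i.d. Gaussians: any rotation whitens; result is returned
        (possibly with a non-convergence warning), never an exception."""
        rng = np.random.default_rng(9)
        S = rng.standard_normal((2, 4000))
        Y, _ = _whiten2(S)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W, info = infomax(Y, seed=1, max_iter=300)
        assert np.isfinite(W).all()
        assert info.iterations >= 1

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_rotation_kurtosis_oracle(self, seed):
        """Infomax matches the exhaustive-rotation max-|kurtosis| oracle on
        sparse (Bernoulli-Gaussian) sources."""
        rng = np.random.default_rng(50 + seed)
        S = (rng.random((2, 5000)) < 0.2) * rng.standard_normal((2, 5000))
        A = rng.standard_normal((2, 2))
        Y, _ = _whiten2(A @ S)
        W, _ = infomax(Y, seed=seed)
        R = rotation_kurtosis_oracle(Y, step_deg=0.5)
        assert amari_index(W @ np.linalg.inv(R)) < 0.05


class TestAmariIndex:
    def test_identity_and_scaled_permutation_are_zero(self):
        assert amari_index(np.eye(3)) == 0.0
        P = np.array([[0, 2.0, 0], [0, 0, -0.5], [3.0, 0, 0]])
        assert amari_index(P) == pytest.approx(0.0, abs=1e-12)

    def test_all_ones_is_maximal(self):
        assert amari_index(np.ones((2, 2))) == pytest.approx(1.0)

    def test_zero_row_rejected(self):
        with pytest.raises(ConfigurationError):
            amari_index(np.array([[0.0, 0.0], [1.0, 2.0]]))


@pytest.fixture(scope="module")
def decomp_and_data(synthetic_run):
    gt, cohort, dm = synthetic_run
    dm_adj = preprocess.residualize(
        dm, preprocess.build_confound_design(cohort)
    )
    return gt, cohort, dm_adj, decompose(dm_adj, K=4, seed=0)


class TestDecomposition:
    def test_reconstruction_identity(self, decomp_and_data):
        _gt, _cohort, dm_adj, dec = decomp_and_data
        assert reconstruction_error(dec, dm_adj) < 1e-6

    def test_canonical_form(self, decomp_and_data):
        *_, dec = decomp_and_data
        np.testing.assert_allclose(dec.sources.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(dec.sources.std(axis=1), 1.0, atol=1e-10)
        assert (stats.skew(dec.sources, axis=1) >= 0).all()
        ev = dec.explained_variance
        assert (np.diff(ev) <= 1e-12).all()

    def test_estimated_sources_decorrelated_for_independent_truth(self):
        """With truly independent sources the estimated source rows are
        mutually uncorrelated within 1e-2 after convergence.  (On spatially
        overlapping blob sources the ML unmixing tracks the true dependence
        instead; see the methods note.)"""
        rng = np.random.default_rng(77)
        S = (rng.random((3, 30000)) < 0.2) * rng.standard_normal((3, 30000))
        A = rng.standard_normal((10, 3))
        X = A @ S
        Y, red = center_and_whiten(X, K=3)
        W, info = infomax(Y, seed=0)
        dec = compose_decomposition(X, red, W)
        assert info.converged
        C = np.corrcoef(dec.sources)
        assert np.abs(C - np.eye(3)).max() < 1e-2

    def test_sign_flip_invariance_of_reconstruction(self, decomp_and_data):
        _gt, _cohort, dm_adj, dec = decomp_and_data
        recon = dec.mixing @ dec.sources
        flipped = (dec.mixing * -1) @ (dec.sources * -1)
        np.testing.assert_allclose(recon, flipped, atol=1e-12)


class TestMatchComponents:
    def _fake_decomp(self, sources, mixing):
        return ica.Decomposition(
            mixing=mixing, sources=sources, reduction=None, convergence=None,
            seed=0, explained_variance=np.arange(sources.shape[0])[::-1].astype(float),
        )

    def test_exact_match_identity_permutation(self, grid):
        S = synthetic.make_sources(grid, K=4, seed=20)
        dec = self._fake_decomp(S, np.eye(4))
        rep = match_components(dec, S)
        np.testing.assert_array_equal(np.sort(rep.permutation), np.arange(4))
        np.testing.assert_array_equal(rep.permutation, np.arange(4))
        np.testing.assert_allclose(rep.spatial_correlation, 1.0, atol=1e-12)
        # the cross-correlation matrix equals the truth's self-correlation,
        # so its Amari index reflects residual source overlap, not error
        assert rep.amari is not None and rep.amari < amari_index(
            np.ones((4, 4))
        )

    def test_permutation_and_sign_recovered(self, grid):
        S = synthetic.make_sources(grid, K=4, seed=21)
        perm = np.array([2, 0, 3, 1])
        flipped = S[perm].copy()
        flipped[1] *= -1
        dec = self._fake_decomp(flipped, np.eye(4))
        rep = match_components(dec, S)
        np.testing.assert_array_equal(rep.permutation, perm)
        assert rep.signs[1] == -1
        assert (rep.signs[[0, 2, 3]] == 1).all()

    def test_assignment_matches_exhaustive_search(self, grid):
        """Hungarian matching equals brute force over all 4! permutations."""
        rng = np.random.default_rng(22)
        S = synthetic.make_sources(grid, K=4, seed=22)
        noisy = S + 0.5 * rng.standard_normal(S.shape)
        dec = self._fake_decomp(noisy, np.eye(4))
        rep = match_components(dec, S)
        C = np.abs(ica._corr_rows(noisy, S))
        best = max(
            sum(C[i, p[i]] for i in range(4))
            for p in itertools.permutations(range(4))
        )
        assert rep.spatial_correlation.sum() == pytest.approx(best, abs=1e-12)

    def test_invariance_to_relabeling_and_rescaling(self, grid):
        """Relabeling truth or rescaling a source (with inverse loading
        rescale) leaves the matched correlation multiset unchanged."""
        S = synthetic.make_sources(grid, K=4, seed=23)
        rng = np.random.default_rng(23)
        est = S + 0.3 * rng.standard_normal(S.shape)
        dec = self._fake_decomp(est, np.eye(4))
        base = np.sort(match_components(dec, S).spatial_correlation)
        perm = np.array([3, 1, 0, 2])
        scaled = S[perm] * np.array([2.0, 1.0, 0.5, 1.0])[:, None]
        again = np.sort(match_components(dec, scaled).spatial_correlation)
        np.testing.assert_allclose(base, again, atol=1e-12)
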