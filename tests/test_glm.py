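"""GLM correctness: design construction, OLS, contrasts, and thresholding."""

import numpy as np
import pytest
from scipy import stats

from emomap import glm, synthetic_data as sd
from emomap.hrf import DEFAULT_HRF, double_gamma_hrf
from emomap.types import GridSpec, StatMap


class TestBuildDesign:
    def test_empty_blocks_gives_drift_plus_intercept(self):
        des = sd.DesignSpec(2.0, 200, (), ("a",))
        X = glm.build_design(des)
        assert all(n.startswith("dct_") or n == "intercept" for n in X.names)

    def test_column_matches_direct_convolution(self):
        """A single 20 s block column equals boxcar*HRF computed by direct
        convolution on a fine grid, independently of the packaged regressor."""
        tr, n = 2.0, 60
        des = sd.DesignSpec(tr, n, (sd.Block(0.0, 20.0, "a"),), ("a",))
        X = glm.build_design(des)
        dt = 0.01
        t_fine = np.arange(0, n * tr, dt)
        box = ((t_fine >= 0) & (t_fine < 20.0)).astype(float)
        h = double_gamma_hrf(np.arange(0, DEFAULT_HRF.duration_s, dt))
        conv = np.convolve(box, h)[: t_fine.size] * dt / (h.sum() * dt)
        oracle = conv[:: int(tr / dt)]
        col = X.column("a")
        # microtime discretisation differs (0.125 s vs 0.01 s grid): edges may
        # shift by one fine sample, so compare pointwise loosely and sums tightly
        assert np.abs(col - oracle).max() < 0.02
        assert abs(col.sum() - oracle.sum()) / oracle.sum() < 0.005

    def test_dct_column_count_rule(self):
        # 650 s run at a 128 s cutoff: floor(2*650/128) = 10 cosine columns
        des = sd.DesignSpec(2.0, 325, (), ("a",))
        X = glm.build_design(des, highpass_s=128.0)
        assert sum(n.startswith("dct_") for n in X.names) == 10
        assert glm.n_dct_columns(650.0, 128.0) == 10

    def test_cutoff_must_exceed_two_tr(self):
        des = sd.DesignSpec(2.0, 100, (), ("a",))
        with pytest.raises(ValueError, match="cutoff"):
            glm.build_design(des, highpass_s=4.0)


class TestScaleGlobal:
    def test_frame_means_rescaled_to_target(self):
        vol = np.ones((4, 4, 4, 2))
        vol[..., 0] *= 50
        vol[..., 1] *= 200
        out = glm.scale_global(vol, mask=np.ones((4, 4, 4), dtype=bool))
        assert np.allclose(out[..., 0].mean(), 100.0)
        assert np.allclose(out[..., 1].mean(), 100.0)

    def test_random_volume_means_equalised(self, rng):
        vol = rng.gamma(5.0, 20.0, size=(8, 8, 6, 20))
        out = glm.scale_global(vol)
        mean_img = vol.mean(axis=3)
        mask = mean_img > mean_img.mean() / 8.0
        means = out[mask].mean(axis=0)
        assert np.abs(means - 100.0).max() < 1e-10

    def test_zero_mean_frame_rejected(self):
        vol = np.zeros((4, 4, 4, 3))
        with pytest.raises(ValueError):
            glm.scale_global(vol, mask=np.ones((4, 4, 4), dtype=bool))


class TestSmoothGaussian:
    def test_delta_matches_analytic_kernel(self):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        img = np.zeros((21, 21, 21))
        img[10, 10, 10] = 1.0
        fwhm = 6.0
        out = glm.smooth_gaussian(img, fwhm, affine)
        sigma_vox = fwhm / (2 * np.sqrt(2 * np.log(2))) / 2.0
        peak = (1.0 / (np.sqrt(2 * np.pi) * sigma_vox)) ** 3
        assert abs(out[10, 10, 10] - peak) / peak < 1e-3
        assert abs(out.sum() - 1.0) < 1e-6  # mass conserved away from edges

    def test_zero_fwhm_is_identity(self, rng):
        img = rng.normal(size=(8, 8, 8))
        out = glm.smooth_gaussian(img, 0.0, np.eye(4))
        assert np.array_equal(out, img)

    def test_constant_image_unchanged_in_interior(self):
        img = np.full((20, 20, 20), 3.5)
        out = glm.smooth_gaussian(img, 4.0, np.diag([2.0, 2.0, 2.0, 1.0]))
        assert np.allclose(out[8:12, 8:12, 8:12], 3.5, atol=1e-10)

    def test_sheared_affine_rejected(self):
        affine = np.eye(4)
        affine[0, 1] = 0.5
        with pytest.raises(ValueError, match="shear"):
            glm.smooth_gaussian(np.zeros((4, 4, 4)), 4.0, affine)


class TestFirstLevel:
    def test_noiseless_beta_recovery(self, grid):
        truth = sd.default_ground_truth(grid, noise_sd=0.0, drift_amplitude=0.0, baseline=0.0)
        des = sd.localizer_design("motor", n_repeats=2)
        vol = sd.simulate_run(des, truth, grid)
        fit = glm.fit_first_level(vol, glm.build_design(des), grid.affine)
        eff = glm.contrast_effect_map(fit, glm.ContrastSpec({"motor_hands": 1.0}))
        roi = truth.roi_mask("hands", "motor", grid)
        assert np.abs(eff.data[roi] - 1.0).max() < 1e-8

    def test_ols_matches_per_voxel_lstsq(self, rng):
        """The vectorised fit agrees with an independent per-voxel least
        squares solve to near machine precision."""
        n, p, nvox = 40, 4, 30
        X = glm.DesignMatrix(rng.normal(size=(n, p)), [f"c{i}" for i in range(p)], "double_gamma", 128.0)
        vol = rng.normal(size=(5, 3, 2, n))
        fit = glm.fit_first_level(vol, X, np.eye(4))
        Y = vol.reshape(-1, n)
        for v in range(nvox):
            beta, res, *_ = np.linalg.lstsq(X.matrix, Y[v], rcond=None)
            assert np.abs(fit.betas.reshape(-1, p)[v] - beta).max() < 1e-10
            resid = Y[v] - X.matrix @ beta
            assert abs(fit.resvar.ravel()[v] - resid @ resid / (n - p)) < 1e-10

    def test_duplicated_column_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 2] = X[:, 1]
        dm = glm.DesignMatrix(X, ["a", "b", "c"], "double_gamma", 128.0)
        with pytest.raises(ValueError, match="rank deficient"):
            glm.fit_first_level(np.zeros((2, 2, 2, 20)), dm, np.eye(4))

    def test_frame_count_mismatch_rejected(self):
        dm = glm.DesignMatrix(np.ones((10, 1)), ["intercept"], "double_gamma", 128.0)
        with pytest.raises(ValueError, match="frames"):
            glm.fit_first_level(np.zeros((2, 2, 2, 12)), dm, np.eye(4))


class TestContrastTmap:
    @staticmethod
    def _hand_case():
        # six timepoints, two regressors: hand-computable scalar OLS
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 3.0], [1.0, 4.0], [1.0, 5.0]])
        y = np.array([1.0, 2.2, 2.9, 4.1, 5.2, 5.8])
        return X, y

    def test_matches_scalar_formula(self):
        X, y = self._hand_case()
        dm = glm.DesignMatrix(X, ["intercept", "slope"], "double_gamma", 128.0)
        vol = y.reshape(1, 1, 1, -1)
        fit = glm.fit_first_level(vol, dm, np.eye(4))
        tmap = glm.contrast_tmap(fit, glm.ContrastSpec({"slope": 1.0}))
        # scalar formulas for simple linear regression
        xbar = X[:, 1].mean()
        sxx = ((X[:, 1] - xbar) ** 2).sum()
        slope = ((X[:, 1] - xbar) * (y - y.mean())).sum() / sxx
        resid = y - (y.mean() - slope * xbar) - slope * X[:, 1]
        s2 = (resid**2).sum() / 4
        t_expected = slope / np.sqrt(s2 / sxx)
        assert abs(tmap.data[0, 0, 0] - t_expected) < 1e-10
        assert tmap.df == 4

    def test_sign_flip_negates_t(self, rng):
        dm = glm.DesignMatrix(
            np.column_stack([np.ones(30), rng.normal(size=30)]), ["i", "x"], "double_gamma", 128.0
        )
        vol = rng.normal(size=(3, 3, 2, 30))
        fit = glm.fit_first_level(vol, dm, np.eye(4))
        t1 = glm.contrast_tmap(fit, glm.ContrastSpec({"x": 1.0}))
        t2 = glm.contrast_tmap(fit, glm.ContrastSpec({"x": -1.0}))
        assert np.allclose(t1.data, -t2.data)

    def test_zero_variance_voxel_flagged(self):
        dm = glm.DesignMatrix(
            np.column_stack([np.ones(6), np.arange(6.0)]), ["i", "x"], "double_gamma", 128.0
        )
        vol = np.zeros((1, 1, 1, 6))
        vol[0, 0, 0] = 2.0 * np.arange(6.0)  # exact fit, zero residual
        fit = glm.fit_first_level(vol, dm, np.eye(4))
        tmap = glm.contrast_tmap(fit, glm.ContrastSpec({"x": 1.0}))
        assert tmap.data[0, 0, 0] == 0.0
        assert tmap.degenerate_mask[0, 0, 0]

    def test_scaling_invariance_after_global_scaling(self, grid):
        """Multiplying a run by k > 0 leaves contrast t-maps unchanged once
        proportional scaling has normalised the global signal."""
        truth = sd.default_ground_truth(grid, noise_sd=1.0)
        des = sd.localizer_design("motor", n_repeats=1)
        vol = sd.simulate_run(des, truth, grid, np.random.default_rng(3))
        X = glm.build_design(des)
        mask = np.ones(grid.shape, dtype=bool)
        t_maps = []
        for k in (1.0, 7.3):
            scaled = glm.scale_global(k * vol, mask=mask)
            fit = glm.fit_first_level(scaled, X, grid.affine)
            t_maps.append(glm.contrast_tmap(fit, glm.ContrastSpec({"motor_hands": 1.0})).data)
        assert np.allclose(t_maps[0], t_maps[1], atol=1e-8)


class TestSecondLevel:
    def test_identical_maps_flagged_degenerate(self, small_grid):
        m = StatMap(np.full(small_grid.shape, 0.7), small_grid.affine, "beta")
        out = glm.second_level_ttest([m, m, m, m])
        assert np.all(out.data == 0)
        assert np.all(out.degenerate_mask)

    def test_two_subjects_rejected(self, small_grid):
        m = StatMap(np.zeros(small_grid.shape), small_grid.affine, "beta")
        with pytest.raises(ValueError, match="at least 3"):
            glm.second_level_ttest([m, m])

    def test_grid_mismatch_rejected(self, small_grid, grid):
        a = StatMap(np.zeros(small_grid.shape), small_grid.affine, "beta")
        b = StatMap(np.zeros(grid.shape), grid.affine, "beta")
        with pytest.raises(ValueError, match="common"):
            glm.second_level_ttest([a, a, b])

    def test_mean_t_matches_analytic_expectation(self, rng):
        """Subject effects N(0.5, 1) with n=20: the mean t across many voxels
        approaches 0.5*sqrt(20) times the small-sample t bias factor."""
        n, nvox = 20, 4000
        data = rng.normal(0.5, 1.0, size=(n, nvox))
        t, _ = glm.one_sample_t(data)
        df = n - 1
        from scipy.special import gammaln

        bias = np.sqrt(df / 2.0) * np.exp(gammaln((df - 1) / 2.0) - gammaln(df / 2.0))
        expected = 0.5 * np.sqrt(n) * bias
        assert abs(t.mean() - expected) < 4 * 1.1 / np.sqrt(nvox)


class TestThresholdCluster:
    def _tmap(self, data, df, affine=None):
        return StatMap(data, affine if affine is not None else np.eye(4), "tstat", df=df)

    def test_zero_map_empty(self):
        out = glm.threshold_cluster(self._tmap(np.zeros((6, 6, 6)), 10), 0.001)
        assert out.count() == 0

    def test_voxel_p_one_keeps_everything(self, rng):
        t = self._tmap(rng.normal(size=(6, 6, 6)), 10)
        out = glm.threshold_cluster(t, 1.0, tail="two-sided")
        assert out.count() == 6**3

    def test_too_few_permutations_rejected(self, rng):
        t = self._tmap(rng.normal(size=(4, 4, 4)), 9)
        subj = rng.normal(size=(10, 4, 4, 4))
        with pytest.raises(ValueError, match="100 permutations"):
            glm.threshold_cluster(t, 0.001, 0.05, subject_maps=subj, n_permutations=50)

    def test_planted_cluster_survives_correction(self, rng):
        """A strong 50-voxel planted effect survives sign-flip cluster
        correction while pure-noise background does not."""
        shape, n = (12, 12, 10), 15
        signal = np.zeros(shape)
        signal[3:8, 4:9, 4:6] = 1.0  # 50 voxels
        data = rng.normal(0, 1, size=(n, *shape)) * 0.3 + signal
        stack = [StatMap(d, np.eye(4), "beta") for d in data]
        tmap = glm.second_level_ttest(stack)
        out = glm.threshold_cluster(tmap, 0.001, 0.05, subject_maps=stack, n_permutations=500, rng=rng)
        planted = signal > 0
        assert np.count_nonzero(out.data.astype(bool) & planted) >= 45
        assert np.count_nonzero(out.data.astype(bool) & ~planted) <= 5

    def test_signflip_t_matches_direct_computation(self, rng):
        data = rng.normal(size=(8, 50))
        signs = rng.choice([-1.0, 1.0], size=(20, 8))
        t_fast = glm.signflip_t_stack(data, signs)
        for i in range(20):
            flipped = data * signs[i][:, None]
            t_direct, _ = glm.one_sample_t(flipped)
            assert np.abs(t_fast[i] - t_direct).max() < 1e-10
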