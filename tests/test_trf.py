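"""TRF estimation: identity systems, regularization, CV, mismatched null."""

import numpy as np
import pytest

from hftag import neurosim, trf
from hftag.trf import TRFHyperParams

SR = 250.0


def simulate_trials(n_trials, n_samples, kernel, lags, noise_sd=0.0,
                    env="white", seed=0, n_channels=None):
    rng = np.random.default_rng(seed)
    n_channels = kernel.shape[0]
    envs, resps = [], []
    for _ in range(n_trials):
        if env == "white":
            s = rng.standard_normal(n_samples)
        else:
            s = neurosim.make_attended_envelope(rng, n_samples, SR)
        z = (s - s.mean()) / s.std()
        r = neurosim._convolve_trf(kernel, lags, z, SR)
        if noise_sd:
            r = r + noise_sd * neurosim.make_pink_noise(rng, n_channels,
                                                        n_samples, SR)
        envs.append(s)
        resps.append(r)
    return envs, resps


@pytest.fixture(scope="module")
def true_kernel():
    return neurosim.default_trf_kernel(4, SR)


class TestEstimateTrf:
    def test_pure_delay_recovers_unit_impulse(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(8000)
        delay = int(0.100 * SR)
        z = (s - s.mean()) / s.std()
        resp = np.zeros((1, 8000))
        resp[0, delay:] = z[: 8000 - delay]
        model = trf.estimate_trf([s], [resp], sample_rate=SR,
                                 compute_power=False)
        peak = np.argmax(np.abs(model.kernel[0]))
        assert model.lags[peak] == pytest.approx(0.100, abs=1e-9)
        side_lobe = 1 - model.kernel[0, peak]**2 / np.sum(model.kernel[0]**2)
        assert side_lobe < 0.05

    def test_full_tolerance_equals_direct_solve_oracle(self, true_kernel):
        kernel, lags = true_kernel
        envs, resps = simulate_trials(3, 2000, kernel, lags, noise_sd=0.5,
                                      seed=2)
        model = trf.estimate_trf(envs, resps, sample_rate=SR,
                                 hp=TRFHyperParams(tolerance=1.0),
                                 compute_power=False)
        # oracle: explicit lagged design matrix and normal-equation solve
        lag_samples = np.arange(round(-0.050 * SR), round(0.400 * SR) + 1)
        xtx = 0.0
        xty = 0.0
        for s, r in zip(envs, resps):
            z = (s - s.mean()) / s.std()
            X = np.zeros((z.size, lag_samples.size))
            for j, l in enumerate(lag_samples):
                if l >= 0:
                    X[l:, j] = z[: z.size - l]
                else:
                    X[:l, j] = z[-l:]
            xtx = xtx + X.T @ X
            xty = xty + X.T @ r.T
        expected = np.linalg.solve(xtx, xty).T
        assert np.allclose(model.kernel, expected, rtol=1e-8, atol=1e-10)

    def test_recovery_at_snr_zero_db(self, true_kernel):
        kernel, lags = true_kernel
        # SNR 0 dB: noise sd equals the per-channel response sd
        sig_sd = simulate_trials(1, 4000, kernel, lags, seed=3)[1][0].std()
        envs, resps = simulate_trials(20, 4000, kernel, lags,
                                      noise_sd=sig_sd, seed=3)
        model = trf.estimate_trf(envs, resps, sample_rate=SR,
                                 compute_power=False)
        r = np.corrcoef(model.kernel.ravel(), kernel.ravel())[0, 1]
        assert r > 0.9

    def test_estimator_linearity_in_response(self, true_kernel):
        kernel, lags = true_kernel
        envs, resps = simulate_trials(4, 1500, kernel, lags, noise_sd=0.3,
                                      seed=4)
        m1 = trf.estimate_trf(envs, resps, sample_rate=SR, compute_power=False)
        m2 = trf.estimate_trf(envs, [3.5 * r for r in resps], sample_rate=SR,
                              compute_power=False)
        assert np.allclose(m2.kernel, 3.5 * m1.kernel, rtol=1e-10)

    def test_constant_envelope_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            trf.estimate_trf([np.ones(500)], [np.zeros((1, 500))],
                             sample_rate=SR)

    def test_pure_noise_predictive_power_near_zero(self, rng):
        envs = [rng.standard_normal(2000) for _ in range(6)]
        resps = [rng.standard_normal((2, 2000)) for _ in range(6)]
        model = trf.estimate_trf(envs, resps, sample_rate=SR,
                                 hp=TRFHyperParams(tolerance=0.99))
        assert np.all(np.abs(model.predictive_power) < 0.1)

    def test_sparseness_zeroes_unstable_coefficients(self, true_kernel):
        kernel, lags = true_kernel
        envs, resps = simulate_trials(8, 2000, kernel, lags, noise_sd=2.0,
                                      seed=6)
        dense = trf.estimate_trf(envs, resps, sample_rate=SR,
                                 compute_power=False)
        sparse = trf.estimate_trf(envs, resps, sample_rate=SR,
                                  hp=TRFHyperParams(sparseness=2.0),
                                  compute_power=False)
        n_zero = np.sum(sparse.kernel == 0)
        assert n_zero > 0
        assert n_zero < sparse.kernel.size  # true structure survives
        nz = sparse.kernel != 0
        assert np.array_equal(sparse.kernel[nz], dense.kernel[nz])

    def test_hyperparameter_validation(self):
        with pytest.raises(ValueError):
            TRFHyperParams(tolerance=0.0)
        with pytest.raises(ValueError):
            TRFHyperParams(sparseness=-1.0)


class TestJackknifeCV:
    def test_single_grid_point_returned(self, true_kernel):
        kernel, lags = true_kernel
        envs, resps = simulate_trials(4, 1000, kernel, lags, seed=7)
        hp = TRFHyperParams(tolerance=0.9)
        best, table = trf.jackknife_cv(envs, resps, sample_rate=SR, grid=[hp])
        assert best == hp
        assert len(table) == 1

    def test_empty_grid_rejected(self, true_kernel):
        kernel, lags = true_kernel
        envs, resps = simulate_trials(3, 500, kernel, lags)
        with pytest.raises(ValueError, match="empty"):
            trf.jackknife_cv(envs, resps, sample_rate=SR, grid=[])

    def test_needs_three_trials(self, true_kernel):
        kernel, lags = true_kernel
        envs, resps = simulate_trials(2, 500, kernel, lags)
        with pytest.raises(ValueError, match="3 trials"):
            trf.jackknife_cv(envs, resps, sample_rate=SR)

    def test_regularization_selected_only_when_noise_present(self, true_kernel):
        kernel, lags = true_kernel
        grid = [TRFHyperParams(tolerance=1.0), TRFHyperParams(tolerance=0.95)]
        # noiseless, white stimulus: the un-regularized solve wins
        envs, resps = simulate_trials(5, 1500, kernel, lags, seed=8)
        best, _ = trf.jackknife_cv(envs, resps, sample_rate=SR, grid=grid)
        assert best.tolerance == 1.0
        # noisy, low-passed stimulus: truncation helps
        envs, resps = simulate_trials(5, 1500, kernel, lags, noise_sd=20.0,
                                      env="lowpass", seed=9)
        best, table = trf.jackknife_cv(envs, resps, sample_rate=SR, grid=grid)
        assert best.tolerance < 1.0
        assert table["cv_score"].iloc[1] > table["cv_score"].iloc[0]

    def test_scores_deterministic(self, true_kernel):
        kernel, lags = true_kernel
        envs, resps = simulate_trials(4, 800, kernel, lags, noise_sd=1.0,
                                      seed=10)
        _, t1 = trf.jackknife_cv(envs, resps, sample_rate=SR)
        _, t2 = trf.jackknife_cv(envs, resps, sample_rate=SR)
        assert t1.equals(t2)


class TestPredictivePowerNull:
    def test_matched_signal_significant(self, true_kernel):
        kernel, lags = true_kernel
        envs, resps = simulate_trials(8, 2000, kernel, lags, noise_sd=1.0,
                                      seed=11)
        res = trf.predictive_power_null(envs, resps, n_perm=199, seed=0,
                                        hp=TRFHyperParams(tolerance=0.99))
        assert res.p < 0.01

    def test_min_p_with_19_permutations(self, true_kernel):
        kernel, lags = true_kernel
        envs, resps = simulate_trials(5, 1500, kernel, lags, noise_sd=0.5,
                                      seed=12)
        res = trf.predictive_power_null(envs, resps, n_perm=19, seed=0)
        assert res.p == pytest.approx(0.05)

    def test_too_few_trials_rejected(self, true_kernel):
        kernel, lags = true_kernel
        envs, resps = simulate_trials(2, 500, kernel, lags)
        with pytest.raises(ValueError, match="derangement"):
            trf.predictive_power_null(envs, resps)

    def test_null_p_uniform_under_no_signal(self):
        # responses are fresh noise: p-values should be uniform
        from scipy import stats
        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(200):
            envs = [rng.standard_normal(400) for _ in range(5)]
            resps = [rng.standard_normal((2, 400)) for _ in range(5)]
            res = trf.predictive_power_null(envs, resps, lags=(0.0, 0.080),
                                            sample_rate=100.0, n_perm=39,
                                            seed=int(rng.integers(2**31)))
            pvals.append(res.p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCompareTrfConditions:
    def test_identical_model_sets_no_clusters(self, true_kernel):
        kernel, lags = true_kernel
        envs, resps = simulate_trials(3, 800, kernel, lags, noise_sd=1.0,
                                      seed=14)
        models = [trf.estimate_trf(envs, resps, sample_rate=SR,
                                   compute_power=False) for _ in range(6)]
        adj = np.ones((4, 4), dtype=bool)
        res = trf.compare_trf_conditions(models, models, adj, n_perm=20,
                                         seed=0)
        assert res.clusters == []

    def test_lag_axis_mismatch_rejected(self, true_kernel):
        kernel, lags = true_kernel
        envs, resps = simulate_trials(3, 800, kernel, lags, seed=15)
        m1 = trf.estimate_trf(envs, resps, sample_rate=SR, compute_power=False)
        m2 = trf.estimate_trf(envs, resps, lags=(0.0, 0.2), sample_rate=SR,
                              compute_power=False)
        with pytest.raises(ValueError, match="lag axis"):
            trf.compare_trf_conditions([m1], [m2], np.ones((4, 4), bool))

    def test_roi_average_kernels(self, rng):
        kernels = rng.normal(size=(5, 6, 10))
        roi = trf.roi_average_kernels(kernels, {"A": [0, 1], "B": [2, 3, 4]})
        assert roi.shape == (5, 2, 10)
        assert np.allclose(roi[:, 0], kernels[:, :2].mean(axis=1))
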