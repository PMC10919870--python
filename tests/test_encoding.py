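"""GLM design construction, OLS fitting against the normal-equations
oracle, prediction, Spearman evaluation, and split-half reliability."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from disface import encoding
from disface.hrf import convolve_events, double_gamma_hrf
from disface.synth import responses as resp


class TestBuildDesign:
    def test_hrf_column_count_matches_regressor_list(self):
        """24 latent dims + 20 test indicators + face bias + drift + 3 motion
        = 49 columns for one run."""
        rng = np.random.default_rng(0)
        train_ids = [f"s{i}" for i in range(10)]
        test_ids = [f"t{i}" for i in range(20)]
        events = pd.DataFrame({
            "onset": np.arange(30) * 3.0,
            "duration": 1.0,
            "stimulus_id": train_ids + test_ids,
        })
        runs = [{"events": events, "n_timepoints": 60,
                 "motion": rng.normal(size=(3, 60))}]
        lat = pd.DataFrame(rng.normal(size=(10, 24)), index=train_ids)
        design = encoding.build_design_hrf(runs, lat, test_ids, TR=2.0)
        assert design.values.shape[1] == 24 + 20 + 1 + 1 + 3 == 49
        assert design.column_roles.count("face_bias") == 1

    def test_amplitude_zero_latents_give_zero_weights(self):
        X = encoding.build_design_amplitude(np.zeros((30, 4)))
        rng = np.random.default_rng(1)
        fit = encoding.fit_glm(X, rng.normal(size=(30, 5)))
        assert np.all(fit.W == 0)

    def test_hrf_single_event_column_is_shifted_scaled_kernel(self):
        """One event: the latent column equals the HRF kernel shifted to the
        onset and scaled by the latent value (direct convolution oracle)."""
        lat = pd.DataFrame([[2.5]], index=["a"])
        events = pd.DataFrame({"onset": [6.0], "duration": [1.0],
                               "stimulus_id": ["a"]})
        runs = [{"events": events, "n_timepoints": 30}]
        design = encoding.build_design_hrf(runs, lat, [], TR=2.0)
        col = design.values[:, 0]
        t = np.arange(30) * 2.0 - 6.0
        expected = 2.5 * np.where(t > 32.0, 0.0, double_gamma_hrf(t))
        np.testing.assert_allclose(col, expected, atol=1e-9)

    def test_missing_latent_row_names_stimulus(self):
        events = pd.DataFrame({"onset": [3.0], "duration": [1.0],
                               "stimulus_id": ["ghost"]})
        lat = pd.DataFrame(np.zeros((1, 2)), index=["a"])
        with pytest.raises(ValueError, match="ghost"):
            encoding.build_design_hrf([{"events": events, "n_timepoints": 10}],
                                      lat, [], TR=2.0)


class TestFitGlm:
    def test_noiseless_recovery_is_exact(self, factors_only_dataset,
                                         ground_truth):
        truth = resp.GroundTruthEncoding(
            W_star=ground_truth.W_star, b_star=ground_truth.b_star,
            drift_coefs=ground_truth.drift_coefs,
            motion_coefs=ground_truth.motion_coefs,
            noise_sd=np.full(ground_truth.n_voxels, 1e-12),
        )
        X = factors_only_dataset.train_factors
        Y = resp.simulate_responses(X, truth, seed=0)
        fit = encoding.fit_glm(encoding.build_design_amplitude(X), Y)
        scale = max(np.abs(truth.W_star).max(), 1.0)
        assert np.abs(fit.W - truth.W_star).max() / scale < 1e-6
        assert np.abs(fit.b - truth.b_star).max() < 1e-6

    def test_pure_drift_recovered_as_nuisance(self):
        rng = np.random.default_rng(0)
        lat = pd.DataFrame(rng.normal(size=(20, 2)),
                           index=[f"s{i}" for i in range(20)])
        events = pd.DataFrame({"onset": np.arange(20) * 3.0, "duration": 1.0,
                               "stimulus_id": lat.index})
        runs = [{"events": events, "n_timepoints": 40}]
        design = encoding.build_design_hrf(runs, lat * 0.0, [], TR=2.0)
        drift = np.linspace(-0.5, 0.5, 40)
        Y = np.outer(drift, [2.0, -3.0])
        fit = encoding.fit_glm(design, Y)
        assert np.abs(fit.W).max() < 1e-8
        np.testing.assert_allclose(fit.nuisance["drift:0"], [2.0, -3.0],
                                   atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        X = encoding.build_design_amplitude(rng.normal(size=(50, 6)),
                                            rng.normal(size=(5, 6)))
        Y = rng.normal(size=(55, 7))
        fit = encoding.fit_glm(X, Y)
        A = X.values
        beta_oracle = np.linalg.solve(A.T @ A, A.T @ Y)
        np.testing.assert_allclose(fit.W, beta_oracle[:6], atol=1e-8)
        np.testing.assert_allclose(fit.b, beta_oracle[-1], atol=1e-8)
        # residual orthogonality
        resid = Y - A @ np.vstack([fit.W,
                                   [fit.nuisance[f"test_image:{i}"]
                                    for i in range(5)],
                                   fit.b[None, :]])
        assert np.abs(A.T @ resid).max() < 1e-8

    def test_rank_deficiency_warns(self):
        X = encoding.DesignMatrix(
            values=np.column_stack([np.ones(10), np.ones(10), np.arange(10)]),
            column_roles=["latent:0", "latent:1", "face_bias"], mode="amplitude")
        with pytest.warns(UserWarning, match="rank"):
            encoding.fit_glm(X, np.random.default_rng(0).normal(size=(10, 2)))


class TestPredictTest:
    def test_zero_latents_predict_bias(self):
        fit = encoding.EncodingFit(W=np.ones((3, 4)), b=np.arange(4.0))
        pred = encoding.predict_test(fit, np.zeros((5, 3)))
        np.testing.assert_array_equal(pred, np.tile(np.arange(4.0), (5, 1)))

    def test_identity_case(self):
        fit = encoding.EncodingFit(W=np.eye(4), b=np.zeros(4))
        np.testing.assert_array_equal(encoding.predict_test(fit, np.eye(4)),
                                      np.eye(4))

    def test_two_by_two_hand_computation(self):
        W = np.array([[1.0, -2.0], [3.0, 0.5]])
        b = np.array([10.0, -1.0])
        X = np.array([[2.0, 1.0], [0.0, -1.0]])
        expected = np.array([[2 + 3 + 10, -4 + 0.5 - 1],
                             [-3 + 10, -0.5 - 1]])
        np.testing.assert_allclose(encoding.predict_test(
            encoding.EncodingFit(W=W, b=b), X), expected)


class TestEvaluate:
    def test_perfect_and_reversed_predictions(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=(20, 6))
        assert np.allclose(encoding.evaluate(obs, obs).per_voxel_r, 1.0)
        assert np.allclose(encoding.evaluate(-obs, obs).per_voxel_r, -1.0)

    def test_matches_scipy_spearman_oracle(self):
        rng = np.random.default_rng(1)
        pred = rng.normal(size=(20, 5))
        obs = rng.normal(size=(20, 5))
        r, _ = encoding.spearman_columns(pred, obs)
        for v in range(5):
            assert r[v] == pytest.approx(spearmanr(pred[:, v], obs[:, v])[0],
                                         abs=1e-12)

    def test_constant_column_flagged_zero(self):
        pred = np.ones((10, 2))
        pred[:, 1] = np.arange(10)
        obs = np.random.default_rng(2).normal(size=(10, 2))
        with pytest.warns(UserWarning, match="constant"):
            res = encoding.evaluate(pred, obs)
        assert res.per_voxel_r[0] == 0.0 and res.constant_flags[0]

    def test_roi_means(self):
        rng = np.random.default_rng(3)
        obs = rng.normal(size=(20, 4))
        res = encoding.evaluate(obs, obs, roi_labels=np.array(["A", "A", "B", "B"]))
        assert res.roi_means == {"A": pytest.approx(1.0), "B": pytest.approx(1.0)}


class TestSplitHalf:
    def test_zero_noise_reliability_one(self):
        rng = np.random.default_rng(0)
        clean = rng.normal(size=(20, 5))
        trials = np.tile(clean, (8, 1, 1))
        rel = encoding.split_half_reliability(trials, n_splits=5, seed=1)
        np.testing.assert_allclose(rel, 1.0)

    def test_pure_noise_reliability_near_zero(self):
        rng = np.random.default_rng(1)
        trials = rng.normal(size=(40, 20, 30))
        rel = encoding.split_half_reliability(trials, n_splits=100, seed=2)
        assert abs(rel.mean()) < 0.1

    def test_requires_two_repeats(self):
        with pytest.raises(ValueError, match="repeats"):
            encoding.split_half_reliability(np.zeros((1, 20, 3)))


class TestAmplitudeHrfEquivalence:
    def test_same_weights_from_both_design_modes(self):
        """Noiseless data: fitting repeat-averaged amplitudes and fitting the
        full time series recover the same W."""
        rng = np.random.default_rng(4)
        truth = resp.GroundTruthEncoding(
            W_star=rng.normal(size=(3, 5)), b_star=rng.normal(size=5),
            drift_coefs=rng.normal(size=(1, 5)) * 0.1,
            motion_coefs=rng.normal(size=(3, 5)) * 0.1,
            noise_sd=np.full(5, 1e-12),
        )
        train = rng.normal(size=(60, 3))
        test = rng.normal(size=(4, 3))
        train_ids = [f"train_{i:05d}" for i in range(60)]
        test_ids = [f"test_{i:02d}" for i in range(4)]
        sess = resp.simulate_timeseries(train, test, truth, TR=2.0, seed=5,
                                        test_repeats=3)
        lat = pd.DataFrame(train, index=train_ids)
        design_h = encoding.build_design_hrf(
            [{"events": r["events"], "series": r["series"],
              "motion": r["motion"]} for r in sess.runs],
            lat, test_ids, TR=2.0)
        Y = np.vstack([r["series"] for r in sess.runs])
        fit_h = encoding.fit_glm(design_h, Y)

        design_a = encoding.build_design_amplitude(train)
        fit_a = encoding.fit_glm(design_a, sess.averaged_train)
        assert np.abs(fit_h.W - fit_a.W).max() < 1e-4
        assert np.abs(fit_h.b - fit_a.b).max() < 1e-4


class TestRecoveryAcrossSnr:
    def test_recovery_monotone_in_snr(self, factors_only_dataset):
        X = factors_only_dataset.train_factors[:300]
        medians = []
        for noise in (2.0, 0.5, 0.1):
            truth = resp.make_ground_truth(8, 40, seed=6, noise_sd=noise,
                                           single_dim_fraction=0.0)
            Y = resp.simulate_responses(X, truth, seed=7)
            fit = encoding.fit_glm(encoding.build_design_amplitude(X), Y)
            cors = [np.corrcoef(fit.W[:, v], truth.W_star[:, v])[0, 1]
                    for v in range(40)]
            medians.append(np.median(cors))
        assert medians[0] < medians[1] < medians[2]
        assert medians[2] > 0.95
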