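"""VAE objectives, training reproducibility, traversals, the hyperparameter
grid, and the disentanglement gap score."""

import numpy as np
import pytest

from disface import dvae


def _untrained(latent_dim=4, side=32, seed=0, family="beta_vae", **kw):
    cfg = dvae.ModelConfig(family=family, latent_dim=latent_dim,
                           image_side=side, seed=seed, **kw)
    rng = np.random.default_rng(seed)
    params = dvae._init_params(cfg, rng)
    disc = dvae._init_disc(cfg, rng) if family == "factor_vae" else None
    return dvae.TrainedModel(params=params, disc_params=disc, config=cfg)


class TestEncodeDecode:
    def test_encode_deterministic(self, trained_ci_model):
        model, ds = trained_ci_model
        a = dvae.encode(model, ds.test_images[0])
        b = dvae.encode(model, ds.test_images[0])
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_untrained_zero_head_gives_prior_posterior(self):
        model = _untrained()
        mu, logvar = dvae.encode(model, np.random.default_rng(0).random((32, 32)))
        assert np.all(mu == 0) and np.all(logvar == 0)

    def test_latent_matrix_shape_for_test_set(self, trained_ci_model):
        model, ds = trained_ci_model
        lat = dvae.extract_latents(model, ds.test_images, ds.test_ids)
        assert lat.values.shape == (20, model.config.latent_dim)
        assert lat.stimulus_ids == ds.test_ids

    def test_shape_mismatch_rejected(self, trained_ci_model):
        model, _ = trained_ci_model
        with pytest.raises(ValueError, match="side"):
            dvae.encode(model, np.zeros((16, 16)))


class TestLossTerms:
    def test_kl_closed_form_values(self):
        # q = prior -> 0; unit mean shift in one dim -> 1/2
        assert dvae.kl_to_prior(np.zeros(4), np.zeros(4))[0] == 0.0
        mu = np.array([1.0, 0.0, 0.0, 0.0])
        assert dvae.kl_to_prior(mu, np.zeros(4))[0] == pytest.approx(0.5)

    def test_kl_nonnegative_on_random_posteriors(self):
        rng = np.random.default_rng(0)
        kl = dvae.kl_to_prior(rng.normal(size=(1000, 6)),
                              rng.normal(size=(1000, 6)))
        assert np.all(kl >= 0)

    def test_gamma_zero_factor_vae_equals_standard_vae(self):
        """A FactorVAE with gamma=0 and a beta-VAE with beta=1 compute the
        same objective on the same parameters and batch."""
        rng = np.random.default_rng(1)
        batch = rng.random((16, 32, 32))
        m_f = _untrained(family="factor_vae", gamma=0.0, seed=2)
        m_b = _untrained(family="beta_vae", beta=1.0, seed=2)
        lf = dvae.loss_terms(m_f, batch, seed=9)
        lb = dvae.loss_terms(m_b, batch, seed=9)
        assert lf["objective"] == pytest.approx(lb["objective"], abs=1e-6)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            dvae.loss_terms(_untrained(), np.zeros((0, 32, 32)))


class TestTrain:
    def test_seeded_training_reproducible(self, small_dataset):
        cfg = dvae.ModelConfig(latent_dim=4, epochs=2, image_side=32, seed=5)
        a = dvae.train(cfg, small_dataset.train_images)
        b = dvae.train(cfg, small_dataset.train_images)
        assert a.training_log == b.training_log
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_log_length_and_holdout_improvement(self, trained_ci_model):
        model, _ = trained_ci_model
        log = model.training_log
        assert len(log) == model.config.epochs
        assert log[-1]["holdout_reconstruction"] < log[0]["holdout_reconstruction"]

    def test_reconstruction_beats_mean_image_baseline(self, trained_ci_model):
        model, ds = trained_ci_model
        x = ds.train_images.reshape(len(ds.train_images), -1)
        mu, _ = dvae.encode(model, ds.train_images)
        recon = dvae.decode(model, mu).reshape(x.shape)
        model_mse = np.mean((recon - x) ** 2)
        baseline_mse = np.mean((x.mean(axis=0) - x) ** 2)
        assert model_mse < baseline_mse

    def test_divergence_aborts_with_diagnostic(self, small_dataset):
        cfg = dvae.ModelConfig(latent_dim=4, epochs=3, image_side=32,
                               learning_rate=1e4, seed=0)
        with np.errstate(all="ignore"), pytest.raises(RuntimeError,
                                                      match="diverged"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dvae.train(cfg, small_dataset.train_images)


class TestHyperparameterGrid:
    def test_published_grid_counts(self):
        grid = dvae.full_grid()
        n_factor = sum(c.family == "factor_vae" for c in grid)
        n_beta = sum(c.family == "beta_vae" for c in grid)
        assert n_factor == 240
        assert n_beta == 240
        # the gamma=0 cell is aliased to beta=1, never duplicated
        assert not any(c.family == "factor_vae" and c.gamma == 0 for c in grid)
        assert all(c.is_standard_vae() for c in grid
                   if c.family == "beta_vae" and c.beta == 1)

    def test_minimal_grid(self):
        grid = dvae.hyperparameter_grid(latent_dims=(8,), betas=(),
                                        gammas=(10.0,), n_seeds=1)
        assert len(grid) == 1
        assert grid[0].family == "factor_vae" and grid[0].gamma == 10.0


class TestLatentTraversal:
    def test_default_range_and_length(self, trained_ci_model):
        model, ds = trained_ci_model
        seq = dvae.latent_traversal(model, ds.test_images[0], dim=0, steps=7)
        assert seq.shape == (7, 32, 32)
        assert dvae.TRAVERSAL_RANGE == (-2.0, 2.0)

    def test_single_step_reproduces_posterior_decode(self, trained_ci_model):
        model, ds = trained_ci_model
        mu, _ = dvae.encode(model, ds.test_images[3])
        seq = dvae.latent_traversal(model, ds.test_images[3], dim=2, steps=1)
        np.testing.assert_allclose(seq[0], dvae.decode(model, mu)[0], atol=1e-12)

    def test_dimension_with_zero_decoder_weights_is_constant(self):
        model = _untrained(latent_dim=4)
        model.params["V1"][3, :] = 0.0  # decoder ignores dim 3
        seq = dvae.latent_traversal(model, np.zeros((32, 32)), dim=3, steps=5)
        assert np.all(seq == seq[0])

    def test_gif_written(self, trained_ci_model, tmp_path):
        model, ds = trained_ci_model
        path = tmp_path / "trav.gif"
        dvae.write_traversal_gif(model, ds.test_images[0], 0, str(path), steps=4)
        assert path.stat().st_size > 0


class TestDisentanglementScore:
    def test_permuted_factors_score_one_on_rank_orthogonal_design(self):
        """Factors built with exactly zero pairwise Spearman correlation:
        permuted copies align 1:1 with zero cross-talk, so the gap is 1."""
        f1 = np.repeat(np.arange(8.0), 4)
        f2 = np.tile(np.arange(4.0), 8)  # balanced -> rank-orthogonal to f1
        F = np.column_stack([f1, f2])
        assert abs(np.corrcoef(*F.T)[0, 1]) < 1e-12
        score, imp = dvae.disentanglement_score(F[:, ::-1], F)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert imp.shape == (2, 2)

    def test_generic_permuted_factors_score_near_one(self):
        rng = np.random.default_rng(0)
        F = rng.random((2000, 5))
        score, _ = dvae.disentanglement_score(F[:, [4, 2, 0, 1, 3]], F)
        assert score > 0.9

    def test_fully_mixed_latents_score_zero(self):
        rng = np.random.default_rng(1)
        F = rng.random((500, 4))
        L = np.tile(F.sum(axis=1, keepdims=True), (1, 4))
        score, _ = dvae.disentanglement_score(L, F)
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_latent_permutation_and_sign(self):
        rng = np.random.default_rng(2)
        F = rng.random((800, 4))
        L = F + 0.1 * rng.random((800, 4))
        s0, _ = dvae.disentanglement_score(L, F)
        s1, _ = dvae.disentanglement_score(-L[:, [2, 0, 3, 1]], F)
        assert s0 == pytest.approx(s1, abs=1e-12)

    def test_mixing_two_aligned_latents_lowers_score(self):
        rng = np.random.default_rng(3)
        F = rng.random((1000, 4))
        L = F.copy()
        s0, _ = dvae.disentanglement_score(L, F)
        L[:, 0] = 0.5 * (F[:, 0] + F[:, 1])
        L[:, 1] = 0.5 * (F[:, 0] - F[:, 1]) + F[:, 1]
        s1, _ = dvae.disentanglement_score(L, F)
        assert s1 < s0

    def test_random_rotation_scores_low(self):
        from scipy.stats import ortho_group

        rng = np.random.default_rng(4)
        F = rng.random((2000, 8))
        scores = []
        for i in range(5):
            R = ortho_group.rvs(8, random_state=i)
            s, _ = dvae.disentanglement_score(F @ R, F)
            scores.append(s)
        assert np.mean(scores) < 0.3

    def test_constant_latent_warns_and_zeroed(self):
        rng = np.random.default_rng(5)
        F = rng.random((100, 3))
        L = F.copy()
        L[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            _, imp = dvae.disentanglement_score(L, F)
        assert np.all(imp[1] == 0)


class TestSelectModel:
    def test_argmax_and_tie_rules(self):
        c24 = dvae.ModelConfig(latent_dim=24, seed=1)
        c48 = dvae.ModelConfig(latent_dim=48, seed=0)
        c24b = dvae.ModelConfig(latent_dim=24, seed=0)
        assert dvae.select_model([(c24, 0.5)]) == c24
        assert dvae.select_model([(c24, 0.5), (c48, 0.5)]) == c24
        assert dvae.select_model([(c24, 0.5), (c24b, 0.5)]) == c24b
        assert dvae.select_model([(c24, 0.2), (c48, 0.6)]) == c48

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dvae.select_model([])
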