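"""Temporal VAE contracts: encoding, decoding, losses, training dynamics."""

import numpy as np
import pytest

import chronovae as cv
from chronovae._autodiff import Tensor
from chronovae.model import _cross_entropy


class TestEncode:
    def test_identical_cells_get_identical_posteriors(self, tiny_fit,
                                                      tiny_rna_sim):
        data, _ = tiny_rna_sim
        dup = data.subset([0, 0, 1])
        post = tiny_fit.encode(dup)
        assert np.array_equal(post.mean[0], post.mean[1])
        assert not np.array_equal(post.mean[0], post.mean[2])

    def test_posterior_is_finite_for_extreme_cells(self, tiny_fit,
                                                   tiny_rna_sim):
        data, _ = tiny_rna_sim
        post = tiny_fit.encode(data.subset(np.arange(10)))
        assert np.all(np.isfinite(post.mean))
        assert np.all(np.isfinite(post.log_variance))

    def test_feature_length_mismatch_raises(self, tiny_fit):
        other = cv.simulate_rna(cv.SimulationConfig(
            n_cell_types=1, n_genes=7, time_points=(7.0,),
            cells_per_type_per_time=5, seed=9))[0]
        with pytest.raises(ValueError, match="feature dimension"):
            tiny_fit.encode(other)

    def test_posterior_sampling_uses_the_reparameterisation(self, tiny_fit,
                                                            tiny_rna_sim):
        data, _ = tiny_rna_sim
        post = tiny_fit.encode(data.subset([0]))
        rng = np.random.default_rng(0)
        draws = np.stack([post.sample(rng) for _ in range(4000)])
        assert np.allclose(draws.mean(axis=0), post.mean, atol=0.1)


class TestDecode:
    def test_mean_fraction_sums_to_one(self, tiny_fit, tiny_rna_sim):
        data, _ = tiny_rna_sim
        pred = tiny_fit.predict_profile(data.subset(np.arange(6)),
                                        t_target=7.5)
        assert pred.min() >= 0
        assert np.allclose(pred.sum(axis=1), 1.0)

    def test_decoder_is_continuous_in_target_time(self, tiny_fit,
                                                  tiny_rna_sim):
        data, _ = tiny_rna_sim
        sub = data.subset(np.arange(4))
        a = tiny_fit.predict_profile(sub, t_target=7.5)
        b = tiny_fit.predict_profile(sub, t_target=7.5 + 1e-4)
        assert np.abs(a - b).sum(axis=1).max() < 1e-3

    def test_reconstruction_uses_own_time_and_condition(self, tiny_fit,
                                                        tiny_rna_sim):
        data, _ = tiny_rna_sim
        sub = data.subset(np.arange(3))
        own = tiny_fit.predict_profile(sub)
        explicit = tiny_fit.predict_profile(sub, t_target=None,
                                            condition_target=None)
        assert np.array_equal(own, explicit)

    def test_unseen_condition_rejected(self, tiny_fit, tiny_rna_sim):
        data, _ = tiny_rna_sim
        with pytest.raises(ValueError, match="unseen"):
            tiny_fit.predict_profile(data.subset([0]),
                                     condition_target="mystery")

    def test_unseen_time_class_rejected_in_discriminator_loss(self, tiny_fit,
                                                              tiny_rna_sim):
        data, _ = tiny_rna_sim
        shifted = data.subset(np.arange(5))
        shifted.time = shifted.time + 0.123
        with pytest.raises(ValueError, match="time"):
            tiny_fit.discriminator_loss(shifted)


class TestLosses:
    def test_kl_zero_for_prior_posterior_and_half_for_unit_shift(self):
        assert cv.gaussian_kl(np.zeros((1, 4)), np.zeros((1, 4)))[0] == 0.0
        assert cv.gaussian_kl([[1.0]], [[0.0]])[0] == 0.5

    def test_uniform_discriminator_loss_is_log_t(self):
        logits = Tensor(np.zeros((6, 4)))
        classes = np.array([0, 1, 2, 3, 0, 1])
        assert float(_cross_entropy(logits, classes).data) == pytest.approx(
            np.log(4.0))

    def test_perfect_discriminator_loss_vanishes(self):
        classes = np.array([0, 1, 1])
        logits = np.full((3, 2), -60.0)
        logits[np.arange(3), classes] = 60.0
        assert float(_cross_entropy(Tensor(logits), classes).data) == \
            pytest.approx(0.0, abs=1e-12)

    def test_generator_loss_is_rna_minus_discriminator(self, tiny_fit,
                                                       tiny_rna_sim):
        data, _ = tiny_rna_sim
        sub = data.subset(np.arange(40))
        got = tiny_fit.generator_loss(sub)
        want = tiny_fit.rna_loss(sub) - tiny_fit.discriminator_loss(sub)
        assert got == pytest.approx(want)

    def test_generator_step_leaves_discriminator_gradients_empty(self,
                                                                 tiny_fit,
                                                                 tiny_rna_sim):
        data, _ = tiny_rna_sim
        model, nets = tiny_fit.model, tiny_fit.nets
        xt, xn, te, co, ba, lib = model._inputs(data.subset(np.arange(32)))
        eps = np.zeros((32, model.config.latent_dim))
        z, m, lv = model._forward_z(nets, xn, te, co, ba, eps)
        recon = model._recon_loss(nets, z, m, lv, te, co, ba, xt, lib)
        adv = _cross_entropy(nets.discriminator(z, frozen=True),
                             model._time_class_index(data.time[:32]))
        for p in nets.discriminator_params:
            p.zero_grad()
        (recon - adv).backward()
        assert all(p.grad is None for p in nets.discriminator_params)
        assert any(p.grad is not None for p in nets.generator_params)


class TestTrainingDynamics:
    def test_reconstruction_loss_decreases_over_training(self, tiny_fit):
        hist = tiny_fit.history["train_recon"]
        assert hist[-1] < hist[0]
        assert np.all(np.isfinite(hist))

    def test_discriminator_loss_stays_finite_under_alternation(self,
                                                               tiny_fit):
        assert np.all(np.isfinite(tiny_fit.history["dis"]))

    def test_same_seed_reproduces_loss_history(self, tiny_rna_sim):
        data, _ = tiny_rna_sim
        cfg = cv.VAEConfig(latent_dim=4, time_dim=8, max_epochs=5,
                           kl_warmup_epochs=2, batch_size=64)
        split = cv.make_split(data, holdout_times=(), seed=0)
        h1 = cv.TemporalVAE(data, split, cfg).fit(seed=7).history
        h2 = cv.TemporalVAE(data, split, cfg).fit(seed=7).history
        assert np.allclose(h1["train_recon"], h2["train_recon"], rtol=1e-12)

    def test_summary_mentions_key_dimensions(self, tiny_fit):
        text = tiny_fit.summary()
        assert "latent dim" in text and "time classes" in text


class TestHeldOutRecovery:
    def test_prediction_beats_nearest_time_baseline_for_most_pairs(
            self, rna_sim, rna_heldout_fits):
        """Cross-time imputation vs copying the neighbouring pseudobulk."""
        import pandas as pd

        from chronovae.evaluation import heldout_time_evaluation

        data, _ = rna_sim
        frames = []
        for ht, (split, results) in rna_heldout_fits.items():
            for direction in ("previous", "next"):
                per_model = [heldout_time_evaluation(r, data, split, ht,
                                                     direction)
                             for r in results]
                agg = per_model[0].copy()
                agg["pearson_model"] = np.median(
                    [f["pearson_model"] for f in per_model], axis=0)
                frames.append(agg)
        table = pd.concat(frames, ignore_index=True)
        wins = (table["pearson_model"] > table["pearson_baseline"]).mean()
        assert len(table) >= 8
        assert wins > 0.5

    def test_trend_gene_interpolation_between_flanking_times(self):
        """On noiseless linear-trend genes, the prediction at a held-out
        midpoint lies between the predictions at the flanking time points
        for >=90% of genes (ensemble-median prediction)."""
        cfg = cv.SimulationConfig(
            n_cell_types=2, n_genes=20,
            time_points=(7.0, 7.25, 7.5, 7.75, 8.0),
            cells_per_type_per_time=60, noise_sd=0.0, pseudotime_step=0.0,
            pattern_families=("linear",), seed=21)
        data, _ = cv.simulate_rna(cfg)
        split = cv.make_split(data, holdout_times=(7.5,), seed=0)
        vcfg = cv.VAEConfig(latent_dim=8, time_dim=50, max_epochs=500,
                            patience=30)
        results = [cv.TemporalVAE(data, split, vcfg).fit(seed=s)
                   for s in (0, 1, 2)]
        fractions = []
        for k in range(2):
            sub = data.subset(np.isclose(data.time, 7.25)
                              & (data.cell_type == f"type{k}"))
            mid, lo, hi = (np.median([r.predict_profile(sub, t_target=t)
                                      .mean(axis=0) for r in results], axis=0)
                           for t in (7.5, 7.25, 7.75))
            between = ((mid >= np.minimum(lo, hi) - 1e-9)
                       & (mid <= np.maximum(lo, hi) + 1e-9))
            fractions.append(between.mean())
        assert np.mean(fractions) >= 0.9


class TestTimeInvariance:
    def test_probe_on_identity_embedding_near_chance_but_time_aware_not(
            self, rna_sim, rna_heldout_fits, fit_config):
        """Seed-averaged over the ensemble: a logistic probe on frozen
        identity embeddings stays within 10 points of chance while the
        time-aware embedding exceeds chance by at least 20 points."""
        from conftest import probe_accuracy

        data, _ = rna_sim
        _, results = rna_heldout_fits[7.75]
        leaks, gains = [], []
        for res in results:
            train = data.subset_by_ids(res.model.split.train_ids)
            acc_z, chance = probe_accuracy(res.embeddings(train), train.time)
            acc_e, _ = probe_accuracy(res.time_aware_embeddings(train),
                                      train.time)
            leaks.append(acc_z - chance)
            gains.append(acc_e - chance)
        assert np.mean(leaks) <= 0.10
        assert np.mean(gains) >= 0.20
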