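"""Multimodal coupling: losses, freezing, alignment and translation."""

import numpy as np
import pytest

import chronovae as cv
from chronovae import nn
from chronovae.multimodal import (alignment_loss, multimodal_loss,
                                  translation_loss)


class TestConstruction:
    def test_empty_pairing_rejected(self, mm_sim):
        rna, atac, _, _ = mm_sim
        with pytest.raises(ValueError, match="coassay"):
            cv.MultimodalVAE(rna, atac, cv.CoassayPairing(()))

    def test_atac_times_must_be_subset_of_rna_times(self, tiny_mm_fit):
        mm, _, (rna, atac, pairing, _) = tiny_mm_fit
        rna_sparse = rna.subset(~np.isclose(rna.time, atac.time[0]))
        pairs = cv.CoassayPairing(tuple(
            (r, a) for r, a in pairing.pairs if r in set(rna_sparse.cell_ids)))
        with pytest.raises(ValueError, match="subset"):
            cv.MultimodalVAE(rna_sparse, atac, pairs)

    def test_lambda_must_be_positive(self):
        with pytest.raises(ValueError):
            cv.MultimodalConfig(mse_weight=0.0)


class TestAlignmentLoss:
    def test_identical_embeddings_give_zero(self):
        z = np.random.default_rng(0).normal(size=(5, 3))
        pairing = cv.CoassayPairing(tuple((f"r{i}", f"a{i}")
                                          for i in range(5)))
        ids_r = [f"r{i}" for i in range(5)]
        ids_a = [f"a{i}" for i in range(5)]
        assert alignment_loss(z, z, pairing, ids_r, ids_a) == 0.0

    def test_constant_offset_costs_its_squared_norm(self):
        z = np.random.default_rng(1).normal(size=(4, 3))
        c = np.array([1.0, -2.0, 0.5])
        pairing = cv.CoassayPairing(tuple((f"r{i}", f"a{i}")
                                          for i in range(4)))
        got = alignment_loss(z, z + c, pairing, [f"r{i}" for i in range(4)],
                             [f"a{i}" for i in range(4)])
        assert got == pytest.approx(float(c @ c))

    def test_unpaired_id_raises(self):
        z = np.zeros((2, 2))
        pairing = cv.CoassayPairing((("rX", "a0"),))
        with pytest.raises(ValueError, match="missing"):
            alignment_loss(z, z, pairing, ["r0", "r1"], ["a0", "a1"])


class TestAtacLoss:
    def test_nonbinary_input_rejected(self, tiny_mm_fit):
        _, res, (rna, atac, _, _) = tiny_mm_fit
        fake = cv.AnnotatedMatrix(
            counts=atac.counts[:5] * 1.0, feature_ids=atac.feature_ids,
            cell_ids=atac.cell_ids[:5], time=atac.time[:5],
            condition=atac.condition[:5], batch=atac.batch[:5],
            modality="rna")  # rna modality skips binarisation
        fake.counts.data[:] = 3.0
        with pytest.raises(ValueError, match="binarised"):
            res.atac_loss(fake)

    def test_loss_finite_and_positive(self, tiny_mm_fit):
        _, res, (rna, atac, _, _) = tiny_mm_fit
        loss = res.atac_loss(atac.subset(np.arange(30)))
        assert np.isfinite(loss) and loss > 0

    def test_training_reduces_atac_objective(self, tiny_mm_fit):
        _, res, _ = tiny_mm_fit
        hist = res.history["train_total"]
        assert hist[-1] < hist[0]


class TestMultimodalLossComposition:
    def test_total_is_sum_of_named_terms(self, tiny_mm_fit):
        mm, res, (rna, atac, pairing, _) = tiny_mm_fit
        sub_pairs = cv.CoassayPairing(pairing.pairs[:12])
        batch = atac.subset(np.arange(25))
        total = multimodal_loss(batch, sub_pairs, mm.config, res)
        rna_p = rna.subset_by_ids([r for r, _ in sub_pairs.pairs])
        atac_p = atac.subset_by_ids([a for _, a in sub_pairs.pairs])
        align = alignment_loss(res.rna.embeddings(rna_p),
                               res.atac_embeddings(atac_p), sub_pairs,
                               rna_p.cell_ids, atac_p.cell_ids)
        expect = (res.atac_loss(batch) + mm.config.mse_weight * align
                  + translation_loss("rna->atac", sub_pairs, res)
                  + translation_loss("atac->rna", sub_pairs, res))
        assert total == pytest.approx(expect)

    def test_both_translation_directions_computable(self, tiny_mm_fit):
        _, res, (_, _, pairing, _) = tiny_mm_fit
        sub = cv.CoassayPairing(pairing.pairs[:8])
        ra = translation_loss("rna->atac", sub, res)
        ar = translation_loss("atac->rna", sub, res)
        assert np.isfinite(ra) and np.isfinite(ar)
        with pytest.raises(ValueError, match="direction"):
            translation_loss("sideways", sub, res)

    def test_translation_requires_pairs(self, tiny_mm_fit):
        _, res, _ = tiny_mm_fit
        with pytest.raises(ValueError):
            translation_loss("rna->atac", cv.CoassayPairing(()), res)


class TestStepwiseTraining:
    def test_atac_path_shares_the_rna_interaction_parameters(self,
                                                             tiny_mm_fit):
        """Perturbing the RNA interaction layer must change ATAC-side
        predictions: both modalities read the same parameter tensors (the
        ATAC step trains against a frozen copy-by-reference, and fit()
        asserts bit-identity across that step)."""
        _, res, (rna, _, _, _) = tiny_mm_fit
        sub = rna.subset(np.arange(3))
        before = res.predict_cross_modality(sub, 8.0)
        layer = res.rna.nets.interaction.layers[0]
        state = nn.get_state([layer.W])
        layer.W.data += 0.05
        try:
            after = res.predict_cross_modality(sub, 8.0)
        finally:
            nn.set_state([layer.W], state)
        assert not np.allclose(before, after)

    def test_rna_only_time_points_train_only_the_rna_side(self, mm_sim):
        rna, atac, _, _ = mm_sim
        assert set(np.unique(rna.time)) - set(np.unique(atac.time))

    def test_cross_modality_probabilities_in_unit_interval(self, tiny_mm_fit):
        _, res, (rna, _, _, _) = tiny_mm_fit
        probs = res.predict_cross_modality(rna.subset(np.arange(4)), 8.0)
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_cross_modality_prediction_continuous_in_time(self, tiny_mm_fit):
        _, res, (rna, _, _, _) = tiny_mm_fit
        sub = rna.subset(np.arange(4))
        a = res.predict_cross_modality(sub, 8.0)
        b = res.predict_cross_modality(sub, 8.0 + 1e-4)
        assert np.abs(a - b).max() < 1e-3


class TestTrainedAlignment:
    def test_paired_cells_far_closer_than_random_pairs(self, mm_sim,
                                                       mm_ensemble):
        """Coassay partners' embeddings are pulled together; cells within a
        simulated (type, time) block are exchangeable, so exact-pair nearest
        neighbours are not identifiable — distance contraction is."""
        rna, atac, pairing, _ = mm_sim
        res = mm_ensemble[0]
        rna_p = rna.subset_by_ids([r for r, _ in pairing.pairs])
        atac_p = atac.subset_by_ids([a for _, a in pairing.pairs])
        zr = res.rna.embeddings(rna_p)
        za = res.atac_embeddings(atac_p)
        paired = np.linalg.norm(zr - za, axis=1).mean()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(zr))
        random = np.linalg.norm(zr - za[perm], axis=1).mean()
        # random partners mostly come from other (type, time) blocks, so the
        # contraction quantifies cross-modality alignment at block level
        assert paired < 0.8 * random

    def test_direction_statistic_recovers_temporal_change(self, mm_sim,
                                                          mm_ensemble):
        """Per-peak normalised signed-rank direction of predicted change
        between two times agrees with the programmed direction."""
        from chronovae.metrics import auroc, paired_rank_statistic

        rna, _, _, truth = mm_sim
        res = mm_ensemble[0]
        query = rna.subset(np.isclose(rna.time, 8.25)
                           & (rna.cell_type == "type0"))
        pred_late = res.predict_cross_modality(query, 8.5)
        pred_query = res.predict_cross_modality(query, 8.25)
        stat = np.array([paired_rank_statistic(pred_late[:, p],
                                               pred_query[:, p])
                         for p in range(pred_late.shape[1])])
        true_late = truth.peak_probability(0, 8.5)[:, 0]
        true_query = truth.peak_probability(0, 8.25)[:, 0]
        changing = np.abs(true_late - true_query) > 0.02
        labels = (true_late - true_query > 0).astype(int)
        assert auroc(stat[changing], labels[changing]) > 0.7

    def test_translation_scores_linked_peaks_above_background(self, mm_sim,
                                                              mm_ensemble):
        from chronovae.metrics import auroc

        rna, atac, pairing, truth = mm_sim
        res = mm_ensemble[0]
        rna_p = rna.subset_by_ids([r for r, _ in pairing.pairs])
        atac_p = atac.subset_by_ids([a for _, a in pairing.pairs])
        x = np.asarray(atac_p.counts.todense())
        probs = np.vstack([
            res.predict_cross_modality(rna_p.subset([i]), rna_p.time[i])
            for i in range(0, rna_p.n_cells, 2)])
        xs = x[::2]
        linked = [p for p in range(x.shape[1]) if truth.peak_gene[p] >= 0]
        unlinked = [p for p in range(x.shape[1]) if truth.peak_gene[p] < 0]
        def mean_auc(peaks):
            vals = [auroc(probs[:, p], xs[:, p].astype(int)) for p in peaks
                    if len(np.unique(xs[:, p])) > 1]
            return np.mean(vals)
        linked_auc = mean_auc(linked)
        assert linked_auc > 0.55
        assert linked_auc > mean_auc(unlinked)
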