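"""Multimodal extension: ATAC-side VAE coupled to an RNA reference.

The scRNA-seq model (denser time coverage) is trained first and acts as the
reference.  The scATAC-seq model is then trained with its temporal
interaction layer *copied from and frozen to* the RNA model's, so that the
interaction effect among cell identity, time and condition is shared across
modalities, and with its cell embeddings pulled toward the RNA embeddings of
coassay partner cells.  The ATAC objective is

    loss_multi = loss_ATAC + lambda * MSE(z_atac, z_rna)
               + loss_trans(ATAC | RNA) + loss_trans(RNA | ATAC)

where ``loss_ATAC`` is Bernoulli BCE + KL (with its own adversarial time
discriminator), the MSE runs over coassay pairs, and the translation losses
encode one modality and decode the other through the shared interaction
layer.  Because the RNA objective does not depend on the ATAC model, a
single pass of step 1 (RNA) followed by step 2 (ATAC) reaches the fixed
point of the stepwise schedule.

Cross-modality prediction couples the RNA encoder with the ATAC decoder at
any target time, giving per-peak accessibility probabilities for cells that
were only measured in RNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from ._autodiff import Tensor, concat
from .data import AnnotatedMatrix, CoassayPairing, SplitPlan, make_split
from .encodings import sinusoidal_encode
from .likelihoods import (bernoulli_log_likelihood, bernoulli_nll_t,
                          gaussian_kl_t, zinb_nll_t)
from .model import (TemporalVAE, TemporalVAEResults, VAEConfig,
                    _cross_entropy)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MultimodalConfig:
    """Coupling hyperparameters; ``mse_weight`` is the grid-searched lambda."""

    mse_weight: float = 100.0
    reference_modality: str = "rna"
    vae: VAEConfig = VAEConfig()

    def __post_init__(self):
        if self.mse_weight <= 0:
            raise ValueError("mse_weight must be positive")
        if self.reference_modality != "rna":
            raise ValueError("only an RNA reference is supported")


@dataclass
class BernoulliParams:
    """Per-peak accessibility probabilities for a batch of cells."""

    peak_prob: np.ndarray

    def __post_init__(self):
        self.peak_prob = np.atleast_2d(np.asarray(self.peak_prob, float))
        if np.any(self.peak_prob <= 0) or np.any(self.peak_prob >= 1):
            raise ValueError("peak probabilities must lie in (0, 1)")


class _AtacNetworks:
    """ATAC encoder/decoder/discriminator; the interaction layer is shared."""

    def __init__(self, n_peaks: int, n_cond: int, n_batch: int,
                 n_time_classes: int, cfg: VAEConfig,
                 rng: np.random.Generator):
        L, D = cfg.latent_dim, cfg.time_dim
        enc_in = n_peaks + D + n_cond + n_batch
        h_enc = nn.hidden_width(enc_in, L)
        self.encoder = nn.MLP([enc_in] + [h_enc] * cfg.hidden_layers, rng,
                              final_activation="relu")
        self.enc_mean = nn.Dense(h_enc, L, rng)
        self.enc_logvar = nn.Dense(h_enc, L, rng)
        dec_in = L + n_batch
        h_dec = nn.hidden_width(n_peaks, L)
        self.dec_body = nn.MLP([dec_in] + [h_dec] * cfg.hidden_layers, rng,
                               final_activation="relu")
        self.dec_logits = nn.Dense(h_dec, n_peaks, rng)
        # per-cell coverage handling: scalar offset linear in centred
        # log-total accessible peaks
        self.coverage_coef = Tensor(np.zeros(1), requires_grad=True)
        self.discriminator = nn.MLP(
            [L, max(16, nn.hidden_width(L, n_time_classes)), n_time_classes],
            rng)

    @property
    def generator_params(self) -> list[Tensor]:
        return (self.encoder.parameters + self.enc_mean.parameters
                + self.enc_logvar.parameters + self.dec_body.parameters
                + self.dec_logits.parameters + [self.coverage_coef])

    @property
    def discriminator_params(self) -> list[Tensor]:
        return self.discriminator.parameters


class MultimodalVAE:
    """Coupled RNA/ATAC temporal VAEs with coassay supervision.

    Requires a non-empty :class:`CoassayPairing`; ATAC time points must be a
    subset of the RNA time points (the reference has denser coverage).
    """

    def __init__(self, rna_data: AnnotatedMatrix, atac_data: AnnotatedMatrix,
                 pairing: CoassayPairing,
                 config: MultimodalConfig = MultimodalConfig(),
                 rna_split: SplitPlan | None = None,
                 atac_split: SplitPlan | None = None, split_seed: int = 0):
        if atac_data.modality != "atac":
            raise ValueError("atac_data must have modality='atac'")
        if len(pairing) == 0:
            raise ValueError("coassay pairing is empty: cross-modality "
                             "alignment requires coassay anchors")
        pairing.validate_against(rna_data, atac_data)
        if not set(np.unique(atac_data.time)) <= set(np.unique(rna_data.time)):
            raise ValueError("ATAC time points must be a subset of the "
                             "reference RNA time points")
        self.config = config
        self.pairing = pairing
        self.atac_data = atac_data
        self.atac_split = atac_split if atac_split is not None else make_split(
            atac_data, holdout_times=(), seed=split_seed)
        self.rna_model = TemporalVAE(rna_data, rna_split, config.vae,
                                     split_seed=split_seed)
        train_atac = atac_data.subset_by_ids(self.atac_split.train_ids)
        self.atac_time_classes = np.unique(train_atac.time)

    # -- ATAC-side input block ----------------------------------------------
    def _atac_inputs(self, data: AnnotatedMatrix):
        x = np.asarray(data.counts.todense())
        cover = np.log1p(x.sum(axis=1))
        cover = cover - cover.mean()
        te = sinusoidal_encode(data.time, self.rna_model.time_spec)
        co = self.rna_model.condition_enc.encode(data.condition)
        ba = self.rna_model.batch_enc.encode(data.batch)
        return x, cover, te, co, ba

    def _atac_z(self, nets: _AtacNetworks, x, te, co, ba, eps):
        h = nets.encoder(concat([Tensor(x), Tensor(te), Tensor(co),
                                 Tensor(ba)]))
        mean = nets.enc_mean(h)
        logvar = nets.enc_logvar(h).clip(-10.0, 10.0)
        z = mean + (logvar * 0.5).exp() * Tensor(eps)
        return z, mean, logvar

    def _atac_logits(self, nets: _AtacNetworks, rna_nets, z, te, co, ba,
                     cover, frozen_interaction: bool = True):
        e = rna_nets.interaction(concat([z, Tensor(te), Tensor(co)]),
                                 frozen=frozen_interaction)
        h = nets.dec_body(concat([e, Tensor(ba)]))
        logits = nets.dec_logits(h) + nets.coverage_coef * Tensor(
            cover[:, None])
        return logits

    def fit(self, seed: int = 0, verbose: bool = False) -> "MultimodalResults":
        """Stepwise training: RNA reference first, then the coupled ATAC model."""
        cfg = self.config.vae
        lam = self.config.mse_weight
        rng = np.random.default_rng(seed)
        # -- step 1: RNA reference (ATAC model untouched) ---------------------
        rna_results = self.rna_model.fit(seed=seed, verbose=verbose)
        rna_nets = rna_results.nets
        interaction_before = nn.get_state(rna_nets.interaction.parameters)
        # -- step 2: ATAC with shared frozen interaction ----------------------
        atac_train = self.atac_data.subset_by_ids(self.atac_split.train_ids)
        atac_val = (self.atac_data.subset_by_ids(self.atac_split.val_ids)
                    if self.atac_split.val_ids else None)
        nets = _AtacNetworks(self.atac_data.n_features,
                             len(self.rna_model.condition_enc),
                             len(self.rna_model.batch_enc),
                             len(self.atac_time_classes), cfg, rng)
        opt_gen = nn.Adam(nets.generator_params, lr=cfg.learning_rate)
        opt_dis = nn.Adam(nets.discriminator_params, lr=cfg.learning_rate)
        x, cover, te, co, ba = self._atac_inputs(atac_train)
        tclass = np.searchsorted(self.atac_time_classes, atac_train.time)
        # paired-cell tensors: RNA z means are constants during step 2
        rna_lookup = {c: i for i, c in enumerate(self.rna_model.data.cell_ids)}
        atac_lookup = {c: i for i, c in enumerate(atac_train.cell_ids)}
        pair_rna_idx, pair_atac_idx = [], []
        for r, a in self.pairing.pairs:
            if a in atac_lookup:
                pair_rna_idx.append(rna_lookup[r])
                pair_atac_idx.append(atac_lookup[a])
        pair_rna_idx = np.asarray(pair_rna_idx, int)
        pair_atac_idx = np.asarray(pair_atac_idx, int)
        rna_paired = self.rna_model.data.subset(pair_rna_idx)
        z_rna_paired = rna_results.embeddings(rna_paired)
        rxt, _rxn, rte, rco, rba, rlib = self.rna_model._inputs(rna_paired)
        n = atac_train.n_cells
        history = {"train_total": [], "val_recon": [], "dis": [],
                   "align": [], "trans": []}
        best_val, best_state, patience_left = np.inf, None, cfg.patience
        atac_pos = {i: j for j, i in enumerate(pair_atac_idx)}
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            ep = {"total": 0.0, "dis": 0.0, "align": 0.0, "trans": 0.0}
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                if len(sel) < 2:
                    continue
                eps = rng.standard_normal((len(sel), cfg.latent_dim))
                # discriminator step
                z0, _, _ = self._atac_z(nets, x[sel], te[sel], co[sel],
                                        ba[sel], eps)
                dloss = _cross_entropy(nets.discriminator(Tensor(z0.data)),
                                       tclass[sel])
                opt_dis.zero_grad()
                dloss.backward()
                opt_dis.step()
                # generator step: BCE + KL + lambda*MSE + translations - adv
                z, zm, zlv = self._atac_z(nets, x[sel], te[sel], co[sel],
                                          ba[sel], eps)
                logits = self._atac_logits(nets, rna_nets, z, te[sel],
                                           co[sel], ba[sel], cover[sel])
                recon = (bernoulli_nll_t(x[sel], logits)
                         + cfg.kl_weight * gaussian_kl_t(zm, zlv))
                adv = _cross_entropy(nets.discriminator(z, frozen=True),
                                     tclass[sel])
                loss = recon - cfg.adversarial_weight * adv
                in_pair = [i for i, c in enumerate(sel) if c in atac_pos]
                if in_pair:
                    a_sel = np.array([sel[i] for i in in_pair])
                    p_sel = np.array([atac_pos[c] for c in a_sel])
                    # alignment: pull ATAC posterior means to RNA embeddings
                    _, zm_p, zlv_p = self._atac_z(
                        nets, x[a_sel], te[a_sel], co[a_sel], ba[a_sel],
                        np.zeros((len(a_sel), cfg.latent_dim)))
                    diff = zm_p - Tensor(z_rna_paired[p_sel])
                    align = (diff * diff).sum(axis=1).mean()
                    # translation RNA -> ATAC (RNA encoder frozen constants)
                    logits_ra = self._atac_logits(
                        nets, rna_nets, Tensor(z_rna_paired[p_sel]),
                        te[a_sel], co[a_sel], ba[a_sel], cover[a_sel])
                    trans_ra = bernoulli_nll_t(x[a_sel], logits_ra)
                    # translation ATAC -> RNA (RNA decoder frozen)
                    trans_ar = self._rna_decode_nll(
                        rna_nets, zm_p, rte[p_sel], rco[p_sel], rba[p_sel],
                        rxt[p_sel], rlib[p_sel])
                    loss = (loss + lam * align + trans_ra + trans_ar)
                    ep["align"] += float(align.data)
                    ep["trans"] += float(trans_ra.data + trans_ar.data)
                opt_gen.zero_grad()
                loss.backward()
                opt_gen.step()
                ep["total"] += float(loss.data)
                ep["dis"] += float(dloss.data)
                n_batches += 1
            for key, hkey in (("total", "train_total"), ("dis", "dis"),
                              ("align", "align"), ("trans", "trans")):
                history[hkey].append(ep[key] / max(n_batches, 1))
            vloss = self._atac_val_loss(nets, rna_nets, atac_val, cfg) \
                if atac_val is not None and atac_val.n_cells else \
                history["train_total"][-1]
            history["val_recon"].append(vloss)
            if verbose:
                log.info("atac epoch %d total %.3f val %.3f", epoch,
                         history["train_total"][-1], vloss)
            if vloss < best_val - 1e-6:
                best_val, patience_left = vloss, cfg.patience
                best_state = nn.get_state(nets.generator_params
                                          + nets.discriminator_params)
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        if best_state is not None:
            nn.set_state(nets.generator_params + nets.discriminator_params,
                         best_state)
        interaction_after = nn.get_state(rna_nets.interaction.parameters)
        assert all(np.array_equal(a, b) for a, b in
                   zip(interaction_before, interaction_after)), \
            "shared interaction layer must stay frozen during the ATAC step"
        return MultimodalResults(self, rna_results, nets, history, seed)

    def _rna_decode_nll(self, rna_nets, z, te, co, ba, x_counts, lib):
        e = rna_nets.interaction(concat([z, Tensor(te), Tensor(co)]),
                                 frozen=True)
        h = rna_nets.dec_body(concat([e, Tensor(ba)]), frozen=True)
        from ._autodiff import softmax as _softmax
        mean_frac = _softmax(rna_nets.dec_mean_logits(h, frozen=True), axis=1)
        dropout = rna_nets.dec_dropout(h, frozen=True)
        return zinb_nll_t(x_counts, mean_frac,
                          rna_nets.log_dispersion.detach(), dropout, lib)

    def _atac_val_loss(self, nets, rna_nets, val: AnnotatedMatrix,
                       cfg: VAEConfig) -> float:
        x, cover, te, co, ba = self._atac_inputs(val)
        eps0 = np.zeros((val.n_cells, cfg.latent_dim))
        z, zm, zlv = self._atac_z(nets, x, te, co, ba, eps0)
        logits = self._atac_logits(nets, rna_nets, z, te, co, ba, cover)
        return float((bernoulli_nll_t(x, logits)
                      + cfg.kl_weight * gaussian_kl_t(zm, zlv)).data)


class MultimodalResults:
    """Fitted coupled models: reconstruction, alignment and translation."""

    def __init__(self, model: MultimodalVAE, rna_results: TemporalVAEResults,
                 atac_nets: _AtacNetworks, history: dict, seed: int):
        self.model = model
        self.rna = rna_results
        self.atac_nets = atac_nets
        self.history = history
        self.seed = seed

    # -- embeddings ----------------------------------------------------------
    def atac_embeddings(self, data: AnnotatedMatrix | None = None) -> np.ndarray:
        data = data if data is not None else self.model.atac_data
        x, _cover, te, co, ba = self.model._atac_inputs(data)
        eps0 = np.zeros((data.n_cells, self.model.config.vae.latent_dim))
        _, zm, _ = self.model._atac_z(self.atac_nets, x, te, co, ba, eps0)
        return zm.data

    # -- reconstruction / prediction -----------------------------------------
    def predict_atac_profile(self, z: np.ndarray, t_target, condition_target,
                             batch_target) -> BernoulliParams:
        """Decode identity embeddings to peak probabilities at a target time."""
        z = np.atleast_2d(np.asarray(z, float))
        n = len(z)
        times = np.broadcast_to(np.asarray(t_target, float), (n,))
        cond = np.broadcast_to(np.asarray(condition_target, object), (n,))
        batch = np.broadcast_to(np.asarray(batch_target, object), (n,))
        te = sinusoidal_encode(times, self.model.rna_model.time_spec)
        co = self.model.rna_model.condition_enc.encode(cond)
        ba = self.model.rna_model.batch_enc.encode(batch)
        logits = self.model._atac_logits(
            self.atac_nets, self.rna.nets, Tensor(z), te, co, ba,
            np.zeros(n))
        probs = np.clip(1.0 / (1.0 + np.exp(-logits.data)), 1e-6, 1 - 1e-6)
        return BernoulliParams(peak_prob=probs)

    def predict_cross_modality(self, rna_cells: AnnotatedMatrix,
                               t_target) -> np.ndarray:
        """RNA cells -> peak probabilities at ``t_target`` (RNA encoder +
        shared interaction + ATAC decoder)."""
        z = self.rna.embeddings(rna_cells)
        return self.predict_atac_profile(
            z, t_target, rna_cells.condition[0], rna_cells.batch[0]).peak_prob

    def predict_atac_trajectory(self, rna_cells: AnnotatedMatrix,
                                time_grid) -> np.ndarray:
        """(cells, peaks, T) accessibility probabilities from RNA queries."""
        time_grid = np.asarray(time_grid, float)
        z = self.rna.embeddings(rna_cells)
        out = np.empty((rna_cells.n_cells, self.model.atac_data.n_features,
                        len(time_grid)))
        for j, t in enumerate(time_grid):
            out[:, :, j] = self.predict_atac_profile(
                z, t, rna_cells.condition[0], rna_cells.batch[0]).peak_prob
        return out

    # -- losses evaluated as plain numbers ------------------------------------
    def atac_loss(self, data: AnnotatedMatrix) -> float:
        """Mean per-cell Bernoulli BCE + KL on binarised ``data``."""
        raw = np.asarray(data.counts.todense())
        if np.any((raw != 0) & (raw != 1)):
            raise ValueError("atac_loss requires binarised input")
        cfg = self.model.config.vae
        x, cover, te, co, ba = self.model._atac_inputs(data)
        eps0 = np.zeros((data.n_cells, cfg.latent_dim))
        z, zm, zlv = self.model._atac_z(self.atac_nets, x, te, co, ba, eps0)
        logits = self.model._atac_logits(self.atac_nets, self.rna.nets, z,
                                         te, co, ba, cover)
        return float((bernoulli_nll_t(x, logits)
                      + cfg.kl_weight * gaussian_kl_t(zm, zlv)).data)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Multimodal temporal VAE results",
            "===============================",
            f"RNA cells / genes:   {m.rna_model.data.n_cells} / "
            f"{m.rna_model.data.n_features}",
            f"ATAC cells / peaks:  {m.atac_data.n_cells} / "
            f"{m.atac_data.n_features}",
            f"coassay pairs:       {len(m.pairing)}",
            f"MSE weight lambda:   {m.config.mse_weight}",
            f"ATAC time classes:   {np.round(m.atac_time_classes, 4).tolist()}",
            f"ATAC epochs run:     {len(self.history['train_total'])}",
            f"final ATAC val loss: {self.history['val_recon'][-1]:.4f}",
            f"seed:                {self.seed}",
        ]
        return "\n".join(lines + ["", "RNA reference:", self.rna.summary()])


# -- module-level loss operations --------------------------------------------

def alignment_loss(rna_embeddings: np.ndarray, atac_embeddings: np.ndarray,
                   pairing: CoassayPairing, rna_ids, atac_ids) -> float:
    """Mean squared Euclidean distance between paired cell embeddings."""
    rna_pos = {c: i for i, c in enumerate(rna_ids)}
    atac_pos = {c: i for i, c in enumerate(atac_ids)}
    sq = []
    for r, a in pairing.pairs:
        if r not in rna_pos or a not in atac_pos:
            raise ValueError(f"pair ({r!r}, {a!r}) missing from embeddings")
        d = rna_embeddings[rna_pos[r]] - atac_embeddings[atac_pos[a]]
        sq.append(float(d @ d))
    return float(np.mean(sq))


def translation_loss(direction: str, pairing: CoassayPairing,
                     results: MultimodalResults) -> float:
    """Mean per-cell NLL of translating one modality into the other.

    ``direction`` is ``"rna->atac"`` (ZINB-side encode, Bernoulli-side
    decode) or ``"atac->rna"``.
    """
    if len(pairing) == 0:
        raise ValueError("translation requires coassay pairs")
    m = results.model
    rna_cells = m.rna_model.data.subset_by_ids([r for r, _ in pairing.pairs])
    atac_cells = m.atac_data.subset_by_ids([a for _, a in pairing.pairs])
    if direction == "rna->atac":
        probs = np.stack([
            results.predict_atac_profile(
                results.rna.embeddings(rna_cells)[i:i + 1],
                atac_cells.time[i], atac_cells.condition[i],
                atac_cells.batch[i]).peak_prob[0]
            for i in range(rna_cells.n_cells)])
        x = np.asarray(atac_cells.counts.todense())
        return float(-bernoulli_log_likelihood(x, probs) / len(x))
    if direction == "atac->rna":
        z = results.atac_embeddings(atac_cells)
        xt, _xn, rte, rco, rba, rlib = m.rna_model._inputs(rna_cells)
        return float(m._rna_decode_nll(results.rna.nets, Tensor(z), rte, rco,
                                       rba, xt, rlib).data)
    raise ValueError(f"unknown direction {direction!r}")


def multimodal_loss(data: AnnotatedMatrix, pairing: CoassayPairing,
                    config: MultimodalConfig,
                    results: MultimodalResults) -> float:
    """atac_loss + lambda * alignment + both translation directions."""
    rna_cells = results.model.rna_model.data.subset_by_ids(
        [r for r, _ in pairing.pairs])
    atac_cells = results.model.atac_data.subset_by_ids(
        [a for _, a in pairing.pairs])
    align = alignment_loss(results.rna.embeddings(rna_cells),
                           results.atac_embeddings(atac_cells), pairing,
                           rna_cells.cell_ids, atac_cells.cell_ids)
    return (results.atac_loss(data) + config.mse_weight * align
            + translation_loss("rna->atac", pairing, results)
            + translation_loss("atac->rna", pairing, results))
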