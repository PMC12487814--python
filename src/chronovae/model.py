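"""Single-modality conditional VAE for single-cell temporal profiles.

The model decomposes each cell's profile into a time-invariant identity
embedding ``z``, a continuous sinusoidal time factor, and one-hot condition
and batch factors.  The encoder maps depth-normalised log1p counts (plus the
factors) to a diagonal-Gaussian posterior over ``z``; a temporal interaction
layer combines ``z`` with the time and condition factors into a time-aware
embedding of the same dimension; the decoder maps that embedding (plus the
batch factor) to zero-inflated negative-binomial parameters.  An adversarial
discriminator tries to predict the (discretised) collection time from ``z``,
and the generator is penalised by the negated discriminator loss so that
``z`` carries no time information.

Training minimises, in alternation,

    loss_recon = -ZINB.loglik(x, decoder(...)) + KL(q(z|x, t) || N(0, I))
    loss_dis   = CE(discriminator(z), time_class)
    loss_gen   = loss_recon - loss_dis          (discriminator frozen)

with Adam, minibatches, and early stopping on the validation reconstruction
loss.  Prediction swaps the time and/or condition factor of a query cell
while keeping its identity embedding fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from ._autodiff import Tensor, concat, logsumexp, softmax
from .data import AnnotatedMatrix, SplitPlan, make_split
from .encodings import FactorEncoding, TimeEncodingSpec, sinusoidal_encode
from .likelihoods import (ZINBParams, gaussian_kl, gaussian_kl_t,
                          zinb_log_likelihood, zinb_nll_t)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VAEConfig:
    """Hyperparameters of the temporal VAE.

    Defaults follow the reference setting: latent and time dimensions of 50,
    two hidden layers whose width is the rounded geometric mean of the input
    and latent dimensions, minimum sinusoidal wavelength of 1 day, Adam at
    1e-3 with minibatches of 128 and early stopping with patience 10.
    """

    latent_dim: int = 50
    time_dim: int = 50
    min_wavelength: float = 1.0
    hidden_layers: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 500
    patience: int = 10
    kl_weight: float = 1.0
    kl_warmup_epochs: int = 50  # KL weight anneals 0 -> kl_weight linearly
    adversarial_weight: float = 1.0
    counts_scale: float = 1e4  # depth-normalisation target for encoder input


@dataclass
class LatentPosterior:
    """Diagonal-Gaussian posterior over cell identity embeddings."""

    mean: np.ndarray
    log_variance: np.ndarray

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        eps = rng.standard_normal(self.mean.shape)
        return self.mean + np.exp(0.5 * self.log_variance) * eps

    def kl(self) -> np.ndarray:
        return gaussian_kl(self.mean, self.log_variance)


class _Networks:
    """Parameter container: encoder, interaction, decoder, discriminator."""

    def __init__(self, n_features: int, n_cond: int, n_batch: int,
                 n_time_classes: int, cfg: VAEConfig, rng: np.random.Generator):
        L, D = cfg.latent_dim, cfg.time_dim
        enc_in = n_features + D + n_cond + n_batch
        h_enc = nn.hidden_width(enc_in, L)
        self.encoder = nn.MLP([enc_in] + [h_enc] * cfg.hidden_layers, rng,
                              final_activation="relu")
        self.enc_mean = nn.Dense(h_enc, L, rng)
        self.enc_logvar = nn.Dense(h_enc, L, rng)
        inter_in = L + D + n_cond
        self.interaction = nn.MLP(
            [inter_in, nn.hidden_width(inter_in, L), L], rng,
            activation="tanh")
        dec_in = L + n_batch
        h_dec = nn.hidden_width(n_features, L)
        self.dec_body = nn.MLP([dec_in] + [h_dec] * cfg.hidden_layers, rng,
                               final_activation="relu")
        self.dec_mean_logits = nn.Dense(h_dec, n_features, rng)
        self.dec_dropout = nn.Dense(h_dec, n_features, rng)
        self.log_dispersion = Tensor(np.zeros(n_features), requires_grad=True)
        self.discriminator = nn.MLP(
            [L, max(16, nn.hidden_width(L, n_time_classes)), n_time_classes],
            rng)

    @property
    def generator_params(self) -> list[Tensor]:
        return (self.encoder.parameters + self.enc_mean.parameters
                + self.enc_logvar.parameters + self.interaction.parameters
                + self.decoder_params)

    @property
    def decoder_params(self) -> list[Tensor]:
        return (self.dec_body.parameters + self.dec_mean_logits.parameters
                + self.dec_dropout.parameters + [self.log_dispersion])

    @property
    def discriminator_params(self) -> list[Tensor]:
        return self.discriminator.parameters


class TemporalVAE:
    """Conditional VAE over one modality of an annotated count matrix.

    Parameters
    ----------
    data : AnnotatedMatrix
        scRNA-seq counts (this class always models the RNA/ZINB side; the
        ATAC/Bernoulli side lives in :mod:`chronovae.multimodal`).
    split : SplitPlan, optional
        Train/validation/test assignment; when omitted, a split with no
        held-out time point is created from ``split_seed``.
    config : VAEConfig
    """

    def __init__(self, data: AnnotatedMatrix, split: SplitPlan | None = None,
                 config: VAEConfig = VAEConfig(), split_seed: int = 0):
        if data.modality != "rna":
            raise ValueError("TemporalVAE models RNA counts; use the "
                             "multimodal module for ATAC")
        self.data = data
        self.config = config
        self.split = split if split is not None else make_split(
            data, holdout_times=(), seed=split_seed)
        self.time_spec = TimeEncodingSpec(config.time_dim,
                                          config.min_wavelength)
        self.condition_enc = FactorEncoding.from_values(data.condition)
        self.batch_enc = FactorEncoding.from_values(data.batch)
        train = data.subset_by_ids(self.split.train_ids)
        self.time_classes = np.unique(train.time)
        self.library_scale = float(np.median(train.library_size))

    # -- feature preparation -------------------------------------------------
    def _inputs(self, data: AnnotatedMatrix):
        """Encoder input block plus raw counts and libraries."""
        x = np.asarray(data.counts.todense())
        lib = x.sum(axis=1)
        x_norm = np.log1p(self.config.counts_scale * x / lib[:, None])
        t_enc = sinusoidal_encode(data.time, self.time_spec)
        cond = self.condition_enc.encode(data.condition)
        batch = self.batch_enc.encode(data.batch)
        return x, x_norm, t_enc, cond, batch, lib

    def _time_class_index(self, times: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.time_classes, times)
        idx = np.clip(idx, 0, len(self.time_classes) - 1)
        ok = np.isclose(self.time_classes[idx], times)
        left = np.clip(idx - 1, 0, len(self.time_classes) - 1)
        idx = np.where(ok, idx, np.where(
            np.isclose(self.time_classes[left], times), left, -1))
        if np.any(idx < 0):
            bad = np.asarray(times)[idx < 0]
            raise ValueError(f"time point(s) {np.unique(bad)} not among "
                             f"training time classes {self.time_classes}")
        return idx

    def fit(self, seed: int = 0, verbose: bool = False) -> "TemporalVAEResults":
        """Train with alternating generator/discriminator updates."""
        cfg = self.config
        rng = np.random.default_rng(seed)
        train = self.data.subset_by_ids(self.split.train_ids)
        val = (self.data.subset_by_ids(self.split.val_ids)
               if self.split.val_ids else None)
        nets = _Networks(self.data.n_features, len(self.condition_enc),
                         len(self.batch_enc), len(self.time_classes), cfg, rng)
        opt_gen = nn.Adam(nets.generator_params, lr=cfg.learning_rate)
        opt_dis = nn.Adam(nets.discriminator_params, lr=cfg.learning_rate)
        xt, xn, te, co, ba, lib = self._inputs(train)
        tclass = self._time_class_index(train.time)
        vxt = vxn = vte = vco = vba = vlib = None
        if val is not None and val.n_cells:
            vxt, vxn, vte, vco, vba, vlib = self._inputs(val)
        n = train.n_cells
        history = {"train_recon": [], "val_recon": [], "dis": []}
        best_val, best_state, patience_left = np.inf, None, cfg.patience
        all_params = nets.generator_params + nets.discriminator_params
        for epoch in range(cfg.max_epochs):
            # KL warm-up guards against posterior collapse early in training
            kl_scale = (min(1.0, (epoch + 1) / cfg.kl_warmup_epochs)
                        if cfg.kl_warmup_epochs > 0 else 1.0)
            order = rng.permutation(n)
            ep_recon, ep_dis, n_batches = 0.0, 0.0, 0
            for start in range(0, n, cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                if len(sel) < 2:
                    continue
                eps = rng.standard_normal((len(sel), cfg.latent_dim))
                # discriminator step: z detached, only disc params move
                z0, _, _ = self._forward_z(nets, xn[sel], te[sel], co[sel],
                                           ba[sel], eps)
                dis_loss = _cross_entropy(nets.discriminator(Tensor(z0.data)),
                                          tclass[sel])
                opt_dis.zero_grad()
                dis_loss.backward()
                opt_dis.step()
                # generator step: disc frozen
                z, zmean, zlogvar = self._forward_z(nets, xn[sel], te[sel],
                                                    co[sel], ba[sel], eps)
                recon = self._recon_loss(nets, z, zmean, zlogvar, te[sel],
                                         co[sel], ba[sel], xt[sel], lib[sel],
                                         kl_scale=kl_scale)
                adv = _cross_entropy(
                    nets.discriminator(z, frozen=True), tclass[sel])
                gen_loss = recon - cfg.adversarial_weight * adv
                opt_gen.zero_grad()
                gen_loss.backward()
                opt_gen.step()
                ep_recon += float(recon.data)
                ep_dis += float(dis_loss.data)
                n_batches += 1
            history["train_recon"].append(ep_recon / max(n_batches, 1))
            history["dis"].append(ep_dis / max(n_batches, 1))
            if vxn is not None:
                eps0 = np.zeros((len(vxn), cfg.latent_dim))
                zv, vm, vlv = self._forward_z(nets, vxn, vte, vco, vba, eps0)
                vloss = float(self._recon_loss(nets, zv, vm, vlv, vte, vco,
                                               vba, vxt, vlib).data)
            else:
                vloss = history["train_recon"][-1]
            history["val_recon"].append(vloss)
            if verbose:
                log.info("epoch %d recon %.3f val %.3f dis %.3f", epoch,
                         history["train_recon"][-1], vloss, history["dis"][-1])
            if vloss < best_val - 1e-6:
                best_val, patience_left = vloss, cfg.patience
                best_state = nn.get_state(all_params)
            elif epoch >= cfg.kl_warmup_epochs:  # no early stop mid-warm-up
                patience_left -= 1
                if patience_left <= 0:
                    break
        if best_state is not None:
            nn.set_state(all_params, best_state)
        return TemporalVAEResults(self, nets, history, seed)

    # -- forward pieces shared by fit and Results ----------------------------
    def _forward_z(self, nets: _Networks, xn, te, co, ba, eps):
        """Reparameterised z plus its posterior (mean, logvar) tensors."""
        h = nets.encoder(concat([Tensor(xn), Tensor(te), Tensor(co),
                                 Tensor(ba)]))
        mean = nets.enc_mean(h)
        logvar = nets.enc_logvar(h).clip(-10.0, 10.0)
        z = mean + (logvar * 0.5).exp() * Tensor(eps)
        return z, mean, logvar

    def _recon_loss(self, nets: _Networks, z, mean, logvar, te, co, ba,
                    x_counts, lib, kl_scale: float = 1.0):
        e = nets.interaction(concat([z, Tensor(te), Tensor(co)]))
        h = nets.dec_body(concat([e, Tensor(ba)]))
        mean_frac = softmax(nets.dec_mean_logits(h), axis=1)
        dropout = nets.dec_dropout(h)
        nll = zinb_nll_t(x_counts, mean_frac, nets.log_dispersion, dropout, lib)
        return nll + kl_scale * self.config.kl_weight * gaussian_kl_t(mean,
                                                                      logvar)


def _cross_entropy(logits: Tensor, classes: np.ndarray) -> Tensor:
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(classes)), classes] = 1.0
    lse = logsumexp(logits, axis=1)
    return (lse - (logits * Tensor(onehot)).sum(axis=1, keepdims=True)).mean()


class TemporalVAEResults:
    """A fitted temporal VAE: predictions, embeddings and diagnostics."""

    def __init__(self, model: TemporalVAE, nets: _Networks, history: dict,
                 seed: int):
        self.model = model
        self.nets = nets
        self.history = history
        self.seed = seed

    # -- encoding ------------------------------------------------------------
    def encode(self, data: AnnotatedMatrix | None = None) -> LatentPosterior:
        """Posterior over identity embeddings for ``data`` (default: all)."""
        data = data if data is not None else self.model.data
        if data.n_features != self.model.data.n_features:
            raise ValueError(
                f"feature dimension {data.n_features} does not match the "
                f"trained model ({self.model.data.n_features})")
        _, xn, te, co, ba, _ = self.model._inputs(data)
        h = self.nets.encoder(concat([Tensor(xn), Tensor(te), Tensor(co),
                                      Tensor(ba)]))
        mean = self.nets.enc_mean(h).data
        logvar = np.clip(self.nets.enc_logvar(h).data, -10, 10)
        return LatentPosterior(mean=mean, log_variance=logvar)

    def embeddings(self, data: AnnotatedMatrix | None = None) -> np.ndarray:
        """Posterior-mean identity embeddings (cells x latent_dim)."""
        return self.encode(data).mean

    def time_aware_embeddings(self, data: AnnotatedMatrix | None = None,
                              t_target=None, condition_target=None):
        """Interaction-layer output at the cells' own or a swapped time."""
        data = data if data is not None else self.model.data
        z = self.embeddings(data)
        times = (data.time if t_target is None
                 else np.broadcast_to(np.asarray(t_target, float), (len(z),)))
        cond = (data.condition if condition_target is None
                else np.full(len(z), condition_target, dtype=object))
        te = sinusoidal_encode(times, self.model.time_spec)
        co = self.model.condition_enc.encode(cond)
        return self.nets.interaction(concat([Tensor(z), Tensor(te),
                                             Tensor(co)])).data

    # -- decoding ------------------------------------------------------------
    def decode(self, z: np.ndarray, t_target, condition_target, batch_target,
               library) -> ZINBParams:
        """ZINB parameters for identity embeddings at a target time/condition."""
        z = np.atleast_2d(np.asarray(z, float))
        n = len(z)
        times = np.broadcast_to(np.asarray(t_target, float), (n,))
        cond = np.broadcast_to(np.asarray(condition_target, object), (n,))
        batch = np.broadcast_to(np.asarray(batch_target, object), (n,))
        lib = np.broadcast_to(np.asarray(library, float), (n,))
        te = sinusoidal_encode(times, self.model.time_spec)
        co = self.model.condition_enc.encode(cond)
        ba = self.model.batch_enc.encode(batch)
        e = self.nets.interaction(concat([Tensor(z), Tensor(te), Tensor(co)]))
        h = self.nets.dec_body(concat([e, Tensor(ba)]))
        mean_frac = softmax(self.nets.dec_mean_logits(h), axis=1).data
        dropout = self.nets.dec_dropout(h).data
        return ZINBParams(mean_fraction=mean_frac,
                          dispersion=np.exp(self.nets.log_dispersion.data),
                          dropout_logit=dropout, library=lib)

    def predict_profile(self, data: AnnotatedMatrix | None = None,
                        t_target=None, condition_target=None) -> np.ndarray:
        """Depth-corrected expression fractions at a swapped time/condition.

        Keeps each cell's posterior-mean identity embedding and batch, swaps
        the time and/or condition factor, and returns the decoder mean
        fractions (rows sum to 1).
        """
        data = data if data is not None else self.model.data
        post = self.encode(data)
        times = data.time if t_target is None else np.full(
            data.n_cells, float(t_target))
        cond = (data.condition if condition_target is None else
                np.full(data.n_cells, condition_target, dtype=object))
        params = self.decode(post.mean, times, cond, data.batch,
                             np.ones(data.n_cells))
        return params.mean_fraction

    def predict_trajectory(self, data: AnnotatedMatrix, time_grid,
                           condition_target=None) -> np.ndarray:
        """Per-cell predicted fraction trajectories, (cells, genes, T)."""
        time_grid = np.asarray(time_grid, float)
        out = np.empty((data.n_cells, data.n_features, len(time_grid)))
        for j, t in enumerate(time_grid):
            out[:, :, j] = self.predict_profile(data, t_target=t,
                                                condition_target=condition_target)
        return out

    # -- training losses evaluated as plain numbers --------------------------
    def rna_loss(self, data: AnnotatedMatrix) -> float:
        """Mean per-cell -ZINB loglik + KL on ``data`` (posterior mean z)."""
        xt, xn, te, co, ba, lib = self.model._inputs(data)
        eps0 = np.zeros((data.n_cells, self.model.config.latent_dim))
        z, m, lv = self.model._forward_z(self.nets, xn, te, co, ba, eps0)
        return float(self.model._recon_loss(self.nets, z, m, lv, te, co, ba,
                                            xt, lib).data)

    def discriminator_loss(self, data: AnnotatedMatrix) -> float:
        """Cross-entropy of the time discriminator on ``data``."""
        tclass = self.model._time_class_index(data.time)
        z = Tensor(self.embeddings(data))
        return float(_cross_entropy(self.nets.discriminator(z), tclass).data)

    def generator_loss(self, data: AnnotatedMatrix) -> float:
        """rna_loss minus the (frozen-)discriminator loss."""
        w = self.model.config.adversarial_weight
        return self.rna_loss(data) - w * self.discriminator_loss(data)

    def log_likelihood(self, data: AnnotatedMatrix) -> float:
        """Total ZINB log-likelihood of ``data`` under the reconstruction."""
        x = np.asarray(data.counts.todense())
        post = self.encode(data)
        params = self.decode(post.mean, data.time, data.condition, data.batch,
                             data.library_size)
        return zinb_log_likelihood(x, params)

    def summary(self) -> str:
        m, cfg = self.model, self.model.config
        lines = [
            "Temporal VAE results",
            "====================",
            f"cells (train/val/test):  {len(m.split.train_ids)}/"
            f"{len(m.split.val_ids)}/{len(m.split.test_ids)}",
            f"features:                {m.data.n_features}",
            f"latent dim:              {cfg.latent_dim}",
            f"time encoding dim:       {cfg.time_dim} "
            f"(min wavelength {cfg.min_wavelength} d)",
            f"condition levels:        {list(m.condition_enc.levels)}",
            f"batch levels:            {list(m.batch_enc.levels)}",
            f"time classes:            {np.round(m.time_classes, 4).tolist()}",
            f"epochs run:              {len(self.history['train_recon'])}",
            f"final train recon loss:  {self.history['train_recon'][-1]:.4f}",
            f"final val recon loss:    {self.history['val_recon'][-1]:.4f}",
            f"final discriminator CE:  {self.history['dis'][-1]:.4f} "
            f"(chance {np.log(len(m.time_classes)):.4f})",
            f"seed:                    {self.seed}",
        ]
        return "\n".join(lines)


# -- module-level operation aliases ------------------------------------------

def encode(results: TemporalVAEResults, data: AnnotatedMatrix) -> LatentPosterior:
    return results.encode(data)


def decode(results: TemporalVAEResults, z, t_target, condition_target,
           batch_target, library) -> ZINBParams:
    return results.decode(z, t_target, condition_target, batch_target, library)


def predict_profile(results: TemporalVAEResults, data: AnnotatedMatrix,
                    t_target=None, condition_target=None) -> np.ndarray:
    return results.predict_profile(data, t_target, condition_target)
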