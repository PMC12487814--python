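"""Count likelihoods and divergences for the temporal VAE.

Zero-inflated negative binomial (scRNA-seq counts), Bernoulli (binarised
scATAC-seq peaks) and the closed-form KL divergence between a diagonal
Gaussian posterior and the standard-normal prior.  Each function exists in
two forms: a plain-numpy version used for evaluation and testing, and an
autodiff version (suffix ``_t``) used inside training losses.

ZINB parameterisation (the scVI convention): per-cell mean
``mu = library * mean_fraction`` with ``mean_fraction`` a softmax over genes,
per-gene inverse-dispersion ``theta > 0`` shared across cells, and dropout
probability ``pi = sigmoid(dropout_logit)`` per gene per cell:

    P(x) = pi * 1[x = 0] + (1 - pi) * NB(x; mu, theta),
    NB(x; mu, theta) = Gamma(x + theta) / (Gamma(theta) x!)
                       * (theta / (theta + mu))**theta
                       * (mu / (theta + mu))**x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special as sp

from ._autodiff import Tensor

_EPS = 1e-8


@dataclass
class ZINBParams:
    """Zero-inflated negative-binomial parameters for a batch of cells."""

    mean_fraction: np.ndarray  # (cells, genes), rows sum to 1
    dispersion: np.ndarray     # (genes,) positive
    dropout_logit: np.ndarray  # (cells, genes)
    library: np.ndarray        # (cells,) positive

    def __post_init__(self):
        self.mean_fraction = np.atleast_2d(np.asarray(self.mean_fraction, float))
        self.dispersion = np.asarray(self.dispersion, float)
        self.dropout_logit = np.atleast_2d(np.asarray(self.dropout_logit, float))
        self.library = np.atleast_1d(np.asarray(self.library, float))
        if np.any(self.dispersion <= 0):
            raise ValueError("dispersion must be strictly positive")
        rowsums = self.mean_fraction.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-6):
            raise ValueError("mean_fraction rows must sum to 1")

    @property
    def mean(self) -> np.ndarray:
        return self.library[:, None] * self.mean_fraction

    @property
    def dropout(self) -> np.ndarray:
        return sp.expit(self.dropout_logit)


def zinb_log_likelihood(x, params: ZINBParams, per_cell: bool = False):
    """Log-likelihood of counts ``x`` (cells × genes) under ``params``.

    Returns the total over cells and genes (nats), or the per-cell sums when
    ``per_cell`` is true.  Uses the numerically stable logit form: with
    dropout logit ``s``,

        log P(0)   = logaddexp(s, theta*log(theta/(theta+mu))) - softplus(s)
        log P(x>0) = -softplus(s) + log NB(x; mu, theta),

    which avoids evaluating ``pi`` or ``1 - pi`` directly.  Validated against
    brute-force pmf summation in the tests.
    """
    x = np.atleast_2d(np.asarray(x, float))
    mu = np.maximum(params.mean, _EPS)
    theta = params.dispersion[None, :]
    s = params.dropout_logit
    log_theta_over = theta * (np.log(theta + _EPS) - np.log(theta + mu))
    # log P(x=0) = log(pi + (1-pi) * (theta/(theta+mu))^theta)
    #            = softplus(s + theta*log(...)) - softplus(s)   [pi=sigmoid(s)]
    case_zero = np.logaddexp(s, log_theta_over) - np.logaddexp(0.0, s)
    nb_log = (sp.gammaln(x + theta) - sp.gammaln(theta) - sp.gammaln(x + 1.0)
              + log_theta_over + x * (np.log(mu) - np.log(theta + mu)))
    case_pos = -np.logaddexp(0.0, s) + nb_log  # log(1-pi) + log NB
    ll = np.where(x < 0.5, case_zero, case_pos)
    return ll.sum(axis=1) if per_cell else float(ll.sum())


def zinb_nll_t(x: np.ndarray, mean_fraction: Tensor, log_dispersion: Tensor,
               dropout_logit: Tensor, library: np.ndarray) -> Tensor:
    """Mean-per-cell ZINB negative log-likelihood as an autodiff node."""
    x = np.atleast_2d(np.asarray(x, float))
    mask0 = (x < 0.5).astype(float)
    lib = Tensor(library[:, None])
    mu = mean_fraction * lib + _EPS
    theta = log_dispersion.exp() + _EPS
    log_theta_over = theta * (theta.log() - (theta + mu).log())
    s = dropout_logit
    # softplus-based stable mixture, mirroring zinb_log_likelihood
    m = Tensor(np.maximum(s.data, log_theta_over.data))
    case_zero = (((s - m).exp() + (log_theta_over - m).exp()).log() + m
                 - s.softplus())
    nb_log = ((theta + Tensor(x)).lgamma() - theta.lgamma()
              - Tensor(sp.gammaln(x + 1.0))
              + log_theta_over + Tensor(x) * (mu.log() - (theta + mu).log()))
    case_pos = -s.softplus() + nb_log
    ll = Tensor(mask0) * case_zero + Tensor(1.0 - mask0) * case_pos
    return -ll.sum(axis=1).mean()


def bernoulli_log_likelihood(x, peak_prob, per_cell: bool = False):
    """Log-likelihood of binary ``x`` under per-peak probabilities."""
    x = np.atleast_2d(np.asarray(x, float))
    if np.any((x != 0) & (x != 1)):
        raise ValueError("Bernoulli likelihood requires binary input")
    p = np.clip(np.atleast_2d(peak_prob), 1e-6, 1 - 1e-6)
    ll = x * np.log(p) + (1 - x) * np.log(1 - p)
    return ll.sum(axis=1) if per_cell else float(ll.sum())


def bernoulli_nll_t(x: np.ndarray, logits: Tensor) -> Tensor:
    """Mean-per-cell binary cross-entropy from decoder logits."""
    x = np.atleast_2d(np.asarray(x, float))
    # BCE(x, sigmoid(l)) = softplus(l) - x*l
    ll = logits.softplus() - Tensor(x) * logits
    return ll.sum(axis=1).mean()


def gaussian_kl(mean, log_variance):
    """Closed-form KL( N(mean, diag exp(log_variance)) || N(0, I) ), per row."""
    mean = np.atleast_2d(np.asarray(mean, float))
    log_variance = np.atleast_2d(np.asarray(log_variance, float))
    return 0.5 * (mean**2 + np.exp(log_variance) - log_variance - 1.0).sum(axis=1)


def gaussian_kl_t(mean: Tensor, log_variance: Tensor) -> Tensor:
    """Autodiff mean-per-cell KL to the standard-normal prior."""
    per_cell = (mean * mean + log_variance.exp() - log_variance - 1.0).sum(axis=1)
    return per_cell.mean() * 0.5
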