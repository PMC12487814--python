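"""Hyperparameter grid, rank-based model selection, and ensemble training.

The grid is deliberately small: latent dimension in {25, 50, 100} (times
MSE weight lambda in {1, 100, 10000} for the multimodal model), with the
number of hidden layers fixed at two and the time-encoding dimension fixed
at 50.  Candidates are compared on the validation set by summing per-metric
ranks (cross-time pseudobulk Pearson, LISI between neighbouring time
points, LISI around the held-out time point, plus batch / cross-modality
variants when available); the summed ranks are rescaled so the best model
has rank exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .model import VAEConfig
from .multimodal import MultimodalConfig

log = logging.getLogger(__name__)

LATENT_GRID = (25, 50, 100)
LAMBDA_GRID = (1.0, 100.0, 10000.0)
WAVELENGTH_GRID = (1.0,)

#: metrics where larger is better; all others are minimised
HIGHER_IS_BETTER = {"cross_time_pseudobulk_pearson", "lisi_time_neighbors",
                    "lisi_heldout_neighbors", "lisi_batch",
                    "lisi_cross_modality"}


@dataclass
class ModelScoreCard:
    """Validation metrics for one grid candidate."""

    model_id: str
    metrics: dict[str, float]
    summed_rank: float = float("nan")


def grid_candidates(modality: str, base: VAEConfig = VAEConfig()):
    """Enumerate the hyperparameter grid for one modality.

    Returns 3 :class:`VAEConfig` for ``modality="rna"`` and 9
    :class:`MultimodalConfig` (3 latent dims x 3 lambdas) for
    ``modality="multi"``.
    """
    singles = [replace(base, latent_dim=ld, min_wavelength=wl,
                       hidden_layers=2)
               for ld in LATENT_GRID for wl in WAVELENGTH_GRID]
    if modality == "rna":
        return singles
    if modality == "multi":
        return [MultimodalConfig(mse_weight=lam, vae=cfg)
                for cfg in singles for lam in LAMBDA_GRID]
    raise ValueError(f"unknown modality {modality!r}")


def select_best(scorecards: list[ModelScoreCard]) -> str:
    """Summed-rank selection; mutates ``summed_rank`` on each card.

    Per metric, candidates are ranked (rank 1 = best, midranks for ties,
    orientation per :data:`HIGHER_IS_BETTER`); ranks are summed over the
    metrics and rescaled so the minimum is exactly 1.  Ties on the summed
    rank break toward the earlier card (callers order the grid by smaller
    latent dimension, then smaller lambda).
    """
    if len(scorecards) < 2:
        raise ValueError("model selection needs at least two candidates")
    keys = set(scorecards[0].metrics)
    for card in scorecards[1:]:
        missing = keys.symmetric_difference(card.metrics)
        if missing:
            raise ValueError(f"scorecard {card.model_id!r} is missing or adds "
                             f"metric(s): {sorted(missing)}")
    from scipy.stats import rankdata

    total = np.zeros(len(scorecards))
    for key in sorted(keys):
        vals = np.array([c.metrics[key] for c in scorecards], float)
        if np.any(np.isnan(vals)):
            raise ValueError(f"metric {key!r} is NaN for some candidate")
        if key in HIGHER_IS_BETTER:
            vals = -vals
        total += rankdata(vals)
    scaled = total / total.min()
    order = np.lexsort((np.arange(len(scorecards)), scaled))
    for card, s in zip(scorecards, scaled):
        card.summed_rank = float(s)
    return scorecards[order[0]].model_id


def train_ensemble(fit_one, n_models: int = 10, seed: int = 0,
                   holdout_strategy: str = "random-time",
                   time_points=None) -> list:
    """Train ``n_models`` models under distinct seeds for median aggregation.

    ``fit_one(seed, holdout_time)`` builds and fits one model; with
    ``holdout_strategy="random-time"`` each member additionally drops one
    randomly chosen time point from training (sampling with replacement,
    with a log message, when there are fewer time points than members);
    with ``"seed-only"`` every member sees all time points.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(seed)
    member_seeds = rng.integers(0, 2**31 - 1, size=n_models)
    holdouts: list = [None] * n_models
    if holdout_strategy == "random-time":
        if time_points is None:
            raise ValueError("random-time holdout needs the time points")
        times = np.asarray(time_points, float)
        replace_draw = len(times) < n_models
        if replace_draw:
            log.info("fewer time points (%d) than ensemble members (%d); "
                     "sampling held-out times with replacement", len(times),
                     n_models)
        holdouts = list(rng.choice(times, size=n_models,
                                   replace=replace_draw))
    elif holdout_strategy != "seed-only":
        raise ValueError(f"unknown holdout strategy {holdout_strategy!r}")
    return [fit_one(int(s), h) for s, h in zip(member_seeds, holdouts)]


def median_aggregate(arrays: list[np.ndarray]) -> np.ndarray:
    """Element-wise median across ensemble members."""
    return np.median(np.stack(arrays), axis=0)
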