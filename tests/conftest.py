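"""Shared fixtures: simulations and trained models reused across the suite.

Training-based fixtures are session-scoped so each model ensemble is fitted
once; sizes are desk-scale versions of the standard study conditions (100
cells per cell type per time point, noise SD 1, 0.002-day pseudotime steps).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import chronovae as cv

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

RNA_HELDOUT_TIMES = (6.75, 7.25, 7.75, 8.25)
ENSEMBLE_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def rna_sim():
    cfg = cv.preset("sim-pseudotime", seed=11, n_cell_types=3, n_genes=30,
                    cells_per_type_per_time=100)
    return cv.simulate_rna(cfg)


@pytest.fixture(scope="session")
def fit_config():
    return cv.VAEConfig(latent_dim=16, time_dim=50, max_epochs=400,
                        patience=20)


@pytest.fixture(scope="session")
def rna_heldout_fits(rna_sim, fit_config):
    """Per held-out time: (split, list of fitted results across seeds)."""
    data, _ = rna_sim
    out = {}
    for ht in RNA_HELDOUT_TIMES:
        split = cv.make_split(data, holdout_times=(ht,), seed=0)
        results = [cv.TemporalVAE(data, split, fit_config).fit(seed=s)
                   for s in ENSEMBLE_SEEDS]
        out[ht] = (split, results)
    return out


@pytest.fixture(scope="session")
def sex_sim():
    cfg = cv.preset("sex", seed=7, n_cell_types=2, n_genes=40,
                    cells_per_type_per_time=60)
    return cv.simulate_sex(cfg)


@pytest.fixture(scope="session")
def sex_ensemble(sex_sim, fit_config):
    """Ten models, each with a random time point held out: the robustness
    strategy that stabilises condition-swap predictions at time points where
    only one sex was sampled."""
    from chronovae.selection import train_ensemble

    data, _ = sex_sim

    def fit_one(seed, holdout):
        split = cv.make_split(data, holdout_times=(holdout,), seed=seed)
        return cv.TemporalVAE(data, split, fit_config).fit(seed=seed)

    return train_ensemble(fit_one, n_models=10, seed=0,
                          holdout_strategy="random-time",
                          time_points=np.unique(data.time))


@pytest.fixture(scope="session")
def mm_sim():
    cfg = cv.preset("multimodal", seed=5, n_cell_types=2, n_genes=60,
                    cells_per_type_per_time=100,
                    multimodal=cv.MultimodalDesign(n_peaks=30, n_linked=20))
    return cv.simulate_multimodal(cfg)


@pytest.fixture(scope="session")
def mm_ensemble(mm_sim):
    rna, atac, pairing, _ = mm_sim
    vcfg = cv.VAEConfig(latent_dim=16, time_dim=50, max_epochs=500,
                        patience=30)
    return [cv.MultimodalVAE(rna, atac, pairing,
                             cv.MultimodalConfig(mse_weight=100.0, vae=vcfg),
                             split_seed=s).fit(seed=s)
            for s in range(5)]


@pytest.fixture(scope="session")
def tiny_rna_sim():
    """A few hundred cells for fast contract (non-recovery) tests."""
    cfg = cv.SimulationConfig(n_cell_types=2, n_genes=20,
                              time_points=(7.0, 7.5, 8.0),
                              cells_per_type_per_time=40, noise_sd=1.0,
                              seed=3)
    return cv.simulate_rna(cfg)


@pytest.fixture(scope="session")
def tiny_fit(tiny_rna_sim):
    data, _ = tiny_rna_sim
    cfg = cv.VAEConfig(latent_dim=8, time_dim=16, max_epochs=30,
                       kl_warmup_epochs=10, patience=30, batch_size=64)
    split = cv.make_split(data, holdout_times=(), seed=0)
    return cv.TemporalVAE(data, split, cfg).fit(seed=0)


@pytest.fixture(scope="session")
def tiny_mm_fit():
    cfg = cv.preset("multimodal", seed=1, n_cell_types=2, n_genes=24,
                    cells_per_type_per_time=40,
                    multimodal=cv.MultimodalDesign(n_peaks=20, n_linked=12))
    rna, atac, pairing, truth = cv.simulate_multimodal(cfg)
    vcfg = cv.VAEConfig(latent_dim=8, time_dim=16, max_epochs=25,
                        kl_warmup_epochs=10, patience=25, batch_size=64)
    mm = cv.MultimodalVAE(rna, atac, pairing,
                          cv.MultimodalConfig(mse_weight=10.0, vae=vcfg))
    return mm, mm.fit(seed=0), (rna, atac, pairing, truth)


def probe_accuracy(embeddings: np.ndarray, times: np.ndarray) -> tuple[float, float]:
    """Held-out accuracy of a logistic probe predicting the time class,
    plus the majority-class chance level."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    classes = np.unique(times)
    y = np.searchsorted(classes, times)
    Xtr, Xte, ytr, yte = train_test_split(embeddings, y, test_size=0.3,
                                          random_state=0, stratify=y)
    clf = LogisticRegression(max_iter=2000).fit(Xtr, ytr)
    return float(clf.score(Xte, yte)), float(np.bincount(yte).max() / len(yte))
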