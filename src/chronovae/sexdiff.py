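"""Cross-condition (sex) differential prediction.

Because most developmental time points are sampled in one sex only, sex
differences cannot be computed directly from the data.  Instead, every
cell's profile is predicted under both condition factors with its identity
embedding fixed, and a per-gene *sex-biased score* is computed as the
normalised Wilcoxon signed-rank statistic of (female prediction - male
prediction) across the cells of a cell type: 1 means extremely
female-biased, 0 extremely male-biased, 0.5 no shift.  Ensembles are
aggregated by the median score.  Downstream utilities call consistently
biased genes across time, test knockout-derived gene sets for score shifts,
and run the protein-interaction odds-ratio permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import AnnotatedMatrix
from .metrics import paired_rank_statistic
from .model import TemporalVAEResults

log = logging.getLogger(__name__)

MIN_CELLS_SCORE = 50   # minimum cells per (cell type, time) for a score
MIN_CELLS_TIME = 25    # minimum cells for a time point to enter consistency


@dataclass(frozen=True)
class SexBiasRow:
    gene: str
    cell_type: str
    time: float
    score: float
    n_cells: int
    log_fold_change: float


def sex_biased_scores(ensemble: list[TemporalVAEResults],
                      cells: AnnotatedMatrix, cell_type: str, time: float,
                      female: str = "F", male: str = "M",
                      pool_neighbors: bool = True) -> pd.DataFrame:
    """Per-gene sex-bias table for one cell type at one time point.

    For every model in the ensemble, each selected cell is decoded under the
    female and the male condition factor (same identity embedding, same
    time); the per-gene score is the normalised signed-rank statistic of the
    paired predictions across cells, and the ensemble is aggregated by the
    median score.  With ``pool_neighbors`` (the default, the robust
    strategy) cells from the previous and subsequent observed time points
    are pooled with the current one.  Requires more than
    ``MIN_CELLS_SCORE`` cells; otherwise an empty frame is returned with a
    log entry.
    """
    sel = _select_cells(cells, cell_type, time, pool_neighbors)
    if sel.n_cells <= MIN_CELLS_SCORE:
        log.info("skipping %s @ %s: only %d cells (need > %d)", cell_type,
                 time, sel.n_cells, MIN_CELLS_SCORE)
        return _empty_table()
    scores, lfcs = [], []
    for res in ensemble:
        f_pred = res.predict_profile(sel, t_target=time,
                                     condition_target=female)
        m_pred = res.predict_profile(sel, t_target=time,
                                     condition_target=male)
        scores.append([paired_rank_statistic(f_pred[:, g], m_pred[:, g])
                       for g in range(sel.n_features)])
        lfcs.append(np.median(np.log((f_pred + 1e-9) / (m_pred + 1e-9)),
                              axis=0))
    score = np.median(np.asarray(scores), axis=0)
    lfc = np.median(np.asarray(lfcs), axis=0)
    return pd.DataFrame({
        "gene": cells.feature_ids,
        "cell_type": cell_type,
        "time": float(time),
        "score": score,
        "n_cells": sel.n_cells,
        "log_fold_change": lfc,
    })


def mean_predicted_expression(ensemble: list[TemporalVAEResults],
                              cells: AnnotatedMatrix, cell_type: str,
                              time: float, female: str = "F",
                              male: str = "M",
                              pool_neighbors: bool = True) -> np.ndarray:
    """Per-gene predicted mean fraction averaged over sexes (for filtering)."""
    sel = _select_cells(cells, cell_type, time, pool_neighbors)
    out = np.zeros(cells.n_features)
    for res in ensemble:
        f_pred = res.predict_profile(sel, t_target=time, condition_target=female)
        m_pred = res.predict_profile(sel, t_target=time, condition_target=male)
        out += (f_pred.mean(axis=0) + m_pred.mean(axis=0)) / 2
    return out / len(ensemble)


def _select_cells(cells: AnnotatedMatrix, cell_type: str, time: float,
                  pool_neighbors: bool) -> AnnotatedMatrix:
    mask_type = (cells.cell_type == cell_type) if cells.cell_type is not None \
        else np.ones(cells.n_cells, bool)
    times = np.unique(cells.time)
    pos = int(np.argmin(np.abs(times - time)))
    keep_times = {times[pos]}
    if pool_neighbors:
        if pos > 0:
            keep_times.add(times[pos - 1])
        if pos < len(times) - 1:
            keep_times.add(times[pos + 1])
    mask_time = np.isin(cells.time, list(keep_times))
    return cells.subset(mask_type & mask_time)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["gene", "cell_type", "time", "score",
                                 "n_cells", "log_fold_change"])


def consistent_sex_biased_genes(table: pd.DataFrame,
                                expression: pd.DataFrame | None = None
                                ) -> tuple[set, set]:
    """Genes whose score stays strictly >0.5 (female) or <0.5 (male).

    ``table`` is a concatenation of :func:`sex_biased_scores` outputs for one
    cell type; time points with ``n_cells`` <= 25 are dropped first.  When
    ``expression`` (columns ``gene, time, mean_expression``) is given, only
    the top half of genes by predicted mean expression at *every* retained
    time point is eligible — the paper's "consistently expressed" filter.
    """
    if table.empty:
        log.warning("no scored time points; returning empty gene sets")
        return set(), set()
    table = table[table["n_cells"] > MIN_CELLS_TIME]
    if table.empty:
        log.warning("no time point retains > %d cells", MIN_CELLS_TIME)
        return set(), set()
    eligible = set(table["gene"])
    if expression is not None:
        for t, sub in expression.groupby("time"):
            med = sub["mean_expression"].median()
            eligible &= set(sub.loc[sub["mean_expression"] >= med, "gene"])
    pivot = table.pivot_table(index="gene", columns="time", values="score")
    pivot = pivot.dropna()
    female = {g for g, row in pivot.iterrows()
              if g in eligible and (row > 0.5).all()}
    male = {g for g, row in pivot.iterrows()
            if g in eligible and (row < 0.5).all()}
    return female, male


def geneset_shift_test(scores: pd.Series, set_up: set, set_down: set) -> float:
    """One-sided rank-sum p that KO-downregulated genes score higher.

    ``scores`` maps gene -> sex-bias score.  ``set_down`` holds genes
    downregulated in the knockout (candidate female-biased, expected high
    scores); ``set_up`` holds upregulated genes.  Both sets are intersected
    with the scored genes and must remain non-empty.
    """
    down = scores[scores.index.isin(set_down)].to_numpy()
    up = scores[scores.index.isin(set_up)].to_numpy()
    if len(down) == 0 or len(up) == 0:
        raise ValueError("a gene set is empty after intersecting with the "
                         "scored genes")
    return float(stats.mannwhitneyu(down, up, alternative="greater").pvalue)


def ppi_odds_ratio(edges, female_autosomal: set, female_x: set,
                   all_autosomal: set, n_perm: int = 100,
                   min_edges: int = 50, seed: int = 0):
    """Odds ratio of protein interactions linking female-biased autosomal
    genes to female-biased X-linked genes, with a permutation p-value.

    ``edges`` is an iterable of (gene_a, gene_b) pairs.  The odds ratio
    compares interactions {female autosomal} x {female X} against
    {non-female autosomal} x {female X}.  The null resamples autosomal sets
    of the same size ``n_perm`` times; the p-value is plus-one corrected.
    Returns ``(odds_ratio, p_value, status)`` where status is ``"ok"`` or
    ``"refused: fewer than min_edges relevant interactions"``.
    """
    female_autosomal = set(female_autosomal)
    female_x = set(female_x)
    all_autosomal = set(all_autosomal) | female_autosomal
    edge_list = [(a, b) for a, b in edges]
    rng = np.random.default_rng(seed)

    def _odds(auto_set: set) -> tuple[float, int]:
        in_edges = out_edges = 0
        other = all_autosomal - auto_set
        for a, b in edge_list:
            pair = {a, b}
            if pair & female_x:
                partner = pair - female_x
                if not partner:
                    continue
                g = next(iter(partner))
                if g in auto_set:
                    in_edges += 1
                elif g in other:
                    out_edges += 1
        n_in, n_out = len(auto_set), len(other)
        odds_in = in_edges / max(n_in * len(female_x), 1)
        odds_out = out_edges / max(n_out * len(female_x), 1)
        return (np.inf if odds_out == 0 and odds_in > 0
                else (odds_in / odds_out if odds_out > 0 else np.nan),
                in_edges + out_edges)

    observed, n_relevant = _odds(female_autosomal)
    if n_relevant < min_edges:
        return (float("nan"), float("nan"),
                f"refused: {n_relevant} relevant interactions < {min_edges}")
    null = np.empty(n_perm)
    pool = sorted(all_autosomal)
    for i in range(n_perm):
        sample = set(rng.choice(pool, size=len(female_autosomal),
                                replace=False))
        null[i], _ = _odds(sample)
    p = (1 + np.sum(null >= observed)) / (n_perm + 1)
    return float(observed), float(p), "ok"
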