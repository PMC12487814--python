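"""Time-lagged cross-correlation between expression and accessibility.

For a query cell, predicted gene-expression and proximal-peak accessibility
trajectories are laid on a dense uniform time grid (0.01-day step over
[7.5, 9] days by default).  For each (peak, gene) pair the accessibility
trajectory is shifted along time in 0.01-day steps through [-0.5, +0.5]
(101 shifts) and the Pearson correlation with the expression trajectory is
computed inside a core window ([8, 8.5] by default), yielding a
101-dimensional TLCC vector per pair per cell.

Sign convention: ``TLCC(tau) = corr(expr(t), acc(t + tau))``, so a peak
whose accessibility pattern occurs *earlier* than its gene's expression
pattern peaks at a negative shift and is categorised "before" (chromatin
priming); a positive argmax shift is "after".

Trajectories are predicted directly on the grid, so shifting is exact index
arithmetic — no interpolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_SHIFT_RANGE = 0.5
DEFAULT_STEP = 0.01


def default_shifts(step: float = DEFAULT_STEP,
                   shift_range: float = DEFAULT_SHIFT_RANGE) -> np.ndarray:
    """The canonical shift ladder: -0.5 .. +0.5 day in 0.01-day steps (101)."""
    n = int(round(shift_range / step))
    return np.round(np.arange(-n, n + 1) * step, 10)


@dataclass(frozen=True)
class TLCCConfig:
    interval: tuple[float, float] = (7.5, 9.0)
    core_window: tuple[float, float] = (8.0, 8.5)
    step: float = DEFAULT_STEP
    shift_range: float = DEFAULT_SHIFT_RANGE
    k_top: int = 25
    n_keep: int = 4
    min_max_corr: float = 0.5
    min_cells: int = 2

    def time_grid(self) -> np.ndarray:
        lo, hi = self.interval
        n = int(round((hi - lo) / self.step))
        return np.round(lo + np.arange(n + 1) * self.step, 10)

    def __post_init__(self):
        lo, hi = self.interval
        c0, c1 = self.core_window
        if not (lo <= c0 < c1 <= hi):
            raise ValueError("core window must sit inside the interval")
        if c0 - lo < self.shift_range - 1e-9 or hi - c1 < self.shift_range - 1e-9:
            raise ValueError("interval must pad the core window by at least "
                             "the maximum shift on each side")


@dataclass
class TrajectoryGrid:
    """Predicted feature trajectories on a dense, uniform time grid."""

    time_grid: np.ndarray
    values: np.ndarray  # (features, T)
    core_window: tuple[float, float] = (8.0, 8.5)

    def __post_init__(self):
        self.time_grid = np.asarray(self.time_grid, float)
        self.values = np.atleast_2d(np.asarray(self.values, float))
        steps = np.diff(self.time_grid)
        if len(steps) == 0 or np.any(steps <= 0) or not np.allclose(
                steps, steps[0], atol=1e-9):
            raise ValueError("time grid must be strictly ascending and uniform")
        if self.values.shape[1] != len(self.time_grid):
            raise ValueError("values must have one column per grid point")


@dataclass
class TLCCMatrix:
    """Shift-indexed Pearson correlations, one column per (pair, cell)."""

    shifts: np.ndarray
    matrix: np.ndarray                       # (n_shifts, n_columns)
    pair_index: list[tuple[str, str, str]]   # (peak_id, gene_id, cell_id)

    def __post_init__(self):
        self.shifts = np.asarray(self.shifts, float)
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.shifts):
            raise ValueError("matrix must be (n_shifts, n_columns)")
        if self.matrix.shape[1] != len(self.pair_index):
            raise ValueError("one pair_index entry per matrix column required")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{p}|{g}|{c}" for p, g, c in self.pair_index]
        return pd.DataFrame(self.matrix, index=self.shifts, columns=cols)


# -- neighbour selection ------------------------------------------------------

def select_neighbors(ensemble_embeddings: list[np.ndarray], cell_ids: list[str],
                     query_cell: str, k_top: int = 25,
                     n_keep: int = 4) -> list[str]:
    """Ensemble-consensus nearest neighbours of a query cell.

    Per model, cells are ranked by Euclidean distance to the query on the
    identity embeddings and the top ``k_top`` retained; a cell absent from a
    model's top list contributes rank ``k_top + 1`` to its summed rank.
    Cells absent from every model's top list are excluded.  Returns the
    query followed by the ``n_keep`` best cells by summed rank (fewer, with
    a warning, if fewer are eligible).
    """
    ids = list(cell_ids)
    q = ids.index(query_cell)
    # pass 1: the candidate set is any cell in some model's top list
    per_model_ranks: list[dict[int, int]] = []
    seen: set[int] = set()
    for emb in ensemble_embeddings:
        d = np.linalg.norm(emb - emb[q], axis=1)
        d[q] = np.inf
        order = np.argsort(d, kind="stable")[:k_top]
        ranks = {int(c): r + 1 for r, c in enumerate(order)}
        per_model_ranks.append(ranks)
        seen.update(ranks)
    # pass 2: summed ranks with absent-from-a-run contributing k_top + 1
    sum_rank = {c: 0.0 for c in seen}
    for ranks in per_model_ranks:
        for c in sum_rank:
            sum_rank[c] += ranks.get(c, k_top + 1)
    ordered = sorted(sum_rank, key=lambda c: (sum_rank[c], c))
    if len(ordered) < n_keep:
        warnings.warn(f"only {len(ordered)} eligible neighbours "
                      f"(requested {n_keep})")
    return [query_cell] + [ids[c] for c in ordered[:n_keep]]


# -- peak-to-gene assignment --------------------------------------------------

def assign_proximal_peaks(tss_table: pd.DataFrame, peak_bed: pd.DataFrame,
                          window: int = 200_000) -> list[tuple[str, str]]:
    """Pair each peak with genes whose upstream window it overlaps.

    ``tss_table`` columns: ``chrom, position, strand, gene_id`` (0-based TSS
    position); ``peak_bed`` columns: ``chrom, start, end, peak_id``
    (BED-style 0-based half-open).  The upstream window is the single
    ``window``-bp region on the 5' side of the TSS, strand-aware: for a
    ``+`` gene ``[position - window, position)``, for a ``-`` gene
    ``[position + 1, position + 1 + window)``.  Peaks on chromosomes absent
    from the TSS table (or vice versa) are skipped with a warning.
    """
    pairs: list[tuple[str, str]] = []
    tss_chroms = set(tss_table["chrom"])
    peak_chroms = set(peak_bed["chrom"])
    for missing in sorted(peak_chroms - tss_chroms):
        warnings.warn(f"peak chromosome {missing!r} absent from TSS table; "
                      "skipping")
    for missing in sorted(tss_chroms - peak_chroms):
        warnings.warn(f"TSS chromosome {missing!r} has no peaks; skipping")
    for chrom in sorted(tss_chroms & peak_chroms):
        genes = tss_table[tss_table["chrom"] == chrom]
        peaks = peak_bed[peak_bed["chrom"] == chrom]
        for _, g in genes.iterrows():
            pos, strand = int(g["position"]), str(g["strand"])
            if strand == "+":
                lo, hi = pos - window, pos
            elif strand == "-":
                lo, hi = pos + 1, pos + 1 + window
            else:
                raise ValueError(f"bad strand {strand!r} for {g['gene_id']!r}")
            hit = peaks[(peaks["start"] < hi) & (peaks["end"] > lo)]
            pairs.extend((str(p), str(g["gene_id"])) for p in hit["peak_id"])
    return pairs


# -- the statistic ------------------------------------------------------------

def tlcc_vector(expr_traj: TrajectoryGrid | np.ndarray,
                acc_traj: TrajectoryGrid | np.ndarray,
                shifts: np.ndarray | None = None,
                core_window: tuple[float, float] = (8.0, 8.5),
                time_grid: np.ndarray | None = None) -> np.ndarray:
    """Shift-indexed Pearson correlations of one expression/accessibility pair.

    Entry ``j`` is ``corr(expr(t), acc(t + shifts[j]))`` over core-window
    grid points.  Shifts must be integer multiples of the grid step, and the
    grid must pad the core window by the largest shift on both sides.
    Constant windows yield NaN entries.
    """
    if isinstance(expr_traj, TrajectoryGrid):
        time_grid = expr_traj.time_grid
        core_window = expr_traj.core_window
        expr = expr_traj.values.ravel()
    else:
        expr = np.asarray(expr_traj, float).ravel()
    acc = (acc_traj.values.ravel() if isinstance(acc_traj, TrajectoryGrid)
           else np.asarray(acc_traj, float).ravel())
    if time_grid is None:
        raise ValueError("a time grid is required")
    time_grid = np.asarray(time_grid, float)
    if shifts is None:
        shifts = default_shifts()
    dt = time_grid[1] - time_grid[0]
    core = np.flatnonzero((time_grid >= core_window[0] - 1e-9)
                          & (time_grid <= core_window[1] + 1e-9))
    out = np.empty(len(shifts))
    e = expr[core]
    e_c = e - e.mean()
    e_ss = float(e_c @ e_c)
    for j, s in enumerate(shifts):
        k = int(round(s / dt))
        if not np.isclose(k * dt, s, atol=1e-9):
            raise ValueError(f"shift {s} is not a multiple of grid step {dt}")
        idx = core + k
        if idx[0] < 0 or idx[-1] >= len(time_grid):
            raise ValueError("grid does not cover the core window shifted "
                             f"by {s}")
        a = acc[idx]
        a_c = a - a.mean()
        a_ss = float(a_c @ a_c)
        if e_ss <= 0 or a_ss <= 0:
            out[j] = np.nan
        else:
            out[j] = float(e_c @ a_c) / np.sqrt(e_ss * a_ss)
    return out


def build_tlcc_matrix(ensemble, query_cell: str,
                      pairs: list[tuple[str, str]],
                      config: TLCCConfig = TLCCConfig()) -> TLCCMatrix:
    """TLCC matrix for a query cell and its consensus neighbours.

    ``ensemble`` is a list of fitted :class:`~chronovae.multimodal.MultimodalResults`.
    Cell selection uses RNA identity embeddings summed across the ensemble;
    expression and accessibility trajectories are the ensemble *medians* of
    the per-model predictions on the dense grid.  Columns are concatenated
    across the selected cells.
    """
    if not pairs:
        warnings.warn("no (peak, gene) pairs supplied; returning empty matrix")
        return TLCCMatrix(default_shifts(config.step, config.shift_range),
                          np.empty((len(default_shifts(config.step,
                                                       config.shift_range)), 0)),
                          [])
    rna_data = ensemble[0].model.rna_model.data
    cell_ids = list(rna_data.cell_ids)
    embeddings = [r.rna.embeddings(rna_data) for r in ensemble]
    cells = select_neighbors(embeddings, cell_ids, query_cell,
                             k_top=config.k_top, n_keep=config.n_keep)
    grid = config.time_grid()
    shifts = default_shifts(config.step, config.shift_range)
    gene_pos = {g: i for i, g in enumerate(rna_data.feature_ids)}
    peak_pos = {p: i for i, p in
                enumerate(ensemble[0].model.atac_data.feature_ids)}
    sub = rna_data.subset_by_ids(cells)
    expr = np.median(np.stack([r.rna.predict_trajectory(sub, grid)
                               for r in ensemble]), axis=0)
    acc = np.median(np.stack([r.predict_atac_trajectory(sub, grid)
                              for r in ensemble]), axis=0)
    cols, index = [], []
    for ci, cell in enumerate(cells):
        for peak, gene in pairs:
            vec = tlcc_vector(expr[ci, gene_pos[gene]],
                              acc[ci, peak_pos[peak]], shifts,
                              config.core_window, grid)
            cols.append(vec)
            index.append((peak, gene, cell))
    return TLCCMatrix(shifts, np.column_stack(cols), index)


def filter_and_categorize(tlcc: TLCCMatrix, min_max_corr: float = 0.5,
                          min_cells: int = 2) -> pd.DataFrame:
    """Filter pairs and call accessibility "before" or "after" expression.

    Columns whose maximum correlation falls below ``min_max_corr`` are
    dropped; a (peak, gene) pair must survive in at least ``min_cells``
    cells.  Per retained column the best shift is the argmax correlation
    (ties broken toward the smallest ``|shift|``; an exact +/- tie is
    uncategorised).  A pair's category is "before" when every retained
    cell's best shift is negative, "after" when every one is positive;
    pairs with zero best shifts or disagreeing signs are flagged
    "uncategorized" / "discordant".
    """
    rows = []
    by_pair: dict[tuple[str, str], list[float]] = {}
    for col, (peak, gene, cell) in enumerate(tlcc.pair_index):
        vec = tlcc.matrix[:, col]
        if np.all(np.isnan(vec)) or np.nanmax(vec) < min_max_corr:
            continue
        best = _best_shift(tlcc.shifts, vec)
        by_pair.setdefault((peak, gene), []).append(best)
    for (peak, gene), bests in by_pair.items():
        if len(bests) < min_cells:
            continue
        if any(b is None for b in bests):
            category = "uncategorized"
        elif all(b < 0 for b in bests):
            category = "before"
        elif all(b > 0 for b in bests):
            category = "after"
        elif any(b == 0 for b in bests):
            category = "uncategorized"
        else:
            category = "discordant"
        rows.append({"peak_id": peak, "gene_id": gene,
                     "n_cells": len(bests),
                     "median_best_shift": float(np.median(
                         [b for b in bests if b is not None])),
                     "category": category})
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "n_cells",
                                       "median_best_shift", "category"])


def _best_shift(shifts: np.ndarray, vec: np.ndarray) -> float | None:
    """Argmax shift; ties break to smallest |shift|, exact +/- tie -> None."""
    valid = ~np.isnan(vec)
    vmax = vec[valid].max()
    at_max = shifts[valid & np.isclose(vec, vmax)]
    best_abs = np.min(np.abs(at_max))
    cands = at_max[np.isclose(np.abs(at_max), best_abs)]
    if len(cands) > 1 and not np.allclose(cands, cands[0]):
        return None
    return float(cands[0])
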