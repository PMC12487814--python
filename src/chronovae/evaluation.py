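"""Held-out time-point evaluation against nearest-time baselines.

For each cell type with enough cells at a held-out time point, the model's
cross-time prediction (query cells taken from the nearest observed time
point, time factor swapped to the held-out time) is compared with the true
held-out pseudobulk via Pearson correlation, against a baseline that simply
reuses the query time point's pseudobulk.  Cell-type labels are never seen
by the model — they only group cells for this evaluation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import AnnotatedMatrix, SplitPlan
from .metrics import pseudobulk
from .model import TemporalVAEResults

MIN_CELLS_EVAL = 25


def heldout_time_evaluation(results: TemporalVAEResults, data: AnnotatedMatrix,
                            split: SplitPlan, holdout_time: float,
                            direction: str = "previous",
                            min_cells: int = MIN_CELLS_EVAL) -> pd.DataFrame:
    """Per-cell-type pseudobulk Pearson of prediction vs nearest-time baseline.

    ``direction`` selects the query time point: ``"previous"`` (closest
    earlier), ``"next"`` (closest later) or ``"nearest"``.  Returns one row
    per retained cell type with columns ``pearson_model`` and
    ``pearson_baseline``.
    """
    if data.cell_type is None:
        raise ValueError("evaluation requires cell-type labels")
    train = data.subset_by_ids(split.train_ids)
    times = np.unique(train.time)
    if direction == "previous":
        cands = times[times < holdout_time]
        query_time = cands.max() if len(cands) else times.min()
    elif direction == "next":
        cands = times[times > holdout_time]
        query_time = cands.min() if len(cands) else times.max()
    elif direction == "nearest":
        query_time = times[np.argmin(np.abs(times - holdout_time))]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    held = data.subset(np.isclose(data.time, holdout_time))
    query = data.subset(np.isclose(data.time, query_time))
    rows = []
    for ct in sorted(set(held.cell_type)):
        held_ct = held.subset(held.cell_type == ct)
        query_ct = query.subset(query.cell_type == ct)
        if held_ct.n_cells < min_cells or query_ct.n_cells < min_cells:
            continue
        truth_pb = pseudobulk(held_ct.counts)
        base_pb = pseudobulk(query_ct.counts)
        pred = results.predict_profile(query_ct, t_target=holdout_time)
        pred_pb = pred.mean(axis=0)
        rows.append({
            "cell_type": ct,
            "holdout_time": holdout_time,
            "query_time": float(query_time),
            "n_cells": held_ct.n_cells,
            "pearson_model": float(np.corrcoef(pred_pb, truth_pb)[0, 1]),
            "pearson_baseline": float(np.corrcoef(base_pb, truth_pb)[0, 1]),
        })
    return pd.DataFrame(rows, columns=["cell_type", "holdout_time",
                                       "query_time", "n_cells",
                                       "pearson_model", "pearson_baseline"])
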